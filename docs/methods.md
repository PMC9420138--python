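# Methods

This note documents the models, rules and numerical choices behind the
harmonization pipeline, the design decisions taken where the procedure was
genuinely open, and what the synthetic-data tests do and do not establish
about behavior on real exports.

## The harmonization procedure

The pipeline consumes one row per raw nutrient result and emits (a) a
harmonized daily table with one row per (site, date, nutrient parameter)
and (b) an audit table retaining every raw row with per-step keep/drop/NA
flags. The step order is fixed: organization names → site resolution →
the filter cascade (medium, date, chemical form, concentration value,
units, detection codes, sample fraction, activity type, result type) →
unit/form conversion and renaming → detection-limit approximation →
imputation → outlier flagging → duplicate averaging → fraction
combination → filtered/unfiltered consistency. Flags form a cascade: the
first failing step marks the record `drop`, and every later flag on that
record is the literal `NA` (never evaluated). `media_flag` and
`date_flag` sit ahead of the cascade and are always evaluated, so they
have no `NA` arm.

### Site resolution

A site is a unique (MLI, x, y) combination in a projected equal-area
plane (meters). For an MLI with several coordinate pairs, all pairs merge
to the first-appearing pair when **every** pairwise Euclidean distance is
within the 400 m threshold; otherwise all pairs are left untouched. A
distance of exactly 400 m merges (the boundary is unassigned in the
procedure's usual statement; one rule keeps the implementation total).
MLI merging then runs on exact resolved coordinates, assigning the
first-appearing MLI. Coordinate resolution runs first because it can
create the exact coordinate equality MLI merging needs.

The single pass is not a fixpoint on pathological inputs: if MLI merging
assigns one identifier to several coordinate pairs that themselves lie
within 400 m, a second pass would merge further. Such alias chains do
not occur under the generator's conditions and are rare in practice;
the pipeline intentionally performs one pass.

### Chemical form and units

Form inference precedence: the nutrient name ("Nitrate as N" →
elemental, "Ammonia as NH3" → molecular NH₃), then an "as X" qualifier
in the unit text, then an analytical-method registry (e.g. method
4500-NO3-E reports mg/L as N). Records whose form stays unknown are
uninterpretable and dropped. Molecular concentrations are multiplied by
fixed mass ratios (NH₃ 0.822, NH₄ 0.776, NO₃ 0.225, PO₄ 0.326), applied
at the printed 3-decimal precision rather than re-derived from atomic
masses — the published ratios are the interoperability standard, and a
re-derivation would differ in the fourth decimal. Unit conversion
multiplies by a registry factor (µg/L → 1e-3; ppm → 1 under the dilute
aqueous convention); units with no mass-per-volume meaning
(`% recovery`, `cm3/g`, counts, turbidity, …) are unconvertible and
drop the record. Molar units (µmol/L) are deliberately unconvertible:
the conversion needs the molar mass of an often-unknown form. Units are
converted before the form factor; the two factors commute, the order is
fixed only for determinism. Detection limits follow the same conversion
path; a DL whose units are missing or unconvertible is treated as not
provided.

The raw-name vocabulary (31 names with spelling/underscore dialects),
the media whitelist, the QC activity-type set, the detection-code
vocabulary and the fraction map are configuration data, not code: the
raw dialect is not standardized, so the defaults cover the synthetic
generator's vocabulary plus common export terms, and every registry can
be overridden from YAML. The fraction term "total" is mapped to
"unfiltered" (its filtration-status sense); the sum-of-forms sense of
"total" is handled by nutrient naming, not the fraction flag.
"Hydrolyzable" and "soluble reactive" phosphorus names are mapped with
unknown form by default (dropped unless units/method clarify), as their
category assignment is genuinely ambiguous; the vocabulary is editable.

### Non-detects

A non-detect is identified by two joint conditions: reported value zero,
negative or missing, **and** detection code/text indicating censoring. A
zero or negative value without censoring metadata is uninterpretable and
dropped at the concentration step; codes indicating contamination or QC
failure drop the record outright.

Non-detects lacking a detection limit receive a common per-nutrient-year
limit: among organizations that reported DL-less non-detects for that
nutrient-year, take each organization's minimum *detected* concentration
and use the largest of these minima — the least sensitive method
plausibly in use. If no qualifying organization has any detected value
the limit is unassignable; such non-detects stay missing and are logged.
Only detected values inform the minima (imputation runs later in the
step order, so imputed values cannot feed the approximation).

### Imputation model

Within a (site, nutrient parameter, year) group, log concentrations are
modeled as Normal(μ, σ²) with vague conjugate priors
μ ~ Normal(0, 1000²) and σ² ~ Inverse-Gamma(0.001, 0.001). Censored
members are latent draws truncated above at log DL — a non-detect's true
value lies in (0, DL]. A data-augmentation Gibbs sampler alternates
truncated-normal draws for censored values with conjugate updates of μ
and σ²; after a burn-in of 1000 iterations, K = 10 draws thinned at
interval 10 are retained per censored value, back-transformed, and
averaged into one imputed concentration. Truncated draws use inverse-CDF
sampling (Φ⁻¹ of a uniformly rescaled tail probability) with the result
clipped to the bound, so imputed values are strictly positive, never
exceed their DL, and vanish as DL → 0. Each group gets its own RNG
stream derived from the global seed and a CRC of the group key, so
results are reproducible and independent of group iteration order.

Groups at or above the 80 % censoring cutoff are not imputed — their
censored members keep a missing concentration and the whole group is
flagged `dont_impute`. Groups with a single observed value are imputed
(the posterior is prior-dominated and wide, but the truncation bound
still constrains the draws); a group with zero observed values cannot
fall below the cutoff. The lognormal likelihood, the priors and the
burn-in/thinning settings above are this package's documented choices;
other univariate Bayesian imputation implementations make their own, so
exact numerical agreement with any of them is not claimed.

The bias comparison implemented in the tests: lognormal(0, 1) groups of
n = 200 with 30 % censoring at the 30th-percentile DL, 50 seeded
replicates; the imputation-based group mean is compared with DL/2
substitution against the replicate's *latent sample mean* — the quantity
the imputation reconstructs. Against the population mean instead, the
sampling noise of 200 draws (SD ≈ 0.15) would swamp the substitution
bias (≈ 0.016) and the comparison would measure noise, not methods.

### Finalization

Outlier thresholds are the 1st and 99th percentiles per nutrient
parameter, pooled over all years, with linear interpolation between
order statistics; values outside the band are flagged, never removed.
Flagging runs on pre-averaging values (the step order places it before
duplicate resolution); a daily average inherits `potential_outlier` if
any member was flagged. Groups with fewer than three present values are
degenerate and left unflagged.

Daily duplicate resolution groups by (MLI, x, y, date, parameter):
records identical except for the reporting organization count once (the
lexicographically first canonical organization is kept); remaining
detected and imputed concentrations average arithmetically, with or
without timestamps; a group of only unimputed non-detects yields one
missing-concentration row. When an average mixes detected and imputed
members the daily row is flagged `imputed`, and its DL is the largest
member DL (consistent with the least-sensitive-method convention).

Fraction combination adds `filtered + particulate → unfiltered` rows
for total nitrogen and total phosphorus only where the unfiltered total
was not itself measured that site-date, flagged
`calculated_by_combining`. Combined rows are not outlier-flagged (the
percentile thresholds were computed before they existed).

The consistency check drops **both** members of a filtered/unfiltered
pair when filtered ≥ unfiltered on the same site-date — either member
could be the erroneous one, so dropping both is conservative. Equality
counts as inconsistent. Records without a counterpart are kept with an
`NA` flag.

Rows for non-detects left unimputed appear in the harmonized table with
a missing concentration, `outlier_flag = NA` and `impute_flag =
imputed` — the flag marks "this was a censored observation", which is
what a secondary user filters on.

## The synthetic generator

The generator draws latent elemental concentrations from per-nutrient
lognormal distributions (defaults span typical stream levels, e.g.
median 1 mg/L total N as N, 0.1 mg/L total P as P, σ = 1 on the log
scale), then corrupts the *reporting*: molecular-basis handles with the
inverse conversion factor, unit dialects (including unconvertible ones),
non-detects censored below a per-nutrient DL placed at the `nd_rate`
quantile (so each record is censored independently with that
probability) and encoded as zero/negative/missing with a censoring code,
organization spelling variants, duplicate coordinates offset by up to
twice the merge threshold (both merge branches occur), duplicate MLIs,
QC activity types, estimated result types, missing dates, bad media,
sub-daily duplicates, and filtered/unfiltered pairs with occasional
injected inconsistency. Each record occupies its own calendar day within
its site-year except deliberate same-day partners, which makes every
duplicate/consistency decision predictable and gives each record a
computable expected fate — the oracle the end-to-end tests compare
against. A `heavy_tails` flag switches log-concentrations to Student-t(3)
for robustness experiments.

Default conditions: 6 organizations, 30 sites, 5 years from 2000,
roughly monthly sampling (Poisson mean 12 per site-year), 15 %
non-detects of which 30 % lack a DL, and low-percent rates for the
metadata corruptions. What the generator does **not** emulate: spatial
autocorrelation, seasonality, trends, organization-specific reporting
cultures, or correlated multi-fault corruption of single records.
Passing tests therefore establish that the pipeline implements its rules
exactly and recovers known truth under those rules — not that the
default vocabularies cover every dialect in any particular real export.

## Numerical and edge-case choices

- Concentration parsing accepts the Unicode minus; non-numeric text is a
  drop (unless censoring metadata make the record a non-detect).
- Percentiles use linear interpolation (the numpy default), matching the
  definition of the audit columns `pct1`/`pct99`.
- The truncated-normal inverse-CDF draw clips the tail probability at
  1e-300; the draw is additionally clipped to the truncation bound, so
  the (0, DL] guarantee is exact even in extreme tails.
- Empty-string fields are missing data; in flag columns the literal
  string `NA` is a flag value ("not evaluated"), distinct from missing.
- Dates serialize as YYYY-MM-DD; writing refuses tables that violate the
  output invariants (duplicate keys, negative concentrations, DL on
  non-imputed rows) and names the first offending row.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the full pipeline on
synthetic tables of a few hundred to a few thousand records (e.g. the
default-conditions acceptance run is ~1,900 records), with the 50
imputation replicates at n = 200. These sizes were chosen because every
tested property is scale-free — set equalities, exact conservation laws
and seeded statistical checks whose power is already ample at these
sizes.

## Known limitations

- Imputation is univariate per group; no covariates, no
  Kaplan–Meier/regression-on-order-statistics alternatives.
- The method registry is a small static table; there is no online
  method-database lookup.
- Harmonized output for an MLI whose distant coordinate pairs were kept
  separate can, in principle, contain the same (MLI, date, parameter)
  at two coordinate pairs; the writer enforces uniqueness and will
  refuse such a table rather than silently merging two physical sites.
- Geodesic distances are out of scope: inputs must arrive in a projected
  plane in meters.
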