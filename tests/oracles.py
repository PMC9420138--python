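"""Independent brute-force re-implementations of pipeline rules.

Pure-Python, loop-based, pandas-free logic used only as test oracles on
small fixtures.  Deliberately written from the rule statements rather than
by calling the package, so agreement is evidence and not tautology.
"""

from __future__ import annotations

import math


def brute_resolve_sites(records: list[dict], threshold: float) -> list[dict]:
    """Site resolution by exhaustive scanning.

    ``records`` need ``record_id``, ``orig_MLI``, ``orig_x``, ``orig_y``;
    returns aligned dicts with ``new_x``, ``new_y``, ``new_MLI``,
    ``combine`` (bool or None) and counts.
    """
    ordered = sorted(records, key=lambda r: r["record_id"])
    # coordinates per MLI, first-appearance order
    coords_of: dict[str, list[tuple]] = {}
    for r in ordered:
        if r["orig_x"] is None or r["orig_y"] is None:
            continue
        pair = (r["orig_x"], r["orig_y"])
        lst = coords_of.setdefault(r["orig_MLI"], [])
        if pair not in lst:
            lst.append(pair)
    out = []
    for r in ordered:
        res = dict(r)
        res["new_x"], res["new_y"] = r["orig_x"], r["orig_y"]
        res["combine"] = None
        pairs = coords_of.get(r["orig_MLI"], [])
        res["n_coords"] = max(len(pairs), 1)
        if len(pairs) > 1:
            close = all(
                math.dist(pairs[i], pairs[j]) <= threshold
                for i in range(len(pairs))
                for j in range(i + 1, len(pairs))
            )
            res["combine"] = close
            if close and r["orig_x"] is not None:
                res["new_x"], res["new_y"] = pairs[0]
        out.append(res)
    # MLIs per exact resolved coordinate, first-appearance order
    mlis_of: dict[tuple, list[str]] = {}
    for res in out:
        if res["new_x"] is None:
            continue
        key = (res["new_x"], res["new_y"])
        lst = mlis_of.setdefault(key, [])
        if res["orig_MLI"] not in lst:
            lst.append(res["orig_MLI"])
    for res in out:
        res["new_MLI"] = res["orig_MLI"]
        res["n_mlis"] = 1
        if res["new_x"] is None:
            continue
        mlis = mlis_of[(res["new_x"], res["new_y"])]
        res["n_mlis"] = len(mlis)
        if len(mlis) > 1:
            res["new_MLI"] = mlis[0]
    return sorted(out, key=lambda r: r["record_id"])


def brute_dl_approximation(rows: list[dict]) -> dict[int, float]:
    """Max-of-org-minima common detection limits.

    ``rows``: dicts with ``record_id``, ``org``, ``param``, ``year``,
    ``is_nd``, ``dl`` (None when absent), ``conc`` (detected mg/L or None).
    Returns {record_id: assigned DL} for every ND lacking one.
    """
    assigned = {}
    keys = {(r["param"], r["year"]) for r in rows if r["is_nd"] and r["dl"] is None}
    for param, year in keys:
        qual_orgs = {
            r["org"]
            for r in rows
            if r["param"] == param and r["year"] == year and r["is_nd"] and r["dl"] is None
        }
        minima = []
        for org in qual_orgs:
            detected = [
                r["conc"]
                for r in rows
                if r["org"] == org
                and r["param"] == param
                and r["year"] == year
                and not r["is_nd"]
                and r["conc"] is not None
            ]
            if detected:
                minima.append(min(detected))
        if not minima:
            continue
        common = max(minima)
        for r in rows:
            if r["param"] == param and r["year"] == year and r["is_nd"] and r["dl"] is None:
                assigned[r["record_id"]] = common
    return assigned


def brute_daily_average(rows: list[dict]) -> dict[tuple, dict]:
    """Daily duplicate resolution by explicit grouping.

    ``rows``: dicts with ``mli``, ``x``, ``y``, ``date``, ``param``,
    ``time``, ``org``, ``conc`` (None for unimputed NDs), ``is_nd``.
    Returns {(mli, x, y, date, param): {"conc", "n", "any_nd"}}.
    """
    groups: dict[tuple, list[dict]] = {}
    for r in rows:
        key = (r["mli"], r["x"], r["y"], r["date"], r["param"])
        groups.setdefault(key, []).append(r)
    out = {}
    for key, members in groups.items():
        # cross-org exact duplicates count once
        seen = {}
        for m in sorted(members, key=lambda m: m["org"]):
            k = (m["time"], m["conc"], m["is_nd"])
            if k not in seen:
                seen[k] = m
        dedup = list(seen.values())
        concs = [m["conc"] for m in dedup if m["conc"] is not None]
        out[key] = {
            "conc": sum(concs) / len(concs) if concs else None,
            "n": len(concs) if concs else len(dedup),
            "any_nd": any(m["is_nd"] for m in dedup),
        }
    return out


def brute_filt_unfilt_qc(daily: dict[tuple, dict]) -> set[tuple]:
    """Keys of daily rows dropped by the filtered >= unfiltered rule.

    ``daily``: {(mli, x, y, date, name, fraction): conc}.
    """
    dropped = set()
    sample_keys = {(k[0], k[1], k[2], k[3], k[4]) for k in daily}
    for sk in sample_keys:
        fk = sk + ("filtered",)
        uk = sk + ("unfiltered",)
        if fk in daily and uk in daily:
            cf, cu = daily[fk], daily[uk]
            if cf is not None and cu is not None and cf >= cu:
                dropped.update({fk, uk})
    return dropped
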