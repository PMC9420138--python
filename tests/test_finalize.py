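"""Outlier flagging, duplicate resolution, fraction combination and QC."""

import numpy as np
import pandas as pd
import pytest

from snapd import (
    HarmonizationConfig,
    combine_fractions,
    flag_outliers,
    qc_filtered_vs_unfiltered,
    resolve_duplicates,
)

from oracles import brute_daily_average, brute_filt_unfilt_qc


def _work_frame(rows):
    """Minimal post-imputation working frame for the finalize stages."""
    defaults = dict(
        media="Water",
        st_abbr="IL",
        st_name="Illinois",
        org_name="USGS",
        N_or_P="N",
        nutrient_name="nitrate",
        sample_fraction="filtered",
        nutrient_parameter="nitrate_filtered",
        year=2000,
        new_MLI="S1",
        new_x=0.0,
        new_y=0.0,
        time="10:00:00",
        ND_flag="keep",
        new_DL=np.nan,
        outlier_flag="not_flagged_as_outlier",
        _dropped=False,
    )
    full = []
    for r in rows:
        d = dict(defaults)
        d.update(r)
        full.append(d)
    df = pd.DataFrame(full)
    df["_date"] = pd.to_datetime(df.get("date", "2000-06-01"))
    df["record_id"] = np.arange(len(df))
    return df


class TestOutliers:
    def test_linear_interpolation_percentiles_on_1_to_100(self):
        rows = [{"new_conc": float(v)} for v in range(1, 101)]
        out = flag_outliers(_work_frame(rows))
        # p1 = 1.99, p99 = 99.01 under linear interpolation
        assert out["pct1"].iloc[0] == pytest.approx(1.99)
        assert out["pct99"].iloc[0] == pytest.approx(99.01)
        flags = dict(zip(out["new_conc"], out["outlier_flag"]))
        assert flags[100.0] == "potential_outlier"
        assert flags[1.0] == "potential_outlier"
        assert flags[50.0] == "not_flagged_as_outlier"

    def test_missing_concentration_gets_na(self):
        rows = [{"new_conc": 1.0}, {"new_conc": 2.0}, {"new_conc": 3.0}, {"new_conc": np.nan}]
        out = flag_outliers(_work_frame(rows))
        assert out.loc[3, "outlier_flag"] == "NA"

    def test_degenerate_equal_values_unflagged(self):
        rows = [{"new_conc": 2.0} for _ in range(10)]
        out = flag_outliers(_work_frame(rows))
        assert set(out["outlier_flag"]) == {"not_flagged_as_outlier"}

    def test_tiny_group_unflagged(self):
        rows = [{"new_conc": 1.0}, {"new_conc": 100.0}]
        out = flag_outliers(_work_frame(rows))
        assert set(out["outlier_flag"]) == {"not_flagged_as_outlier"}

    def test_dropped_rows_untouched(self):
        rows = [{"new_conc": 1.0, "_dropped": True}] + [
            {"new_conc": float(v)} for v in (1, 2, 3, 4)
        ]
        out = flag_outliers(_work_frame(rows))
        assert out.loc[0, "outlier_flag"] == "NA"


class TestDuplicates:
    def test_same_day_values_average(self):
        rows = [
            {"new_conc": 2.0, "time": "08:00:00"},
            {"new_conc": 4.0, "time": "14:00:00"},
        ]
        _, daily = resolve_duplicates(_work_frame(rows))
        assert len(daily) == 1
        assert daily.loc[0, "conc"] == pytest.approx(3.0)
        assert daily.loc[0, "num_obs_per_date"] == 2
        assert daily.loc[0, "impute_flag"] == "detected"

    def test_detected_and_imputed_mix_flags_imputed(self):
        rows = [
            {"new_conc": 1.0},
            {"new_conc": 0.2, "ND_flag": "ND", "new_DL": 0.4, "time": "15:00:00"},
        ]
        _, daily = resolve_duplicates(_work_frame(rows))
        assert daily.loc[0, "conc"] == pytest.approx(0.6)
        assert daily.loc[0, "impute_flag"] == "imputed"
        assert daily.loc[0, "DL"] == pytest.approx(0.4)

    def test_cross_org_identical_records_collapse(self):
        rows = [
            {"new_conc": 1.5, "org_name": "USGS"},
            {"new_conc": 1.5, "org_name": "EPA"},
        ]
        flagged, daily = resolve_duplicates(_work_frame(rows))
        assert len(daily) == 1
        assert daily.loc[0, "conc"] == pytest.approx(1.5)
        assert daily.loc[0, "num_obs_per_date"] == 1
        assert set(flagged["num_orgs_per_obs"]) == {2}
        assert daily.loc[0, "org_name"] == "EPA"  # lexicographically first

    def test_all_unimputed_nds_collapse_to_one_na_row(self):
        rows = [
            {"new_conc": np.nan, "ND_flag": "ND", "outlier_flag": "NA"},
            {"new_conc": np.nan, "ND_flag": "ND", "outlier_flag": "NA", "time": "16:00:00"},
        ]
        _, daily = resolve_duplicates(_work_frame(rows))
        assert len(daily) == 1
        assert pd.isna(daily.loc[0, "conc"])
        assert daily.loc[0, "outlier_flag"] == "NA"
        assert daily.loc[0, "impute_flag"] == "imputed"

    def test_daily_row_inherits_outlier_flag(self):
        rows = [
            {"new_conc": 50.0, "outlier_flag": "potential_outlier"},
            {"new_conc": 1.0, "time": "17:00:00"},
        ]
        _, daily = resolve_duplicates(_work_frame(rows))
        assert daily.loc[0, "outlier_flag"] == "potential_outlier"

    def test_mean_preservation(self):
        rng = np.random.default_rng(0)
        rows = [
            {
                "new_conc": float(rng.uniform(0.1, 5)),
                "time": f"{int(rng.integers(6, 20)):02d}:00:00",
                "date": rng.choice(["2000-06-01", "2000-06-02"]),
                "nutrient_parameter": rng.choice(["a_f", "b_u"]),
            }
            for _ in range(40)
        ]
        frame = _work_frame(rows)
        _, daily = resolve_duplicates(frame)
        total_daily = (daily["conc"] * daily["num_obs_per_date"]).sum()
        assert total_daily == pytest.approx(frame["new_conc"].sum(), rel=1e-9)


class TestCombination:
    def _daily(self, rows):
        base = dict(
            media="Water", st_abbr="IL", st_name="Illinois", org_name="USGS",
            N_or_P="P", nutrient_name="total phosphorus", year=2000,
            date=pd.Timestamp("2000-06-01"), MLI="S1", x=0.0, y=0.0,
            conc_units="mg/L as P", outlier_flag="not_flagged_as_outlier",
            num_obs_per_date=1, impute_flag="detected", DL=np.nan, DL_units=np.nan,
        )
        out = []
        for r in rows:
            d = dict(base)
            d.update(r)
            d.setdefault("nutrient_parameter", f"{d['nutrient_name']}_{d['sample_fraction']}")
            out.append(d)
        return pd.DataFrame(out)

    def test_components_sum_into_missing_total(self, config):
        daily = self._daily(
            [
                {"sample_fraction": "filtered", "conc": 0.1},
                {"sample_fraction": "particulate", "conc": 0.2},
            ]
        )
        out = combine_fractions(daily, config)
        assert len(out) == 3
        new = out.iloc[-1]
        assert new["nutrient_parameter"] == "total phosphorus_unfiltered"
        assert new["conc"] == pytest.approx(0.3)
        assert new["impute_flag"] == "calculated_by_combining"

    def test_single_component_adds_nothing(self, config):
        daily = self._daily([{"sample_fraction": "filtered", "conc": 0.1}])
        assert len(combine_fractions(daily, config)) == 1

    def test_measured_total_blocks_combination(self, config):
        daily = self._daily(
            [
                {"sample_fraction": "filtered", "conc": 0.1},
                {"sample_fraction": "particulate", "conc": 0.2},
                {"sample_fraction": "unfiltered", "conc": 0.5},
            ]
        )
        assert len(combine_fractions(daily, config)) == 3


class TestFilteredUnfilteredQc:
    def _daily(self, pairs):
        rows = []
        for i, (fraction, conc) in enumerate(pairs):
            rows.append(
                dict(
                    media="Water", st_abbr="IL", st_name="Illinois", org_name="USGS",
                    N_or_P="N", nutrient_name="total nitrogen",
                    sample_fraction=fraction,
                    nutrient_parameter=f"total nitrogen_{fraction}",
                    year=2000, date=pd.Timestamp("2000-06-01"), MLI="S1",
                    x=0.0, y=0.0, conc=conc, conc_units="mg/L as N",
                    outlier_flag="not_flagged_as_outlier" if conc is not None else "NA",
                    num_obs_per_date=1, impute_flag="detected",
                    DL=np.nan, DL_units=np.nan,
                )
            )
        return pd.DataFrame(rows)

    def test_inconsistent_pair_dropped(self):
        flagged, surviving = qc_filtered_vs_unfiltered(
            self._daily([("filtered", 0.5), ("unfiltered", 0.4)])
        )
        assert set(flagged["filt2unfilt_flag"]) == {"unfilt conc <= filt conc"}
        assert surviving.empty

    def test_consistent_pair_kept(self):
        flagged, surviving = qc_filtered_vs_unfiltered(
            self._daily([("filtered", 0.3), ("unfiltered", 0.4)])
        )
        assert set(flagged["filt2unfilt_flag"]) == {"keep"}
        assert len(surviving) == 2

    def test_unpaired_record_na_and_kept(self):
        flagged, surviving = qc_filtered_vs_unfiltered(self._daily([("filtered", 0.3)]))
        assert set(flagged["filt2unfilt_flag"]) == {"NA"}
        assert len(surviving) == 1

    def test_equality_counts_as_inconsistent(self):
        _, surviving = qc_filtered_vs_unfiltered(
            self._daily([("filtered", 0.4), ("unfiltered", 0.4)])
        )
        assert surviving.empty


class TestBruteForceEquivalence:
    def test_daily_averaging_matches_oracle(self):
        rng = np.random.default_rng(2)
        rows = []
        for _ in range(90):
            is_nd = rng.random() < 0.2
            rows.append(
                {
                    "new_MLI": rng.choice(["S1", "S2"]),
                    "date": rng.choice(["2000-06-01", "2000-06-02", "2000-06-03"]),
                    "nutrient_parameter": rng.choice(["a_f", "b_u"]),
                    "time": rng.choice(["08:00:00", "12:00:00"]),
                    "org_name": rng.choice(["USGS", "EPA"]),
                    "ND_flag": "ND" if is_nd else "keep",
                    "new_conc": np.nan if is_nd else float(np.round(rng.uniform(0.1, 3), 3)),
                }
            )
        frame = _work_frame(rows)
        _, daily = resolve_duplicates(frame)
        oracle_rows = [
            dict(
                mli=r["new_MLI"], x=r["new_x"], y=r["new_y"], date=r["_date"],
                param=r["nutrient_parameter"], time=r["time"], org=r["org_name"],
                conc=None if pd.isna(r["new_conc"]) else r["new_conc"],
                is_nd=r["ND_flag"] == "ND",
            )
            for _, r in frame.iterrows()
        ]
        expected = brute_daily_average(oracle_rows)
        assert len(daily) == len(expected)
        for _, row in daily.iterrows():
            exp = expected[(row["MLI"], row["x"], row["y"], row["date"], row["nutrient_parameter"])]
            if exp["conc"] is None:
                assert pd.isna(row["conc"])
            else:
                assert row["conc"] == pytest.approx(exp["conc"], rel=1e-12)
            assert row["num_obs_per_date"] == exp["n"]
            assert (row["impute_flag"] == "imputed") == exp["any_nd"]

    def test_qc_matches_oracle(self):
        rng = np.random.default_rng(7)
        rows = []
        for mli in ("S1", "S2"):
            for day in ("2000-06-01", "2000-06-02"):
                for fraction in ("filtered", "unfiltered"):
                    if rng.random() < 0.8:
                        rows.append(
                            dict(
                                media="Water", st_abbr="IL", st_name="Illinois",
                                org_name="USGS", N_or_P="N",
                                nutrient_name="total nitrogen",
                                sample_fraction=fraction,
                                nutrient_parameter=f"total nitrogen_{fraction}",
                                year=2000, date=pd.Timestamp(day), MLI=mli,
                                x=0.0, y=0.0,
                                conc=float(np.round(rng.uniform(0.1, 1.0), 3)),
                                conc_units="mg/L as N",
                                outlier_flag="not_flagged_as_outlier",
                                num_obs_per_date=1, impute_flag="detected",
                                DL=np.nan, DL_units=np.nan,
                            )
                        )
        daily = pd.DataFrame(rows)
        flagged, surviving = qc_filtered_vs_unfiltered(daily)
        oracle_daily = {
            (r["MLI"], r["x"], r["y"], r["date"], r["nutrient_name"], r["sample_fraction"]): r["conc"]
            for _, r in daily.iterrows()
        }
        dropped = brute_filt_unfilt_qc(oracle_daily)
        got_dropped = {
            (r["MLI"], r["x"], r["y"], r["date"], r["nutrient_name"], r["sample_fraction"])
            for _, r in flagged.iterrows()
            if r["filt2unfilt_flag"] == "unfilt conc <= filt conc"
        }
        assert got_dropped == dropped
        assert len(surviving) == len(daily) - len(dropped)
        # surviving pairs are strictly consistent
        for _, grp in surviving.groupby(["MLI", "date", "nutrient_name"]):
            f = grp.loc[grp["sample_fraction"] == "filtered", "conc"]
            u = grp.loc[grp["sample_fraction"] == "unfiltered", "conc"]
            if len(f) and len(u):
                assert f.iloc[0] < u.iloc[0]
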