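"""Fingerprint extraction and the subtype statistics."""

import numpy as np
import pandas as pd
import pytest

from wmfp import (PhantomSpec, cohens_d, cohens_d_contributions,
                  cross_correlation_matrix, extract_fingerprint_table,
                  generate_phantom_cohort, paired_subtype_tests,
                  tract_overlap_proportions)
from wmfp.maps import ANALYSIS_PARAMS


class TestExtraction:
    def test_noise_free_extraction_equals_planted(self, noise_free_cohort):
        records, truth = noise_free_cohort
        table = extract_fingerprint_table(truth.atlas(), records)
        for name in truth.geometry.names:
            sub = table[table.subtype == name]
            for p in ANALYSIS_PARAMS:
                planted = truth.spec.fingerprints[name][p]
                assert np.nanmean(sub[p]) == pytest.approx(planted,
                                                           rel=0.01, abs=0.15)

    def test_missing_map_gives_nan_cell_only(self, default_cohort):
        records, truth = default_cohort
        table = extract_fingerprint_table(truth.atlas(), records)
        sub0 = table[table.subject_id == records[0].subject_id]
        assert sub0["MPF"].isna().all()          # MPF dropped for subject 0
        assert sub0["R1"].notna().all()

    def test_impossible_gate_warns_and_yields_all_nan(self, default_cohort):
        records, truth = default_cohort
        with pytest.warns(RuntimeWarning):
            table = extract_fingerprint_table(truth.atlas(), records,
                                              wm_p_min=1.01)
        assert table[list(ANALYSIS_PARAMS)].isna().all().all()

    def test_gm_comparison_rows_optional(self, default_cohort):
        records, truth = default_cohort
        table = extract_fingerprint_table(truth.atlas(), records,
                                          include_gm=True)
        assert set(table.subtype) == set(truth.geometry.names) | {"GM"}
        gm_mpf = table[table.subtype == "GM"]["MPF"].mean()
        wm_mpf = table[table.subtype == "frontal"]["MPF"].mean()
        assert gm_mpf < wm_mpf  # grey matter carries less macromolecular pool


class TestPairedTests:
    def test_identical_columns_t_zero_p_one(self):
        table = _toy_table({"A": 1.0, "B": 1.0})
        res = paired_subtype_tests(table, params=["R1"])
        row = res.iloc[0]
        assert row["t"] == 0.0 and row["p"] == 1.0

    def test_constant_offset_zero_variance_floors_p(self):
        table = _toy_table({"A": 1.0, "B": 2.0})
        res = paired_subtype_tests(table, params=["R1"])
        assert res.iloc[0]["p"] <= 1e-300

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(10, 2, 20)
        y = x + rng.normal(2, 1, 20)
        rows = []
        for i in range(20):
            rows.append({"subject_id": f"s{i}", "subtype": "A", "R1": x[i],
                         "age": 30, "gender": "F"})
            rows.append({"subject_id": f"s{i}", "subtype": "B", "R1": y[i],
                         "age": 30, "gender": "F"})
        res = paired_subtype_tests(pd.DataFrame(rows), params=["R1"])
        d = x - y
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.iloc[0]["t"] == pytest.approx(t_oracle, abs=1e-10)

    def test_too_few_pairs_nan_with_warning(self):
        table = _toy_table({"A": 1.0, "B": 2.0}, n=2)
        with pytest.warns(RuntimeWarning):
            res = paired_subtype_tests(table, params=["R1"])
        assert np.isnan(res.iloc[0]["t"])


class TestCohensD:
    def test_reported_ad_separation(self):
        # the printed track vs frontal AD values: (1066 +/- 40) vs (863 +/- 22)
        assert cohens_d(1066.0, 40.0, 863.0, 22.0) == pytest.approx(6.29,
                                                                    abs=0.005)

    def test_identical_groups_zero_distance(self):
        table = _toy_table({"A": 1.0, "B": 1.0}, jitter=0.1)
        half = table.copy()
        half.loc[half.subtype == "B", "R1"] = \
            table[table.subtype == "A"]["R1"].to_numpy()
        res = cohens_d_contributions(half, params=["R1"])
        assert res.iloc[0]["d"] == pytest.approx(0.0, abs=1e-12)

    def test_contributions_sum_to_one(self, default_cohort):
        records, truth = default_cohort
        table = extract_fingerprint_table(truth.atlas(), records)
        res = cohens_d_contributions(table)
        for _, grp in res.groupby("pair"):
            s = grp["contribution"].dropna().sum()
            assert s == pytest.approx(1.0, abs=1e-9)

    def test_ad_dominates_track_vs_subcortical_pairs(self, default_cohort):
        records, truth = default_cohort
        table = extract_fingerprint_table(truth.atlas(), records)
        res = cohens_d_contributions(table)
        for pair in ("track vs frontal", "track vs central"):
            grp = res[res.pair == pair].set_index("param")
            assert grp["contribution"].idxmax() == "AD"


class TestCrossCorrelation:
    def test_self_and_anti_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=24)
        rows = []
        for i, v in enumerate(x):
            rows.append({"subject_id": f"s{i}", "subtype": "A",
                         "R1": v, "R2": -v, "AD": v, "age": 30, "gender": "F"})
        out = cross_correlation_matrix(pd.DataFrame(rows),
                                       params=["R1", "R2", "AD"])["A"]
        r12 = out[(out.param_a == "R1") & (out.param_b == "R2")].iloc[0]["r"]
        r13 = out[(out.param_a == "R1") & (out.param_b == "AD")].iloc[0]["r"]
        assert r12 == pytest.approx(-1.0, abs=1e-12)
        assert r13 == pytest.approx(1.0, abs=1e-12)

    def test_monte_carlo_mean_r_near_population(self, rng):
        rho, n = 0.7, 24
        rs = []
        cov = np.array([[1, rho], [rho, 1]])
        for _ in range(1000):
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            rs.append(np.corrcoef(xy[:, 0], xy[:, 1])[0, 1])
        assert abs(np.mean(rs) - 0.69) < 0.03  # small-sample bias included

    def test_constant_column_gives_nan(self):
        rows = [{"subject_id": f"s{i}", "subtype": "A", "R1": 1.0,
                 "R2": float(i), "age": 30, "gender": "F"} for i in range(10)]
        out = cross_correlation_matrix(pd.DataFrame(rows),
                                       params=["R1", "R2"])["A"]
        assert np.isnan(out.iloc[0]["r"])


class TestTractOverlap:
    def test_phantom_tracts_follow_construction(self, decomposition,
                                                default_cohort):
        atlas, _, _ = decomposition
        _, truth = default_cohort
        table = tract_overlap_proportions(atlas, truth.tracts).set_index("tract")
        crossing = table.loc["crossing"]
        assert crossing["track"] > 0.2 and crossing["central"] > 0.2
        confined = table.loc["confined"]
        assert confined["track"] > 0.9
        assert confined[["frontal", "central"]].max() < 0.05

    def test_disjoint_tract_all_zero(self, decomposition, default_cohort):
        atlas, _, _ = decomposition
        _, truth = default_cohort
        corner = np.zeros_like(truth.tracts["confined"])
        corner[:3, :3, :3] = True  # outside the brain
        out = tract_overlap_proportions(atlas, {"corner": corner})
        assert out.iloc[0][atlas.subtype_names].sum() == 0.0

    def test_empty_tract_rejected(self, decomposition, default_cohort):
        atlas, _, _ = decomposition
        _, truth = default_cohort
        with pytest.raises(ValueError, match="empty"):
            tract_overlap_proportions(
                atlas, {"none": np.zeros_like(truth.tracts["confined"])})


def _toy_table(values: dict, n: int = 10, jitter: float = 0.0):
    rng = np.random.default_rng(0)
    rows = []
    for i in range(n):
        for subtype, v in values.items():
            rows.append({"subject_id": f"s{i}", "subtype": subtype,
                         "R1": v + jitter * rng.normal(),
                         "age": 30.0, "gender": "F"})
    return pd.DataFrame(rows)
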