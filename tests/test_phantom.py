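"""Synthetic cohort generator: geometry, mixing, determinism, raw signals."""

import numpy as np
import pytest

from wmfp import (MGREParams, PhantomSpec, build_component_geometry,
                  fit_r2star, generate_phantom_cohort, inject_missing_entries,
                  inject_subject_artifact, make_tract_fixtures,
                  simulate_raw_signals)
from wmfp.maps import ANALYSIS_PARAMS
from wmfp.phantom import SequenceSet
from wmfp.relaxometry import fit_r1_vfa
from wmfp.sequences import VFAParams


class TestGeometry:
    def test_default_fields_weakly_correlated_and_disjoint(self):
        geom = build_component_geometry(PhantomSpec())
        assert geom.weights.shape[0] == 3
        brain = geom.brain_mask
        for i in range(3):
            for j in range(i + 1, 3):
                r = np.corrcoef(geom.weights[i][brain], geom.weights[j][brain])[0, 1]
                assert r <= 0.2
                si, sj = geom.weights[i] >= 0.5, geom.weights[j] >= 0.5
                assert np.sum(si & sj) <= 0.1 * min(si.sum(), sj.sum())

    def test_single_component_inside_wm(self):
        spec = PhantomSpec(geometries=PhantomSpec().geometries[:1])
        geom = build_component_geometry(spec)
        support = geom.weights[0] >= 0.5
        assert np.all(geom.p_wm[support] > 0.8)

    def test_fixed_seed_is_deterministic(self):
        g1 = build_component_geometry(PhantomSpec(seed=5))
        g2 = build_component_geometry(PhantomSpec(seed=5))
        assert np.array_equal(g1.weights, g2.weights)

    def test_overlapping_spec_rejected(self):
        from wmfp.phantom import BlobGeometry
        spec = PhantomSpec(geometries=(
            BlobGeometry("a", (0, 0, 0), (5, 5, 5)),
            BlobGeometry("b", (1, 0, 0), (5, 5, 5))))
        with pytest.raises(ValueError):
            build_component_geometry(spec)


class TestCohort:
    def test_pure_core_equals_fingerprint(self, noise_free_cohort):
        records, truth = noise_free_cohort
        for c, name in enumerate(truth.geometry.names):
            core = truth.core_mask(c)
            assert core.any()
            for p in ANALYSIS_PARAMS:
                vals = records[0].maps[p].data[core]
                assert np.allclose(vals, truth.spec.fingerprints[name][p])

    def test_track_ad_mean_within_2se_of_planted(self, default_cohort):
        records, truth = default_cohort
        core = truth.core_mask("track")
        means = [r.maps["AD"].data[core].mean() for r in records if "AD" in r.maps]
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - 1066.0) < 2 * se + 1e-9

    def test_default_missingness_gives_133_maps(self, default_cohort):
        records, _ = default_cohort
        assert sum(len(r.maps) for r in records) == 20 * 7 - 7

    def test_byte_identical_for_fixed_seed(self):
        r1, t1 = generate_phantom_cohort(PhantomSpec(seed=3))
        r2, t2 = generate_phantom_cohort(PhantomSpec(seed=3))
        for a, b in zip(r1, r2):
            assert a.maps.keys() == b.maps.keys()
            for p in a.maps:
                assert a.maps[p].data.tobytes() == b.maps[p].data.tobytes()
        assert t1.covariates.equals(t2.covariates)

    def test_between_subject_sd_matches_design(self, default_cohort):
        # in-core fingerprint means spread within 25% of the designed SD
        # (averaged over the three components to beat the n=20 chi noise)
        records, truth = default_cohort
        spec = truth.spec
        for p in ("AD", "MPF"):
            sds = []
            for c in range(3):
                core = truth.core_mask(c)
                means = [r.maps[p].data[core].mean() for r in records
                         if p in r.maps]
                sds.append(np.std(means, ddof=1))
            assert abs(np.mean(sds) - spec.subject_sd[p]) \
                < 0.25 * spec.subject_sd[p]

    def test_covariate_slopes_recoverable_by_regression(self, default_cohort):
        records, truth = default_cohort
        core = truth.core_mask("frontal")
        ages = np.array([r.age for r in records if "R1" in r.maps])
        means = np.array([r.maps["R1"].data[core].mean() for r in records
                          if "R1" in r.maps])
        slope = np.polyfit(ages, means, 1)[0]
        assert slope < 0  # planted negative frontal R1 age slope

    def test_exterior_voxels_zero(self, default_cohort):
        records, truth = default_cohort
        outside = ~truth.geometry.brain_mask
        for p, m in records[5].maps.items():
            assert np.all(m.data[outside] == 0)


class TestMissingness:
    def test_drop_single_map(self):
        records, _ = generate_phantom_cohort(PhantomSpec(missing_entries=()))
        records = inject_missing_entries(records, [(1, "MPF")])
        assert "MPF" not in records[1].maps and len(records[1].maps) == 6

    def test_drop_nothing_is_identity(self):
        records, _ = generate_phantom_cohort(PhantomSpec(missing_entries=()))
        n = sum(len(r.maps) for r in records)
        records = inject_missing_entries(records, [])
        assert sum(len(r.maps) for r in records) == n

    def test_unknown_entry_rejected(self):
        records, _ = generate_phantom_cohort(PhantomSpec(missing_entries=()))
        with pytest.raises(KeyError):
            inject_missing_entries(records, [(0, "MPF"), (0, "MPF")])

    def test_subject_with_no_maps_flagged_unusable(self):
        records, _ = generate_phantom_cohort(PhantomSpec(missing_entries=()))
        records = inject_missing_entries(
            records, [(0, p) for p in ANALYSIS_PARAMS])
        assert not records[0].usable_for_decomposition
        assert records[1].usable_for_decomposition


class TestTracts:
    def test_crossing_tract_spans_two_territories(self, default_cohort):
        _, truth = default_cohort
        tracts = truth.tracts
        w = truth.geometry.weights
        crossing = tracts["crossing"]
        assert (crossing & (w[0] > 0.5)).sum() > 0   # track territory
        assert (crossing & (w[2] > 0.5)).sum() > 0   # central territory

    def test_confined_tract_single_territory(self, default_cohort):
        _, truth = default_cohort
        confined = truth.tracts["confined"]
        w = truth.geometry.weights
        assert np.all(w[0][confined] > 0.5)
        assert (confined & (w[1] > 0.1)).sum() == 0
        assert (confined & (w[2] > 0.1)).sum() == 0

    def test_deterministic(self):
        a = make_tract_fixtures(PhantomSpec())
        b = make_tract_fixtures(PhantomSpec())
        for k in a:
            assert np.array_equal(a[k], b[k])


class TestRawSignals:
    def test_simulate_then_fit_r2star_noiseless(self, noise_free_cohort):
        records, truth = noise_free_cohort
        raw = simulate_raw_signals(records[0])
        r2s, _ = fit_r2star(raw["mgre"], MGREParams(),
                            mask=truth.geometry.brain_mask)
        brain = truth.geometry.brain_mask
        true = records[0].maps["R2star"].data
        err = np.abs(r2s.data[brain] - true[brain]) / np.maximum(true[brain], 1e-9)
        assert np.nanmax(err) < 1e-6

    def test_b1_field_biases_r1_unless_corrected(self, noise_free_cohort):
        records, truth = noise_free_cohort
        raw = simulate_raw_signals(records[0], b1_field=0.9)
        brain = truth.geometry.brain_mask
        biased = fit_r1_vfa(raw["vfa"][..., 0], raw["vfa"][..., 1], VFAParams(),
                            mask=brain)
        fixed = fit_r1_vfa(raw["vfa"][..., 0], raw["vfa"][..., 1], VFAParams(),
                           b1=0.9, mask=brain)
        true = records[0].maps["R1"].data
        assert np.nanmax(np.abs(fixed.data[brain] - true[brain])
                         / true[brain]) < 1e-6
        assert np.nanmedian(np.abs(biased.data[brain] - true[brain])
                            / true[brain]) > 0.01

    def test_missing_prerequisite_skips_sequence(self, caplog):
        records, _ = generate_phantom_cohort(PhantomSpec(missing_entries=()))
        del records[0].maps["R2"]
        raw = simulate_raw_signals(records[0])
        assert "pssfp" not in raw and "mgre" in raw

    def test_exterior_stays_zero_in_outputs(self, noise_free_cohort):
        records, truth = noise_free_cohort
        raw = simulate_raw_signals(records[0])
        outside = ~truth.geometry.brain_mask
        for key, vol in raw.items():
            assert np.all(vol[outside] == 0), key


def test_subject_artifact_affects_one_subject_only():
    records, _ = generate_phantom_cohort(PhantomSpec(seed=2, missing_entries=()))
    before = records[5].maps["R1"].data.copy()
    other = records[6].maps["R1"].data.copy()
    inject_subject_artifact(records, 5)
    assert not np.array_equal(records[5].maps["R1"].data, before)
    assert np.array_equal(records[6].maps["R1"].data, other)
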