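"""Shared fixtures: the default phantom cohort and one full decomposition.

The expensive objects (cohort, multi-order ICA run) are session-scoped so
the acceptance tests and the unit tests share a single computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from wmfp import PhantomSpec, RunConfig, generate_phantom_cohort
from wmfp.pipeline import decompose_records, label_atlas_from_truth


@pytest.fixture(scope="session")
def default_cohort():
    records, truth = generate_phantom_cohort(PhantomSpec(seed=0))
    return records, truth


@pytest.fixture(scope="session")
def noise_free_cohort():
    spec = PhantomSpec(
        seed=0,
        subject_sd={p: 0.0 for p in PhantomSpec().subject_sd},
        component_jitter_frac=0.0,
        covariate_effects=(),
        noise_sd={p: 0.0 for p in PhantomSpec().noise_sd},
        anatomy_contrast_frac=0.0,
        missing_entries=(),
    )
    return generate_phantom_cohort(spec)


@pytest.fixture(scope="session")
def decomposition(default_cohort):
    """Multi-order decomposition of the default cohort, truth-labelled."""
    records, truth = default_cohort
    config = RunConfig()
    atlas, selection = decompose_records(
        records, truth.geometry.brain_mask, truth.geometry.p_wm, config)
    label_atlas_from_truth(atlas, truth, config.thresholds.smoothing_fwhm_mm)
    return atlas, selection, config


@pytest.fixture(scope="session")
def matrix_n8(default_cohort):
    """Smoothed group matrix of the default cohort plus its N = 8 ICA run."""
    from wmfp import build_group_matrix, run_spatial_ica, smooth_subject_maps

    records, truth = default_cohort
    smoothed = smooth_subject_maps(records, truth.geometry.brain_mask, 5.0)
    gm = build_group_matrix(smoothed, truth.geometry.brain_mask)
    comps = run_spatial_ica(gm, 8, seed=17)
    return gm, comps


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
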