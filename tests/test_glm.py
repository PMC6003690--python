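"""Repeated-measures GLM: Wilks tests, planted effects, refusal contract."""

import numpy as np
import pandas as pd
import pytest

from wmfp import PhantomSpec, extract_fingerprint_table, generate_phantom_cohort, glm_subtype_age_gender
from wmfp.glm import wilks_single_df


def _table_from_truth(seed, **spec_kw):
    records, truth = generate_phantom_cohort(PhantomSpec(seed=seed, **spec_kw))
    return extract_fingerprint_table(truth.atlas(), records)


def test_wilks_single_df_matches_univariate_f():
    # with one response the Wilks F must equal the classical OLS t^2 = F
    rng = np.random.default_rng(0)
    n = 25
    x = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = (0.4 * x[:, 1] + rng.normal(size=n))[:, None]
    b = np.linalg.lstsq(x, y, rcond=None)[0]
    resid = y - x @ b
    e = resid.T @ resid
    xtx_inv = np.linalg.inv(x.T @ x)
    h = np.outer(b[1], b[1]) / xtx_inv[1, 1]
    t = wilks_single_df(e, h, n - 2)
    # classical regression F for the slope
    se = np.sqrt(e[0, 0] / (n - 2) * xtx_inv[1, 1])
    f_classic = float((b[1, 0] / se) ** 2)
    assert t.f_value == pytest.approx(f_classic, rel=1e-10)
    assert (t.df1, t.df2) == (1, n - 2)


def test_planted_global_mpf_age_slope_detected():
    g = glm_subtype_age_gender(_table_from_truth(0), omnibus=False)
    g = g.set_index(["analysis", "term"])
    assert g.loc[("MPF", "age"), "p"] < 0.05
    assert g.loc[("MPF", "type_x_age"), "p"] > 0.05  # no interaction planted


def test_planted_r1_interaction_detected():
    g = glm_subtype_age_gender(_table_from_truth(0), omnibus=False)
    g = g.set_index(["analysis", "term"])
    assert g.loc[("R1", "type_x_age"), "p"] < 0.05


def test_planted_adc_gender_interaction_detected():
    # diffusivity raised in women inside the track territory only
    g = glm_subtype_age_gender(_table_from_truth(1), params=["AD"],
                               omnibus=False).set_index("term")
    assert g.loc["type_x_gender", "p"] < 0.05


def test_omnibus_dfs_match_formulation():
    # 21 complete subjects, rank-3 design -> within tests are F(14, 6)
    table = _table_from_truth(3, n_subjects=21, missing_entries=())
    g = glm_subtype_age_gender(table).set_index(["analysis", "term"])
    # error df = 21 - 3 = 18; Wilks df2 = 18 - p + 1
    assert (g.loc[("omnibus", "type_x_age"), "df1"],
            g.loc[("omnibus", "type_x_age"), "df2"]) == (14, 5)
    assert (g.loc[("omnibus", "age"), "df1"],
            g.loc[("omnibus", "age"), "df2"]) == (7, 12)


def test_omnibus_refused_when_underdetermined(default_cohort):
    # the default cohort keeps only 16 complete subjects: 14 response
    # dimensions cannot be tested on 13 error df
    records, truth = default_cohort
    table = extract_fingerprint_table(truth.atlas(), records)
    with pytest.raises(ValueError, match="error df|complete"):
        glm_subtype_age_gender(table, omnibus=True)


def test_null_rejection_rate_calibrated():
    rng = np.random.default_rng(7)
    rejections = 0
    n_rep = 60
    for _ in range(n_rep):
        n = 20
        rows = []
        age = rng.uniform(20, 58, n)
        gen = np.where(rng.random(n) < 0.5, "F", "M")
        for i in range(n):
            for s in ("A", "B", "C"):
                rows.append({"subject_id": f"s{i}", "subtype": s,
                             "age": age[i], "gender": gen[i],
                             "R1": rng.normal()})
        g = glm_subtype_age_gender(pd.DataFrame(rows), params=["R1"],
                                   omnibus=False).set_index("term")
        rejections += g.loc["type_x_age", "p"] < 0.05
    assert rejections / n_rep <= 0.10
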