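"""Subtype x age/gender repeated-measures GLM on fingerprint tables.

Subtype is a complete within-subject factor; age (continuous, centered) and
gender (binary, centered) are between-subject terms.  Tests follow the
multivariate repeated-measures formulation: between-subject effects act on
the subject means across subtypes, within-subject effects (subtype and its
covariate interactions) act on the subtype difference contrasts, with Wilks'
lambda and its exact F transform for single-degree hypotheses.  The omnibus
analysis stacks all analysis parameters into one doubly multivariate
response.  Missing cells are handled by casewise deletion; a model with more
response dimensions than error degrees of freedom is refused.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .maps import ANALYSIS_PARAMS


@dataclass
class WilksTest:
    statistic: float  # Wilks' lambda
    f_value: float
    df1: int
    df2: int
    p_value: float


def wilks_single_df(e_sscp: np.ndarray, h_sscp: np.ndarray, n_error: int
                    ) -> WilksTest:
    """Wilks' lambda test of a single-degree hypothesis on p responses.

    For hypothesis df = 1 the transform F = ((n_e - p + 1)/p) (1 - L)/L is
    exactly F(p, n_e - p + 1) distributed under the null.
    """
    p = e_sscp.shape[0]
    df2 = n_error - p + 1
    if df2 < 1:
        raise ValueError(
            f"too few error df ({n_error}) for {p} response dimensions")
    lam = float(np.linalg.det(e_sscp) / np.linalg.det(e_sscp + h_sscp))
    lam = min(max(lam, 1e-300), 1.0)
    f = (df2 / p) * (1.0 - lam) / lam
    pval = float(sps.f.sf(f, p, df2))
    return WilksTest(lam, float(f), p, df2, pval)


def _design(age: np.ndarray, gender: np.ndarray) -> np.ndarray:
    age_c = age - age.mean()
    g = np.where(np.asarray(gender) == "F", 0.5, -0.5)
    g = g - g.mean()
    return np.column_stack([np.ones_like(age_c), age_c, g])


def _mlm_tests(y: np.ndarray, x: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray, int]]:
    """Multivariate OLS of y (n x p) on x (n x 3); per-coefficient SSCPs.

    Returns {term: (E, H, n_error)} for the intercept, age and gender rows.
    """
    n, k = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    b = xtx_inv @ x.T @ y
    resid = y - x @ b
    e = resid.T @ resid
    n_error = n - k
    out = {}
    for name, j in (("intercept", 0), ("age", 1), ("gender", 2)):
        bj = b[j][:, None]
        h = (bj @ bj.T) / xtx_inv[j, j]
        out[name] = (e, h, n_error)
    return out


_TERMS = (("age", "between", "age"), ("gender", "between", "gender"),
          ("type", "within", "intercept"), ("type_x_age", "within", "age"),
          ("type_x_gender", "within", "gender"))


def glm_subtype_age_gender(table: pd.DataFrame,
                           params: list[str] | None = None,
                           subtypes: list[str] | None = None,
                           omnibus: bool = True) -> pd.DataFrame:
    """Run the subtype x age/gender GLM on a fingerprint table.

    Returns a tidy frame with one row per (analysis, term): the omnibus
    doubly multivariate tests over all parameters (when enough complete
    subjects are available ``omnibus=True`` raises otherwise) and the
    per-parameter univariate repeated-measures tests.  Terms: age, gender
    (between-subject, acting on subject means), type, type_x_age,
    type_x_gender (within-subject, acting on subtype difference contrasts).
    """
    params = params or [p for p in ANALYSIS_PARAMS if p in table.columns]
    subtypes = subtypes or [s for s in table["subtype"].unique() if s != "GM"]
    n_s = len(subtypes)
    if n_s < 2:
        raise ValueError("need at least two subtypes for a within factor")
    contrast = np.zeros((n_s - 1, n_s))
    for i in range(n_s - 1):
        contrast[i, i], contrast[i, i + 1] = 1.0, -1.0

    wide = {}
    for p in params:
        w = table.pivot_table(index="subject_id", columns="subtype", values=p,
                              dropna=False)
        wide[p] = w.reindex(columns=subtypes)
    covs = table.drop_duplicates("subject_id").set_index("subject_id")

    rows = []

    def run_block(label: str, block_params: list[str]) -> None:
        stacked = pd.concat([wide[p] for p in block_params], axis=1)
        ok = stacked.notna().all(axis=1)
        subj = stacked.index[ok]
        if len(subj) < 4:
            raise ValueError(f"too few complete subjects for {label}")
        x = _design(covs.loc[subj, "age"].to_numpy(float),
                    covs.loc[subj, "gender"].to_numpy())
        y_means = np.column_stack([wide[p].loc[subj].mean(axis=1) for p in block_params])
        y_diffs = np.column_stack([wide[p].loc[subj].to_numpy() @ contrast.T
                                   for p in block_params])
        between = _mlm_tests(y_means, x)
        within = _mlm_tests(y_diffs, x)
        for term, kind, coef in _TERMS:
            e, h, n_e = between[coef] if kind == "between" else within[coef]
            t = wilks_single_df(e, h, n_e)
            rows.append({"analysis": label, "term": term, "wilks": t.statistic,
                         "F": t.f_value, "df1": t.df1, "df2": t.df2,
                         "p": t.p_value, "n_subjects": len(subj)})

    if omnibus:
        run_block("omnibus", params)
    for p in params:
        run_block(p, [p])
    return pd.DataFrame(rows)
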