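"""Subtype comparison statistics.

Paired t-tests between subtype fingerprints, the Cohen's-d contribution
ledger (how much each parameter contributes to the separation of a subtype
pair), within-subtype cross-correlation matrices with two significance
tiers, and tract-overlap proportions.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .decompose import SubtypeAtlas
from .maps import ANALYSIS_PARAMS

_P_FLOOR = 1e-300


def paired_subtype_tests(table: pd.DataFrame,
                         params: list[str] | None = None,
                         alpha: float = 0.05,
                         n_tests: int | None = None) -> pd.DataFrame:
    """Paired t-test per parameter per subtype pair on subject-wise means.

    Casewise deletion per cell pair; fewer than 3 complete pairs yields NaN
    with a warning.  The Bonferroni-corrected threshold alpha / n_tests
    (n_tests defaults to parameters x pairs) drives the ``significant`` flag.
    """
    params = params or list(ANALYSIS_PARAMS)
    subtypes = [s for s in table["subtype"].unique() if s != "GM"]
    pairs = list(itertools.combinations(subtypes, 2))
    m = n_tests if n_tests is not None else len(params) * len(pairs)
    thresh = alpha / max(m, 1)
    rows = []
    for a, b in pairs:
        ta = table[table.subtype == a].set_index("subject_id")
        tb = table[table.subtype == b].set_index("subject_id")
        common = ta.index.intersection(tb.index)
        for p in params:
            x = ta.loc[common, p].to_numpy(float)
            y = tb.loc[common, p].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            if n < 3:
                warnings.warn(f"<3 complete pairs for {p} ({a} vs {b})",
                              RuntimeWarning)
                t = pval = np.nan
            else:
                d = x[ok] - y[ok]
                if np.allclose(d.std(ddof=1), 0.0):
                    if np.allclose(d.mean(), 0.0):
                        t, pval = 0.0, 1.0
                    else:
                        t = np.sign(d.mean()) * np.inf
                        pval = _P_FLOOR
                else:
                    t, pval = sps.ttest_rel(x[ok], y[ok])
                    pval = max(float(pval), _P_FLOOR)
            rows.append({"pair": f"{a} vs {b}", "param": p, "n": n,
                         "t": float(t), "df": n - 1, "p": pval,
                         "significant": bool(np.isfinite(pval) and pval <= thresh)})
    out = pd.DataFrame(rows)
    out.attrs["corrected_threshold"] = thresh
    return out


def cohens_d(m1: float, s1: float, m2: float, s2: float) -> float:
    """Cohen's d with pooled SD sqrt((s1^2 + s2^2)/2) (equal-n groups)."""
    pooled = np.sqrt((s1 ** 2 + s2 ** 2) / 2.0)
    if pooled == 0:
        return float("nan")
    return float((m1 - m2) / pooled)


def cohens_d_contributions(table: pd.DataFrame,
                           params: list[str] | None = None) -> pd.DataFrame:
    """Cohen's-d ledger per subtype pair: d, cumulative distance, contributions.

    distance = sum_p |d_p| and contribution_p = |d_p| / distance; parameters
    with undefined d (zero pooled SD) are excluded from the sum with a
    warning.  Contributions per pair sum to 1 whenever the distance is
    positive.
    """
    params = params or list(ANALYSIS_PARAMS)
    subtypes = [s for s in table["subtype"].unique() if s != "GM"]
    rows = []
    for a, b in itertools.combinations(subtypes, 2):
        ta = table[table.subtype == a]
        tb = table[table.subtype == b]
        ds = {}
        for p in params:
            x = ta[p].to_numpy(float)
            y = tb[p].to_numpy(float)
            x, y = x[np.isfinite(x)], y[np.isfinite(y)]
            if x.size < 2 or y.size < 2:
                ds[p] = np.nan
                continue
            d = cohens_d(x.mean(), x.std(ddof=1), y.mean(), y.std(ddof=1))
            if not np.isfinite(d):
                warnings.warn(f"zero pooled SD for {p} ({a} vs {b}); "
                              "excluded from the distance", RuntimeWarning)
            ds[p] = d
        finite = {p: v for p, v in ds.items() if np.isfinite(v)}
        distance = float(np.sum([abs(v) for v in finite.values()]))
        for p in params:
            contrib = (abs(ds[p]) / distance
                       if distance > 0 and np.isfinite(ds[p]) else np.nan)
            rows.append({"pair": f"{a} vs {b}", "param": p, "d": ds[p],
                         "distance": distance, "contribution": contrib})
    return pd.DataFrame(rows)


def cross_correlation_matrix(table: pd.DataFrame,
                             params: list[str] | None = None,
                             r_tiers: tuple[float, float] = (0.38, 0.48),
                             min_n: int = 4) -> dict[str, pd.DataFrame]:
    """Pearson correlations between parameters across subjects per subtype.

    Returns one long-format frame per subtype with r, n, and two-tier flags
    at |r| >= ``r_tiers`` (exploratory thresholds, stored with n rather than
    re-derived from alpha).  Constant columns or fewer than ``min_n``
    complete cases give NaN.
    """
    params = params or list(ANALYSIS_PARAMS)
    out: dict[str, pd.DataFrame] = {}
    for s in [s for s in table["subtype"].unique() if s != "GM"]:
        ts = table[table.subtype == s]
        rows = []
        for pa, pb in itertools.combinations(params, 2):
            x = ts[pa].to_numpy(float)
            y = ts[pb].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            if n < min_n or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                r = np.nan
            else:
                r = float(sps.pearsonr(x[ok], y[ok]).statistic)
            rows.append({"param_a": pa, "param_b": pb, "r": r, "n": n,
                         "tier1": bool(np.isfinite(r) and abs(r) >= r_tiers[0]),
                         "tier2": bool(np.isfinite(r) and abs(r) >= r_tiers[1])})
        out[s] = pd.DataFrame(rows)
    return out


def tract_overlap_proportions(atlas: SubtypeAtlas,
                              tracts: dict[str, np.ndarray],
                              z_thresh: float = 2.0) -> pd.DataFrame:
    """Fraction of each tract's voxels inside each subtype's z > threshold region.

    Rows may sum above 1 (subtypes can overlap) or below 1 (unassigned
    voxels).  Empty tracts are rejected.
    """
    rows = []
    for tname, tmask in tracts.items():
        tmask = np.asarray(tmask, bool)
        n_tract = int(tmask.sum())
        if n_tract == 0:
            raise ValueError(f"tract {tname!r} is empty")
        row: dict[str, object] = {"tract": tname, "n_voxels": n_tract}
        for i, sname in enumerate(atlas.subtype_names):
            region = np.nan_to_num(atlas.z_volume(i), nan=-np.inf) > z_thresh
            row[sname] = float(np.sum(tmask & region) / n_tract)
        rows.append(row)
    return pd.DataFrame(rows)
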