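"""Spatial ICA of the group matrix, subtype selection, and reproducibility.

The group matrix (maps x voxels) is decomposed into spatially independent
z-scored source maps with per-row mixing loadings.  White-matter subtype
components are selected by two criteria: the positive suprathreshold part of
the source must overlap white matter, and the component must be shared by
the subjects (between-parameter SD of its loadings exceeding the
between-subject SD by a configurable factor, default 1.5).  Decompositions
at several model orders are matched one-to-one (Hungarian assignment on
spatial correlation), their agreement is quantified with Fleiss' kappa, and
matched components are averaged into the subtype atlas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import label as cc_label
from scipy.optimize import linear_sum_assignment
from scipy.stats import skew

from .agreement import fleiss_kappa
from .groupmatrix import GroupMatrix
from .infomax import infomax
from .maps import ANALYSIS_PARAMS

_EPS = 1e-12


@dataclass(eq=False)  # identity semantics: fields hold arrays
class ComponentMap:
    """One spatial component: z-scored source + mixing loadings + statistics."""

    z_map: np.ndarray                  # in-mask vector, mean 0 / SD 1, skew >= 0
    loadings: np.ndarray               # per-row mixing weights
    row_index: list[tuple[str, str]]
    variance_explained: float
    model_order: int
    ratio: float = float("nan")
    wm_overlap: float = float("nan")

    def fingerprint_loading(self) -> dict[str, float]:
        """Mean loading per parameter (over subjects contributing that map)."""
        out = {}
        for p in ANALYSIS_PARAMS:
            vals = [l for l, (_, pid) in zip(self.loadings, self.row_index) if pid == p]
            out[p] = float(np.mean(vals)) if vals else float("nan")
        return out


def run_spatial_ica(matrix: GroupMatrix, n_components: int, seed: int = 0,
                    extended: bool = False) -> list[ComponentMap]:
    """Infomax spatial ICA of the group matrix at one model order.

    Sources are z-scored over the analysis mask and sign-fixed to
    non-negative skewness; components are ordered by variance explained.
    """
    if n_components > matrix.n_rows:
        raise ValueError("model order exceeds the number of rows")
    res = infomax(matrix.data, n_components, seed=seed, extended=extended)
    total_var = float(np.sum((matrix.data - matrix.data.mean(axis=1, keepdims=True)) ** 2))
    comps: list[ComponentMap] = []
    for i in range(n_components):
        src = res.sources[i]
        load = res.mixing[:, i].copy()
        sk = skew(src)
        if sk < 0:
            src, load = -src, -load
        src = (src - src.mean()) / max(src.std(), _EPS)
        var_i = float(np.sum(np.outer(load, src) ** 2)) / max(total_var, _EPS)
        comps.append(ComponentMap(src, load, matrix.row_index, var_i, n_components))
    comps.sort(key=lambda c: c.variance_explained, reverse=True)
    for c in comps:
        c.ratio = param_subject_ratio(c.loadings, c.row_index)
    return comps


def param_subject_ratio(loadings: np.ndarray, row_index: list[tuple[str, str]]
                        ) -> float:
    """Between-parameter over between-subject SD of the mixing loadings.

    Loadings are reshaped to subject x parameter (missing maps excluded);
    the ratio is SD over parameters of the parameter-wise means divided by
    SD over subjects of the subject-wise means (epsilon-guarded).  A shared
    tissue component loads consistently across subjects but differently
    across parameters, giving a large ratio; a subject artifact gives a
    small one.
    """
    subjects = sorted({s for s, _ in row_index})
    params = sorted({p for _, p in row_index})
    if len(subjects) < 2 or len(params) < 2:
        raise ValueError("ratio needs >= 2 subjects and >= 2 parameters")
    by_param = {p: [] for p in params}
    by_subj = {s: [] for s in subjects}
    for l, (s, p) in zip(loadings, row_index):
        by_param[p].append(l)
        by_subj[s].append(l)
    sd_param = np.std([np.mean(v) for v in by_param.values()])
    sd_subj = np.std([np.mean(v) for v in by_subj.values()])
    return float(sd_param / max(sd_subj, _EPS))


def select_wm_components(components: list[ComponentMap], wm_prob: np.ndarray,
                         analysis_mask: np.ndarray, z_thresh: float = 2.0,
                         overlap_min: float = 0.5, ratio_min: float = 1.5,
                         wm_prob_min: float = 0.5) -> list[ComponentMap]:
    """Keep components that overlap WM and are shared across subjects.

    ``wm_overlap`` is the fraction of positive z >= ``z_thresh`` voxels whose
    WM probability exceeds ``wm_prob_min``; a component is selected when
    wm_overlap >= overlap_min and ratio >= ratio_min.  May select zero
    components.
    """
    wm_in_mask = np.asarray(wm_prob)[np.asarray(analysis_mask, bool)]
    selected = []
    for comp in components:
        supra = comp.z_map >= z_thresh
        comp.wm_overlap = (float(np.mean(wm_in_mask[supra] > wm_prob_min))
                           if supra.any() else 0.0)
        if comp.wm_overlap >= overlap_min and comp.ratio >= ratio_min:
            selected.append(comp)
    return selected


@dataclass
class MatchResult:
    reference_order: int
    matched: list[list[ComponentMap]]   # one stack per reference component
    correlations: np.ndarray            # (n_ref, n_runs) spatial r to reference
    unstable: list[tuple[int, int]]     # (ref component, run) pairs with r < 0.3


def match_components_across_runs(runs: list[list[ComponentMap]],
                                 min_stable_r: float = 0.3) -> MatchResult:
    """One-to-one matching of components across model orders.

    The run with the smallest model order among those with the modal
    selection count serves as reference (an occasional borderline extra
    selection at one order must not redefine the subtypes); every other run
    is assigned to it by the Hungarian algorithm maximizing total |spatial
    correlation| of z-maps.  Matched components are sign-aligned to the
    reference; pairs with |r| < ``min_stable_r`` are flagged unstable, and
    components left unmatched in a run simply contribute no rater there.
    """
    if len(runs) < 2:
        raise ValueError("matching needs at least two runs")
    lengths = [len(r) for r in runs if len(r) > 0]
    if not lengths:
        raise ValueError("no run selected any component")
    modal_len = max(set(lengths), key=lambda n: (lengths.count(n), -n))
    candidates = [r for r in runs if len(r) == modal_len]
    ref = min(candidates, key=lambda r: r[0].model_order if r else 0)
    n_ref = len(ref)
    stacks: list[list[ComponentMap]] = [[c] for c in ref]
    corrs = np.ones((n_ref, len(runs)))
    unstable: list[tuple[int, int]] = []
    for run_idx, run in enumerate(runs):
        if run is ref:
            continue
        if not run:
            corrs[:, run_idx] = np.nan
            continue
        cmat = np.zeros((n_ref, len(run)))
        for i, c_ref in enumerate(ref):
            for j, c in enumerate(run):
                cmat[i, j] = np.corrcoef(c_ref.z_map, c.z_map)[0, 1]
        rows, cols = linear_sum_assignment(-np.abs(cmat))
        assigned = dict(zip(rows, cols))
        for i in range(n_ref):
            if i not in assigned:
                corrs[i, run_idx] = np.nan
                continue
            j = assigned[i]
            r = cmat[i, j]
            comp = run[j]
            if r < 0:
                flipped = ComponentMap(-comp.z_map, -comp.loadings, comp.row_index,
                                       comp.variance_explained, comp.model_order,
                                       comp.ratio, comp.wm_overlap)
                comp, r = flipped, -r
            stacks[i].append(comp)
            corrs[i, run_idx] = r
            if r < min_stable_r:
                unstable.append((i, run_idx))
    ref_idx = runs.index(ref)
    corrs[:, ref_idx] = 1.0
    return MatchResult(ref[0].model_order if ref else 0, stacks, corrs, unstable)


@dataclass
class SubtypeAtlas:
    """Averaged subtype z-maps with agreement statistics and thresholds."""

    z_maps: np.ndarray                  # (n_subtypes, n_mask_voxels)
    analysis_mask: np.ndarray
    subtype_names: list[str]
    kappa: dict[str, dict[float, float]]  # subtype -> {z threshold: kappa}
    z_display: float = 2.0
    z_extract: float = 3.2
    cluster_k: int = 200
    member_stacks: list[list[ComponentMap]] = field(default_factory=list)

    def z_volume(self, subtype: int | str) -> np.ndarray:
        if isinstance(subtype, str):
            subtype = self.subtype_names.index(subtype)
        vol = np.full(self.analysis_mask.shape, np.nan)
        vol[self.analysis_mask] = self.z_maps[subtype]
        return vol

    def display_mask(self, subtype: int | str) -> np.ndarray:
        """z >= z_display mask with the cluster-extent filter applied (26-conn)."""
        vol = self.z_volume(subtype)
        supra = np.nan_to_num(vol, nan=-np.inf) >= self.z_display
        labels, n = cc_label(supra, structure=np.ones((3, 3, 3), int))
        keep = np.zeros_like(supra)
        for lab in range(1, n + 1):
            sel = labels == lab
            if sel.sum() >= self.cluster_k:
                keep |= sel
        return keep

    def pairwise_dice(self, z_thresh: float | None = None) -> np.ndarray:
        """Dice overlap between subtype suprathreshold masks (marginal overlap QC)."""
        zt = self.z_display if z_thresh is None else z_thresh
        masks = [self.z_maps[i] >= zt for i in range(len(self.subtype_names))]
        n = len(masks)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                denom = masks[i].sum() + masks[j].sum()
                d[i, j] = 2.0 * np.sum(masks[i] & masks[j]) / denom if denom else 0.0
        return d


def average_matched_components(match: MatchResult, analysis_mask: np.ndarray,
                               subtype_names: list[str] | None = None,
                               z_display: float = 2.0, z_extract: float = 3.2,
                               cluster_k: int = 200) -> SubtypeAtlas:
    """Average matched z-map stacks and compute per-subtype Fleiss kappa.

    Kappa is computed over analysis-mask voxels at both the display and the
    extraction threshold, with the decompositions as raters.
    """
    names = subtype_names or [f"subtype-{i + 1}" for i in range(len(match.matched))]
    z_avg = np.vstack([np.mean([c.z_map for c in stack], axis=0)
                       for stack in match.matched])
    kappa: dict[str, dict[float, float]] = {}
    for name, stack in zip(names, match.matched):
        kappa[name] = {}
        for zt in (z_display, z_extract):
            if len(stack) < 2:  # matched in no other run: agreement undefined
                kappa[name][zt] = float("nan")
                continue
            ratings = np.vstack([(c.z_map >= zt).astype(int) for c in stack])
            kappa[name][zt] = fleiss_kappa(ratings)
    return SubtypeAtlas(z_avg, np.asarray(analysis_mask, bool), names, kappa,
                        z_display, z_extract, cluster_k, match.matched)
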