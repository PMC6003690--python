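"""Per-subject, per-subtype parameter fingerprints.

A fingerprint is the vector of mean quantitative parameter values inside a
subtype's ROI.  ROIs come from the averaged subtype atlas thresholded at the
extraction z-score (default 3.2); to avoid values diluted by smoothing, means
are taken on the *unsmoothed* maps, gated by the subject's white-matter
probability (default > 0.8).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .decompose import SubtypeAtlas
from .maps import ANALYSIS_PARAMS, DERIVED_PARAMS, SubjectRecord


def extract_fingerprint_table(atlas: SubtypeAtlas, records: list[SubjectRecord],
                              z_min: float = 3.2, wm_p_min: float = 0.8,
                              min_voxels: int = 10,
                              include_gm: bool = False,
                              gm_p_min: float = 0.5) -> pd.DataFrame:
    """Extract the (subject, subtype) x parameter fingerprint table.

    For each subject and subtype, each available parameter map is averaged
    over ROI voxels (atlas z >= ``z_min``) passing the subject's WM
    probability gate; cells with fewer than ``min_voxels`` eligible voxels
    are NaN.  With ``include_gm`` an extra per-subject "GM" row is appended
    (grey-matter probability gate over the whole analysis mask) for
    comparison plots.  Covariates (age, gender) are joined.
    """
    rois = []
    any_voxels = False
    for i, name in enumerate(atlas.subtype_names):
        roi = np.nan_to_num(atlas.z_volume(i), nan=-np.inf) >= z_min
        rois.append((name, roi))
        any_voxels |= bool(roi.any())
    if not any_voxels:
        raise ValueError("no atlas ROI survives the extraction threshold")

    params = list(ANALYSIS_PARAMS) + [p for p in DERIVED_PARAMS if p != "pWM"]
    rows = []
    n_usable = 0
    for rec in records:
        wm = rec.p_wm.data if rec.p_wm is not None else None
        targets = list(rois)
        if include_gm and rec.p_gm is not None:
            targets = targets + [("GM", np.asarray(atlas.analysis_mask, bool))]
        for name, roi in targets:
            if name == "GM":
                gate = roi & (rec.p_gm.data > gm_p_min)
            else:
                gate = roi if wm is None else roi & (wm > wm_p_min)
            row: dict[str, object] = {"subject_id": rec.subject_id,
                                      "subtype": name,
                                      "age": rec.age, "gender": rec.gender,
                                      "n_voxels": int(gate.sum())}
            for p in params:
                if p in rec.maps and gate.sum() >= min_voxels:
                    vals = rec.maps[p].data[gate]
                    vals = vals[np.isfinite(vals)]
                    row[p] = float(vals.mean()) if vals.size >= min_voxels else np.nan
                else:
                    row[p] = np.nan
            if name != "GM" and wm is not None and gate.sum() >= min_voxels:
                row["pWM"] = float(wm[gate].mean())
            else:
                row["pWM"] = np.nan
            if gate.sum() >= min_voxels:
                n_usable += 1
            rows.append(row)
    table = pd.DataFrame(rows)
    if n_usable == 0:
        warnings.warn("every fingerprint cell is empty after gating",
                      RuntimeWarning)
    return table
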