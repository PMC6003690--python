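"""Group-level intensity normalization and the (maps x voxels) group matrix."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maps import ANALYSIS_PARAMS, ParameterMap, SubjectRecord


def normalize_group_intensity(records: list[SubjectRecord], brain_mask: np.ndarray,
                              clamp_sd: float = 4.0,
                              ) -> dict[tuple[str, str], np.ndarray]:
    """Scale each parameter to group z-units, clamped to +/- ``clamp_sd``.

    For each parameter one mean/SD is computed over all in-mask voxels of all
    subjects that have the map, so inter-subject differences in the global
    level are preserved; each map is then transformed x -> (x - m)/sd and
    clamped to [-clamp_sd, clamp_sd].  Returns ``{(subject_id, param): array}``
    of scaled in-mask vectors.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    out: dict[tuple[str, str], np.ndarray] = {}
    for param in ANALYSIS_PARAMS:
        rows = [(rec.subject_id, rec.maps[param].data[mask])
                for rec in records if param in rec.maps]
        if len(rows) < 2:
            continue
        pooled = np.concatenate([v for _, v in rows])
        pooled = pooled[np.isfinite(pooled)]
        m, sd = pooled.mean(), pooled.std()
        if sd == 0:
            raise ValueError(f"parameter {param!r} has zero group SD")
        for sid, vec in rows:
            out[(sid, param)] = np.clip((vec - m) / sd, -clamp_sd, clamp_sd)
    return out


@dataclass
class GroupMatrix:
    """Rows = available (subject, parameter) maps, columns = analysis voxels."""

    data: np.ndarray
    row_index: list[tuple[str, str]]  # (subject_id, param_id)
    analysis_mask: np.ndarray  # boolean grid; columns follow np.flatnonzero order

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    def fold(self, row_vector: np.ndarray) -> np.ndarray:
        """Put an in-mask vector back on the grid (NaN outside the mask)."""
        vol = np.full(self.analysis_mask.shape, np.nan)
        vol[self.analysis_mask] = row_vector
        return vol

    def unfold(self, volume: np.ndarray) -> np.ndarray:
        return np.asarray(volume)[self.analysis_mask]

    def subjects(self) -> list[str]:
        seen: list[str] = []
        for sid, _ in self.row_index:
            if sid not in seen:
                seen.append(sid)
        return seen


def build_group_matrix(records: list[SubjectRecord], brain_mask: np.ndarray,
                       scaled: dict[tuple[str, str], np.ndarray] | None = None,
                       ) -> GroupMatrix:
    """Stack the normalized maps into a 2-D matrix by vectorizing space.

    Columns are restricted to voxels finite in every row, so the matrix never
    carries NaN; rows exist only for non-missing maps.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty analysis mask")
    if scaled is None:
        scaled = normalize_group_intensity(records, mask)
    rows = []
    index: list[tuple[str, str]] = []
    for rec in records:
        for param in ANALYSIS_PARAMS:
            key = (rec.subject_id, param)
            if key in scaled:
                rows.append(scaled[key])
                index.append(key)
    data = np.vstack(rows)
    col_ok = np.all(np.isfinite(data), axis=0)
    final_mask = mask.copy()
    final_mask[mask] = col_ok
    return GroupMatrix(data[:, col_ok], index, final_mask)
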