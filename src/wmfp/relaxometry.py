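"""Relaxometry fitters: multi-echo R2*, two-point VFA R1, and R2'.

All fitters are voxelwise, fully vectorized, and follow one error convention:
a voxel whose signal violates the model's preconditions is marked invalid
(NaN) rather than raising; structurally invalid inputs (too few echoes, grid
mismatch) are rejected with an exception.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .maps import ParameterMap, require_same_grid
from .sequences import MGREParams, VFAParams

# ---------------------------------------------------------------------------
# forward models (shared by the phantom simulator and round-trip tests)


def mgre_signal(s0: np.ndarray, r2star: np.ndarray, params: MGREParams) -> np.ndarray:
    """Mono-exponential magnitude decay S(TE) = S0 exp(-TE * R2*).

    Returns a stack with echo as the last axis; TE in ms, R2* in s^-1.
    """
    te_s = np.asarray(params.echo_times_ms, dtype=float) / 1000.0
    return s0[..., None] * np.exp(-np.asarray(r2star)[..., None] * te_s)


def spgr_signal(m0: np.ndarray, r1: np.ndarray, flip_deg: float | np.ndarray,
                tr_ms: float) -> np.ndarray:
    """Ideally spoiled SPGR steady-state signal."""
    e1 = np.exp(-np.asarray(r1) * tr_ms / 1000.0)
    th = np.deg2rad(flip_deg)
    return m0 * np.sin(th) * (1.0 - e1) / (1.0 - e1 * np.cos(th))


# ---------------------------------------------------------------------------
# fitters


def fit_r2star(echo_stack: np.ndarray, params: MGREParams,
               mask: np.ndarray | None = None,
               subject_id: str = "",
               voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
               ) -> tuple[ParameterMap, ParameterMap]:
    """Log-linear R2* fit of a multi-echo magnitude stack.

    Ordinary least squares of ln S against TE per voxel; the negative slope is
    R2* (clipped at 0 from below).  In-mask voxels with any non-positive
    magnitude are flagged NaN.

    Parameters
    ----------
    echo_stack : 4-D array, echoes along the last axis.
    """
    stack = np.asarray(echo_stack, dtype=float)
    te_ms = np.asarray(params.echo_times_ms, dtype=float)
    if stack.ndim != 4 or stack.shape[-1] != te_ms.size:
        raise ValueError("echo_stack must be 4-D with one volume per echo")
    if te_ms.size < 3:
        raise ValueError("R2* fitting needs at least 3 echoes")

    valid = np.all(stack > 0, axis=-1)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)

    log_s = np.where(stack > 0, np.log(np.where(stack > 0, stack, 1.0)), 0.0)
    te_s = te_ms / 1000.0
    te_c = te_s - te_s.mean()
    # OLS slope of ln S on TE
    slope = (log_s * te_c).sum(axis=-1) / (te_c ** 2).sum()
    intercept = log_s.mean(axis=-1) - slope * te_s.mean()

    r2s = np.where(valid, np.clip(-slope, 0.0, None), np.nan)
    s0 = np.where(valid, np.exp(intercept), np.nan)
    mk = lambda a, pid: ParameterMap(a, pid, subject_id, voxel_size_mm)
    return mk(r2s, "R2star"), mk(s0, "S0")


def fit_r1_vfa(s_low: np.ndarray, s_high: np.ndarray, params: VFAParams,
               b1: ParameterMap | np.ndarray | float | None = None,
               spoiling_correction: Callable[[np.ndarray], np.ndarray] | None = None,
               mask: np.ndarray | None = None,
               subject_id: str = "",
               voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
               ) -> ParameterMap:
    """Two-point VFA R1 fit of an SPGR pair with B1 correction.

    Uses the standard linearization S/sin(th) = E1 * S/tan(th) + M0 (1 - E1)
    at the two B1-corrected flip angles; R1 = -ln(E1)/TR.  An optional
    multiplicative spoiling correction is applied to the recovered T1
    (identity when omitted).  Voxels with E1 outside (0, 1) are NaN.
    """
    s1 = np.asarray(s_low, dtype=float)
    s2 = np.asarray(s_high, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("VFA volumes must share a grid")
    if isinstance(b1, ParameterMap):
        b1 = b1.data
    b1 = 1.0 if b1 is None else np.asarray(b1, dtype=float)

    th1 = np.deg2rad(params.flip_angles_deg[0]) * b1
    th2 = np.deg2rad(params.flip_angles_deg[1]) * b1

    with np.errstate(divide="ignore", invalid="ignore"):
        x1, y1 = s1 / np.tan(th1), s1 / np.sin(th1)
        x2, y2 = s2 / np.tan(th2), s2 / np.sin(th2)
        e1 = (y2 - y1) / (x2 - x1)
        valid = np.isfinite(e1) & (e1 > 0) & (e1 < 1) & (s1 > 0) & (s2 > 0)
        if mask is not None:
            valid &= np.asarray(mask, dtype=bool)
        t1_s = np.where(valid, -params.tr_ms / 1000.0 / np.log(np.where(valid, e1, 0.5)), np.nan)
    if spoiling_correction is not None:
        t1_s = spoiling_correction(t1_s)
    r1 = np.where(valid & (t1_s > 0), 1.0 / t1_s, np.nan)
    return ParameterMap(r1, "R1", subject_id, voxel_size_mm)


def derive_r2prime(r2star: ParameterMap, r2: ParameterMap) -> ParameterMap:
    """R2' = R2* - R2, the static-field-inhomogeneity contribution.

    Negative values (possible under noise) are retained; their count is
    recorded on the returned map as ``n_negative`` for QC.
    """
    require_same_grid(r2star, r2)
    if r2star.subject_id != r2.subject_id:
        raise ValueError(
            f"subject mismatch: {r2star.subject_id!r} vs {r2.subject_id!r}"
        )
    data = r2star.data - r2.data
    out = ParameterMap(data, "R2prime", r2star.subject_id, r2star.voxel_size_mm)
    out.n_negative = int(np.sum(data < 0))  # type: ignore[attr-defined]
    return out
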