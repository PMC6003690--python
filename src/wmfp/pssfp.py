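"""T2 (R2) mapping from partially spoiled SSFP.

Two RF-spoiled gradient-echo acquisitions that differ only in the quadratic
RF-phase increment (a small one, default 1 deg, and a large one, default
20 deg) have a signal ratio that is a smooth monotone function of T2: the
small increment leaves residual transverse coherences whose weight grows with
T2, while the large increment approaches ideal spoiling.  The forward model
here is a direct Bloch steady-state simulation of the sequence over an
isochromat ensemble (quadratic RF phase schedule, per-TR gradient dephasing,
fixed assumed T1); the fitter inverts the simulated signal-ratio curve by
monotone interpolation, applies the configured T2 cap (default 150 ms), and
reports R2 = 1/T2.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .maps import ParameterMap
from .sequences import PSSFPParams

_N_ISO = 128          # isochromats across the 2*pi per-TR spoiler dephasing
_N_TR = 1536          # TRs simulated to reach the pseudo steady state
_N_AVG = 256          # trailing TRs averaged for the reported magnitude
_T2_GRID_N = 56
_T2_MIN_S, _T2_MAX_S = 0.005, 0.6
_B1_QUANT = 0.01      # B1 values are quantized to this step for table reuse


def _simulate_increment(t2_s: np.ndarray, fa_rad: np.ndarray, tr_s: float,
                        t1_s: float, incr_rad: float) -> np.ndarray:
    """Mean steady-state magnitude signal for each (T2, flip-angle) combo."""
    t2 = np.asarray(t2_s, float).ravel()
    fa = np.asarray(fa_rad, float).ravel()
    n = t2.size
    assert fa.size == n
    e1 = np.exp(-tr_s / t1_s)
    e2 = np.exp(-tr_s / t2)[:, None]
    beta = 2.0 * np.pi * (np.arange(_N_ISO) + 0.5) / _N_ISO
    cb, sb = np.cos(beta)[None, :], np.sin(beta)[None, :]
    ca, sa = np.cos(fa)[:, None], np.sin(fa)[:, None]

    mx = np.zeros((n, _N_ISO))
    my = np.zeros((n, _N_ISO))
    mz = np.ones((n, _N_ISO))
    psi = 0.0
    acc = np.zeros(n)
    n_acc = 0
    for k in range(1, _N_TR + 1):
        psi = psi + k * incr_rad
        cp, sp = np.cos(psi), np.sin(psi)
        # R = Rz(psi) Rx(alpha) Rz(-psi)
        r11 = cp * cp + sp * sp * ca
        r12 = cp * sp * (1.0 - ca)
        r13 = sp * sa
        r22 = sp * sp + cp * cp * ca
        r23 = -cp * sa
        r31 = -sp * sa
        r32 = cp * sa
        nx = r11 * mx + r12 * my + r13 * mz
        ny = r12 * mx + r22 * my + r23 * mz
        nz = r31 * mx + r32 * my + ca * mz
        if k > _N_TR - _N_AVG:
            # receiver demodulated at the RF phase
            sig_re = (nx * cp + ny * sp).mean(axis=1)
            sig_im = (-nx * sp + ny * cp).mean(axis=1)
            acc += np.hypot(sig_re, sig_im)
            n_acc += 1
        # relaxation + per-isochromat spoiler dephasing until next pulse
        tx = (nx * cb - ny * sb) * e2
        ty = (nx * sb + ny * cb) * e2
        mx, my = tx, ty
        mz = 1.0 + (nz - 1.0) * e1
    return acc / n_acc


def _params_key(params: PSSFPParams) -> tuple:
    return (params.tr_ms, params.te_ms, params.fa_deg,
            params.spoil_increments_deg, params.assumed_t1_s)


@lru_cache(maxsize=16)
def _signal_tables(params_key: tuple, b1_q: tuple[float, ...]
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(t2_grid, S_small, S_large); signal arrays are (n_b1, n_t2)."""
    tr_ms, te_ms, fa_deg, incr_deg, t1_s = params_key
    t2 = np.geomspace(_T2_MIN_S, _T2_MAX_S, _T2_GRID_N)
    b1 = np.asarray(b1_q, float)
    t2g, b1g = np.meshgrid(t2, b1)  # (n_b1, n_t2)
    fa = np.deg2rad(fa_deg) * b1g
    e_te = np.exp(-te_ms / 1000.0 / t2g)
    out = []
    for incr in incr_deg:
        s = _simulate_increment(t2g.ravel(), fa.ravel(), tr_ms / 1000.0,
                                t1_s, np.deg2rad(incr))
        out.append(s.reshape(t2g.shape) * e_te)
    return t2, out[0], out[1]


def _quantize_b1(b1: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(b1, float) / _B1_QUANT) * _B1_QUANT


def pssfp_signal_pair(t2_s: np.ndarray, params: PSSFPParams,
                      b1: np.ndarray | float = 1.0,
                      m0: np.ndarray | float = 1.0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Forward pSSFP signals at both spoil increments for given T2 (seconds)."""
    t2_s = np.asarray(t2_s, float)
    b1_arr = _quantize_b1(np.broadcast_to(np.asarray(b1, float), t2_s.shape))
    uniq = tuple(np.unique(b1_arr[np.isfinite(b1_arr)]).tolist())
    grid, s_small, s_large = _signal_tables(_params_key(params), uniq)
    out1 = np.full(t2_s.shape, np.nan)
    out2 = np.full(t2_s.shape, np.nan)
    for i, b in enumerate(uniq):
        sel = b1_arr == b
        out1[sel] = np.interp(t2_s[sel], grid, s_small[i])
        out2[sel] = np.interp(t2_s[sel], grid, s_large[i])
    return out1 * m0, out2 * m0


def fit_r2_pssfp(s_inc1: np.ndarray, s_inc2: np.ndarray, params: PSSFPParams,
                 b1: ParameterMap | np.ndarray | float | None = None,
                 mask: np.ndarray | None = None,
                 subject_id: str = "",
                 voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
                 ) -> ParameterMap:
    """Invert the pSSFP signal ratio for T2, cap it, and return R2 = 1/T2.

    ``s_inc1``/``s_inc2`` are the volumes acquired with the small and large
    RF-spoil increments.  Voxels whose ratio falls below the model's
    admissible range (or with non-positive signal) are NaN; ratios beyond the
    large-T2 end of the curve are assigned the cap.
    """
    v1 = np.asarray(s_inc1, float)
    v2 = np.asarray(s_inc2, float)
    if v1.shape != v2.shape:
        raise ValueError("pSSFP volumes must share a grid")
    if isinstance(b1, ParameterMap):
        b1 = b1.data
    b1_arr = np.ones_like(v1) if b1 is None else np.broadcast_to(
        np.asarray(b1, float), v1.shape)

    with np.errstate(divide="ignore", invalid="ignore"):
        robs = v1 / v2
    valid = np.isfinite(robs) & (v1 > 0) & (v2 > 0) & np.isfinite(b1_arr)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)

    b1_q = _quantize_b1(np.where(valid, b1_arr, 1.0))
    uniq = tuple(np.unique(b1_q[valid]).tolist()) if valid.any() else (1.0,)
    grid, s_small, s_large = _signal_tables(_params_key(params), uniq)

    t2 = np.full(v1.shape, np.nan)
    cap_s = params.t2_cap_ms / 1000.0
    for i, b in enumerate(uniq):
        curve = s_small[i] / s_large[i]  # monotone increasing in T2
        sel = valid & (b1_q == b)
        r = robs[sel]
        lo = curve[0] * (1.0 - 1e-6)
        t2_v = np.interp(r, curve, grid)
        t2_v = np.where(r < lo, np.nan, t2_v)
        t2_v = np.where(r >= curve[-1], cap_s, t2_v)
        t2[sel] = t2_v
    t2 = np.minimum(t2, cap_s)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(t2 > 0, 1.0 / t2, np.nan)
    return ParameterMap(r2, "R2", subject_id, voxel_size_mm)
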