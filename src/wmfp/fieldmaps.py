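"""Field-map estimation: transmit B1+ from AFI and B0 from a phase difference."""

from __future__ import annotations

import numpy as np

from .maps import ParameterMap
from .sequences import AFIParams, MTParams


def afi_signal_ratio(b1: np.ndarray | float, params: AFIParams) -> np.ndarray:
    """Forward AFI signal ratio r = S2/S1 in the short-TR regime.

    With TR1, TR2 << T1 the dual-TR spoiled GRE pair gives
    r = (1 + n cos(theta)) / (n + cos(theta)), n = TR2/TR1,
    theta the actual flip angle (nominal angle scaled by B1).
    """
    theta = np.deg2rad(params.nominal_fa_deg) * np.asarray(b1, dtype=float)
    c = np.cos(theta)
    n = params.n
    return (1.0 + n * c) / (n + c)


def fit_b1_afi(s1: np.ndarray, s2: np.ndarray, params: AFIParams,
               subject_id: str = "",
               voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
               ) -> ParameterMap:
    """Invert the AFI ratio for the relative transmit field B1.

    cos(theta_actual) = (r n - 1) / (n - r); B1 = theta_actual/theta_nominal.
    Voxels with r >= n, cos outside [-1, 1], or non-positive signal are NaN.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("AFI volumes must share a grid")
    n = params.n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = s2 / s1
        cos_th = (r * n - 1.0) / (n - r)
    valid = (s1 > 0) & (s2 > 0) & np.isfinite(cos_th) & (r < n)
    valid &= (cos_th >= -1.0) & (cos_th <= 1.0)
    theta = np.arccos(np.clip(cos_th, -1.0, 1.0))
    b1 = np.where(valid, theta / np.deg2rad(params.nominal_fa_deg), np.nan)
    return ParameterMap(b1, "B1", subject_id, voxel_size_mm)


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase to the (-pi, pi] convention."""
    wrapped = np.mod(-np.asarray(phi, dtype=float) + np.pi, 2.0 * np.pi)
    return -(wrapped - np.pi)


def fit_b0_from_phase(phase_te1: np.ndarray, phase_te2: np.ndarray,
                      params: MTParams,
                      subject_id: str = "",
                      voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
                      ) -> ParameterMap:
    """Off-resonance B0 (Hz) from the wrapped two-echo phase difference."""
    te1, te2 = params.te_pair_ms
    dte_s = (te2 - te1) / 1000.0
    if dte_s == 0:
        raise ValueError("echo spacing must be non-zero for B0 mapping")
    dphi = wrap_phase(np.asarray(phase_te2, float) - np.asarray(phase_te1, float))
    b0 = dphi / (2.0 * np.pi * dte_s)
    return ParameterMap(b0, "B0", subject_id, voxel_size_mm)
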