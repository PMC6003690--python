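"""Single-point macromolecular proton fraction (MPF) mapping.

Constrained two-pool pulsed magnetization-transfer model: a free water pool
and a macromolecular bound pool coupled by chemical exchange.  The off-
resonant shaped saturation pulse is treated in the continuous-wave power
equivalent approximation (average saturation rates over the pulse), the bound
pool absorbs with a super-Lorentzian lineshape and the free pool with a
Lorentzian, and the longitudinal two-pool dynamics over one TR are solved
exactly with 2x2 matrix exponentials.  With every nuisance parameter
constrained (T2b, T2f/T1, the exchange constant, and R1f = R1b = R1), the
normalized signal S_MT/S_ref depends on the bound-pool fraction f alone and
is inverted per voxel by bracketed root-finding on f in [0, 0.35].
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss

from .maps import ParameterMap
from .sequences import MTParams, TwoPoolConstraints

_GAUSS_TRUNC_SD = 3.0  # Gaussian pulse truncated at +/- 3 sigma

# Gauss-Legendre nodes for the super-Lorentzian lineshape integral.
_SL_NODES, _SL_WEIGHTS = leggauss(512)


def super_lorentzian(delta_hz: np.ndarray | float, t2b_s: float) -> np.ndarray:
    """Super-Lorentzian absorption lineshape g(delta) in seconds.

    g(d) = sqrt(2/pi) * T2b * int_0^{pi/2} sin(t) / |3cos^2 t - 1|
           * exp(-2 (2 pi d T2b / (3 cos^2 t - 1))^2) dt
    """
    delta = np.atleast_1d(np.asarray(delta_hz, dtype=float))
    theta = 0.25 * np.pi * (_SL_NODES + 1.0)  # map [-1,1] -> [0, pi/2]
    w = 0.25 * np.pi * _SL_WEIGHTS
    u = 3.0 * np.cos(theta) ** 2 - 1.0
    x = 2.0 * np.pi * delta[..., None] * t2b_s
    with np.errstate(divide="ignore", over="ignore"):
        integrand = np.exp(-2.0 * (x / u) ** 2) / np.abs(u)
    vals = (integrand * (np.sin(theta) * w)).sum(axis=-1)
    out = np.sqrt(2.0 / np.pi) * t2b_s * vals
    return out if np.ndim(delta_hz) else float(out[0])


def _gaussian_pulse_w1rms_sq(flip_rad: np.ndarray | float, duration_s: float
                             ) -> np.ndarray:
    """Mean-square RF amplitude (rad^2/s^2) of a truncated Gaussian pulse."""
    sigma = duration_s / (2.0 * _GAUSS_TRUNC_SD)
    from scipy.special import erf
    i1 = np.sqrt(2.0 * np.pi) * erf(_GAUSS_TRUNC_SD / np.sqrt(2.0))  # int shape
    i2 = np.sqrt(np.pi) * erf(_GAUSS_TRUNC_SD)  # int shape^2
    w1_peak = np.asarray(flip_rad, dtype=float) / (sigma * i1)
    return w1_peak ** 2 * (sigma * i2 / duration_s)


def _expm2(a11, a12, a21, a22, t):
    """exp(A t) for 2x2 matrices with real distinct eigenvalues, elementwise."""
    tr = a11 + a22
    det = a11 * a22 - a12 * a21
    disc = np.sqrt(np.maximum(tr * tr - 4.0 * det, 1e-30))
    l1 = 0.5 * (tr + disc)
    l2 = 0.5 * (tr - disc)
    e1 = np.exp(l1 * t)
    e2 = np.exp(l2 * t)
    # exp(At) = e1 (A - l2 I)/(l1 - l2) + e2 (A - l1 I)/(l2 - l1)
    d = l1 - l2
    p11 = (e1 * (a11 - l2) - e2 * (a11 - l1)) / d
    p12 = (e1 - e2) * a12 / d
    p21 = (e1 - e2) * a21 / d
    p22 = (e1 * (a22 - l2) - e2 * (a22 - l1)) / d
    return p11, p12, p21, p22


def _affine_interval(r1f, r1b, kfb, kbf, wf, wb, m0f, m0b, t):
    """Evolution map M -> P M + q over an interval of coupled relaxation
    (+ optional saturation rates wf, wb)."""
    a11 = -(r1f + kfb + wf)
    a12 = kbf
    a21 = kfb
    a22 = -(r1b + kbf + wb)
    b1 = r1f * m0f
    b2 = r1b * m0b
    p11, p12, p21, p22 = _expm2(a11, a12, a21, a22, t)
    # q = (P - I) A^-1 b
    det = a11 * a22 - a12 * a21
    ai_b1 = (a22 * b1 - a12 * b2) / det
    ai_b2 = (-a21 * b1 + a11 * b2) / det
    q1 = (p11 - 1.0) * ai_b1 + p12 * ai_b2
    q2 = p21 * ai_b1 + (p22 - 1.0) * ai_b2
    return (p11, p12, p21, p22), (q1, q2)


def mt_signal_ratio(f: np.ndarray | float, r1: np.ndarray | float,
                    params: MTParams, constraints: TwoPoolConstraints,
                    b0_hz: np.ndarray | float = 0.0,
                    b1: np.ndarray | float = 1.0) -> np.ndarray:
    """Forward model: normalized steady-state signal S_MT / S_ref.

    All array arguments broadcast; f is the bound-pool fraction (0..~0.35),
    r1 in s^-1, b0 in Hz, b1 relative.
    """
    f = np.asarray(f, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    b0 = np.asarray(b0_hz, dtype=float)
    b1v = np.asarray(b1, dtype=float)
    f, r1, b0, b1v = np.broadcast_arrays(f, r1, b0, b1v)

    t1 = 1.0 / np.maximum(r1, 1e-6)
    t2f = constraints.t2f_over_t1 * t1
    t2b = constraints.t2b_us * 1e-6
    kbf = constraints.k_combined  # bound -> free rate, k(1-f)/f by balance
    with np.errstate(divide="ignore", invalid="ignore"):
        kfb = np.where(f < 1.0, kbf * f / np.maximum(1.0 - f, 1e-9), 0.0)
    m0f = 1.0 - f
    m0b = f

    tp = params.pulse_duration_ms / 1000.0
    tr = params.tr_ms / 1000.0
    delta = params.offset_hz - b0  # effective offset seen by the pulse
    w1sq = _gaussian_pulse_w1rms_sq(np.deg2rad(params.fa_mt_deg) * b1v, tp)
    wb = np.pi * w1sq * super_lorentzian(delta, t2b)
    wf = w1sq * t2f / (1.0 + (2.0 * np.pi * delta * t2f) ** 2)

    cos_r = np.cos(np.deg2rad(params.readout_fa_deg) * b1v)

    def steady_mzf(wf_, wb_):
        sat_p, sat_q = _affine_interval(r1, r1, kfb, kbf, wf_, wb_, m0f, m0b, tp)
        rel_p, rel_q = _affine_interval(r1, r1, kfb, kbf, 0.0, 0.0, m0f, m0b, tr - tp)
        # readout: Mzf *= cos_r (bound pool untouched)
        # full cycle P = rel * readout * sat
        s11, s12, s21, s22 = sat_p
        r11, r12, r21, r22 = rel_p
        m11, m12 = cos_r * s11, cos_r * s12
        m21, m22 = s21, s22
        mq1, mq2 = cos_r * sat_q[0], sat_q[1]
        p11 = r11 * m11 + r12 * m21
        p12 = r11 * m12 + r12 * m22
        p21 = r21 * m11 + r22 * m21
        p22 = r21 * m12 + r22 * m22
        q1 = r11 * mq1 + r12 * mq2 + rel_q[0]
        q2 = r21 * mq1 + r22 * mq2 + rel_q[1]
        # fixed point of M -> P M + q
        d11, d12, d21, d22 = 1.0 - p11, -p12, -p21, 1.0 - p22
        det = d11 * d22 - d12 * d21
        m1 = (d22 * q1 - d12 * q2) / det
        m2 = (-d21 * q1 + d11 * q2) / det
        # longitudinal free-pool magnetization at the readout instant
        return s11 * m1 + s12 * m2 + sat_q[0]

    zeros = np.zeros_like(r1)
    s_mt = steady_mzf(wf, wb)
    s_ref = steady_mzf(zeros, zeros)
    return s_mt / s_ref


def fit_mpf_single_point(mt_img: np.ndarray, ref_img: np.ndarray,
                         r1: ParameterMap, b0: ParameterMap | None,
                         b1: ParameterMap | None, params: MTParams,
                         constraints: TwoPoolConstraints | None = None,
                         mask: np.ndarray | None = None,
                         f_max: float = 0.35, tol: float = 1e-6,
                         ) -> ParameterMap:
    """Single-point MPF fit: invert S_MT/S_ref for the bound-pool fraction.

    Bisection on f in [0, f_max] (the model ratio decreases with f) followed
    by one secant refinement; MPF = 100 f.  Voxels whose normalized ratio is
    outside (0, 1.2], whose R1 is invalid, or whose residual does not change
    sign on the bracket are NaN.
    """
    constraints = constraints or TwoPoolConstraints()
    mt_v = np.asarray(mt_img, dtype=float)
    ref_v = np.asarray(ref_img, dtype=float)
    if mt_v.shape != ref_v.shape or mt_v.shape != r1.data.shape:
        raise ValueError("MT, reference and R1 volumes must share a grid")
    b0_v = b0.data if b0 is not None else np.zeros_like(mt_v)
    b1_v = b1.data if b1 is not None else np.ones_like(mt_v)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mt_v / ref_v
    valid = np.isfinite(ratio) & (ratio > 0) & (ratio <= 1.2)
    valid &= np.isfinite(r1.data) & (r1.data > 0)
    valid &= np.isfinite(b0_v) & np.isfinite(b1_v) & (b1_v > 0)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)

    idx = np.flatnonzero(valid.ravel())
    out = np.full(mt_v.size, np.nan)
    if idx.size:
        robs = ratio.ravel()[idx]
        r1_f = r1.data.ravel()[idx]
        b0_f = b0_v.ravel()[idx]
        b1_f = b1_v.ravel()[idx]

        def resid(f):
            return mt_signal_ratio(f, r1_f, params, constraints, b0_f, b1_f) - robs

        lo = np.zeros(idx.size)
        hi = np.full(idx.size, f_max)
        r_lo = resid(lo)
        r_hi = resid(hi)
        bracketed = (r_lo >= 0) & (r_hi <= 0)
        n_iter = int(np.ceil(np.log2(f_max / tol)))
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            r_mid = resid(mid)
            take_hi = r_mid >= 0
            lo = np.where(take_hi, mid, lo)
            r_lo = np.where(take_hi, r_mid, r_lo)
            hi = np.where(take_hi, hi, mid)
            r_hi = np.where(take_hi, r_hi, r_mid)
        # secant refinement inside the final bracket
        denom = r_hi - r_lo
        frac = np.where(np.abs(denom) > 0, r_lo / np.where(denom == 0, 1.0, denom), 0.5)
        f_est = lo - frac * (hi - lo)
        f_est = np.clip(f_est, 0.0, f_max)
        out[idx] = np.where(bracketed, 100.0 * f_est, np.nan)

    return ParameterMap(out.reshape(mt_v.shape), "MPF",
                        r1.subject_id, r1.voxel_size_mm)
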