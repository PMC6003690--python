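"""Acquisition descriptors for the multi-parametric protocol.

Each dataclass carries the pulse-sequence parameters a forward model / fitter
needs.  Defaults reproduce a 3 T multi-parametric session: an 8-echo
gradient-echo stack for R2*, a two-angle SPGR pair for R1 (VFA), an AFI pair
for the transmit field B1+, an MT-weighted/reference pair (with a two-echo
phase difference for B0) for the macromolecular proton fraction, a
partially-spoiled SSFP pair for R2, and a 20-direction b = 0/1500 s/mm2 DTI
scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _paper_like_directions(n: int = 20, seed: int = 7) -> np.ndarray:
    """A deterministic, well-spread gradient scheme (spherical Fibonacci)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (1.0 + np.sqrt(5.0))
    theta = golden * i
    dirs = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


@dataclass
class MGREParams:
    """Multi-echo gradient echo (R2* mapping)."""

    echo_times_ms: tuple[float, ...] = tuple(2.21 + 3.7 * k for k in range(8))

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times_ms, dtype=float)
        if te.size < 3:
            raise ValueError("R2* fitting needs at least 3 echoes")
        if not np.all(np.diff(te) > 0):
            raise ValueError("echo times must be strictly increasing")


@dataclass
class VFAParams:
    """Two-angle variable flip angle SPGR (R1 mapping)."""

    tr_ms: float = 20.0
    flip_angles_deg: tuple[float, float] = (4.0, 25.0)

    def __post_init__(self) -> None:
        if len(self.flip_angles_deg) != 2:
            raise ValueError("VFA uses exactly two flip angles")
        if self.tr_ms <= 0:
            raise ValueError("TR must be positive")


@dataclass
class AFIParams:
    """Actual flip-angle imaging (B1+ mapping), TR2 = n * TR1."""

    tr1_ms: float = 18.5
    tr2_ms: float = 92.5
    nominal_fa_deg: float = 60.0

    def __post_init__(self) -> None:
        n = self.tr2_ms / self.tr1_ms
        if abs(n - round(n)) > 1e-9 or round(n) < 2:
            raise ValueError("AFI requires TR2/TR1 integer >= 2")

    @property
    def n(self) -> float:
        return self.tr2_ms / self.tr1_ms


@dataclass
class MTParams:
    """MT-weighted GRE (single-point MPF mapping) and its B0 phase pair."""

    pulse_duration_ms: float = 12.0
    pulse_shape: str = "gaussian"
    fa_mt_deg: float = 560.0
    offset_hz: float = 6000.0
    tr_ms: float = 28.0
    readout_fa_deg: float = 6.0
    te_pair_ms: tuple[float, float] = (2.25, 6.90)


@dataclass
class PSSFPParams:
    """Partially spoiled SSFP (R2 mapping from two RF-spoil increments)."""

    tr_ms: float = 7.0
    te_ms: float = 3.0
    fa_deg: float = 60.0
    spoil_increments_deg: tuple[float, float] = (1.0, 20.0)
    assumed_t1_s: float = 1.25
    t2_cap_ms: float = 150.0

    def __post_init__(self) -> None:
        if len(self.spoil_increments_deg) != 2:
            raise ValueError("pSSFP uses exactly two spoil increments")


@dataclass
class DTIParams:
    """Two-shell (b = 0 and b = 1500 s/mm2) diffusion scheme."""

    bvals: np.ndarray = field(
        default_factory=lambda: np.concatenate([[0.0], np.full(20, 1500.0)])
    )
    bvecs: np.ndarray = field(
        default_factory=lambda: np.vstack([[0.0, 0.0, 0.0], _paper_like_directions()])
    )

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError("bvecs must be (n, 3) matching bvals")
        nz = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[nz], axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("b-vectors must be unit-norm where b > 0")


@dataclass
class TwoPoolConstraints:
    """Constrained nuisance parameters of the two-pool MT model.

    The single-point MPF method fixes every model parameter except the bound
    pool fraction f: the bound-pool transverse relaxation time T2b, the ratio
    T2f/T1 of the free pool, the combined exchange constant k(1-f)/f (the
    bound-to-free rate), and the coupling R1f = R1b = R1.
    """

    t2b_us: float = 9.7
    t2f_over_t1: float = 0.022
    k_combined: float = 19.0
    r1_coupling: bool = True

    def __post_init__(self) -> None:
        if min(self.t2b_us, self.t2f_over_t1, self.k_combined) <= 0:
            raise ValueError("two-pool constraints must be strictly positive")
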