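"""Diffusion tensor fitting and scalar metrics (AD, RD, ADC, FA).

Log-linear least-squares fit of the six-component symmetric tensor; scalars
from eigenvalues sorted descending, with negative eigenvalues clipped at 0
before scalar computation.  Diffusivities are reported in um^2/s (b-values in
s/mm2, so the fitted tensor in mm2/s is scaled by 1e6).
"""

from __future__ import annotations

import numpy as np

from .maps import ParameterMap
from .sequences import DTIParams

_MM2S_TO_UM2S = 1.0e6


def _design_matrix(params: DTIParams) -> np.ndarray:
    b = params.bvals
    g = params.bvecs
    # ln S = ln S0 - b g^T D g ; D packed as (xx, yy, zz, xy, xz, yz)
    return np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2.0 * b * g[:, 0] * g[:, 1],
        -2.0 * b * g[:, 0] * g[:, 2],
        -2.0 * b * g[:, 1] * g[:, 2],
    ])


def tensor_from_eigen(eigvals_um2s: np.ndarray, eigvecs: np.ndarray | None = None
                      ) -> np.ndarray:
    """Assemble a 3x3 tensor (mm2/s) from eigenvalues in um^2/s."""
    lam = np.asarray(eigvals_um2s, float) / _MM2S_TO_UM2S
    if eigvecs is None:
        eigvecs = np.eye(3)
    return eigvecs @ np.diag(lam) @ eigvecs.T


def dwi_signal(s0: np.ndarray, tensor_mm2s: np.ndarray, params: DTIParams
               ) -> np.ndarray:
    """Forward DWI magnitudes, volumes along the last axis."""
    b = params.bvals
    g = params.bvecs
    bq = b * np.einsum("ni,ij,nj->n", g, np.asarray(tensor_mm2s, float), g)
    return np.asarray(s0, float)[..., None] * np.exp(-bq)


def fit_dti_tensor(dwi: np.ndarray, params: DTIParams,
                   mask: np.ndarray | None = None,
                   subject_id: str = "",
                   voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
                   ) -> dict[str, ParameterMap]:
    """Fit the diffusion tensor and return the AD/RD/ADC/FA scalar maps.

    Requires at least one b = 0 volume and six non-collinear diffusion
    directions; a rank-deficient design is rejected.
    """
    data = np.asarray(dwi, float)
    if data.ndim != 4 or data.shape[-1] != params.bvals.size:
        raise ValueError("dwi must be 4-D with one volume per b-value entry")
    if np.sum(params.bvals == 0) < 1 or np.sum(params.bvals > 0) < 6:
        raise ValueError("need >=1 b=0 volume and >=6 diffusion directions")
    design = _design_matrix(params)
    if np.linalg.matrix_rank(design) < 7:
        raise ValueError("gradient scheme is rank-deficient (collinear directions)")

    valid = np.all(data > 0, axis=-1)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)

    shape = data.shape[:3]
    flat = data.reshape(-1, data.shape[-1])
    idx = np.flatnonzero(valid.ravel())
    coef = np.full((flat.shape[0], 7), np.nan)
    if idx.size:
        logs = np.log(flat[idx])
        sol, *_ = np.linalg.lstsq(design, logs.T, rcond=None)
        coef[idx] = sol.T

    d = coef[:, 1:]
    tens = np.empty((flat.shape[0], 3, 3))
    tens[:, 0, 0] = d[:, 0]
    tens[:, 1, 1] = d[:, 1]
    tens[:, 2, 2] = d[:, 2]
    tens[:, 0, 1] = tens[:, 1, 0] = d[:, 3]
    tens[:, 0, 2] = tens[:, 2, 0] = d[:, 4]
    tens[:, 1, 2] = tens[:, 2, 1] = d[:, 5]

    lam = np.full((flat.shape[0], 3), np.nan)
    if idx.size:
        lam[idx] = np.linalg.eigvalsh(tens[idx])[:, ::-1]  # descending
    lam_c = np.clip(lam, 0.0, None) * _MM2S_TO_UM2S

    ad = lam_c[:, 0]
    rd = 0.5 * (lam_c[:, 1] + lam_c[:, 2])
    adc = lam_c.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = ((lam_c - adc[:, None]) ** 2).sum(axis=1)
        den = (lam_c ** 2).sum(axis=1)
        fa = np.sqrt(1.5) * np.sqrt(np.where(den > 0, num / np.where(den == 0, 1, den), 0.0))
    fa = np.where(np.isfinite(lam_c[:, 0]), fa, np.nan)

    mk = lambda a, pid: ParameterMap(a.reshape(shape), pid, subject_id, voxel_size_mm)
    return {"AD": mk(ad, "AD"), "RD": mk(rd, "RD"),
            "ADC": mk(adc, "ADC"), "FA": mk(fa, "FA")}
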