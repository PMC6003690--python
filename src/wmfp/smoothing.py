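"""Isotropic Gaussian smoothing of parameter maps (FWHM in mm)."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


def smooth_volume(pmap, fwhm_mm: float):
    """Gaussian-smooth a :class:`ParameterMap` with an isotropic kernel.

    sigma_mm = fwhm / 2.3548 per axis, converted to voxels with the map's
    voxel size.  NaN voxels are excluded by normalized convolution (smoothing
    of the finite values only); fwhm = 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return pmap.with_data(pmap.data.copy())
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / v for v in pmap.voxel_size_mm]
    data = pmap.data
    finite = np.isfinite(data)
    filled = np.where(finite, data, 0.0)
    num = gaussian_filter(filled, sigma_vox, mode="nearest", truncate=8.0)
    if finite.all():
        out = num
    else:
        den = gaussian_filter(finite.astype(float), sigma_vox,
                              mode="nearest", truncate=8.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(finite, num / np.where(den > 0, den, 1.0), np.nan)
    return pmap.with_data(out)


def smooth_subject_maps(records, brain_mask, fwhm_mm: float = 5.0):
    """Smooth every analysis map of every record within the brain mask.

    Voxels outside the mask are undefined tissue, not zero signal, so they
    are excluded from the kernel support (normalized convolution) rather
    than diluting boundary voxels.  Returns new records; tissue probability
    maps are left unsmoothed.
    """
    import copy

    mask = np.asarray(brain_mask, dtype=bool)
    out = []
    for rec in records:
        new = copy.copy(rec)
        new.maps = {}
        for p, m in rec.maps.items():
            masked = m.with_data(np.where(mask, m.data, np.nan))
            new.maps[p] = smooth_volume(masked, fwhm_mm)
        out.append(new)
    return out
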