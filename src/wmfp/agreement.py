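"""Fleiss' kappa: chance-corrected agreement among R >= 2 raters.

Here the raters are ICA decompositions at different model orders and the
items are analysis-mask voxels, rated subtype / not-subtype.
"""

from __future__ import annotations

import warnings

import numpy as np


def fleiss_kappa(binary_maps: np.ndarray) -> float:
    """Fleiss' kappa for a (raters, items) stack of binary ratings.

    kappa = (P_bar - P_e) / (1 - P_e) with P_bar the mean per-item pairwise
    agreement and P_e the chance agreement from the marginal category
    frequencies.  If agreement is perfect everywhere the degenerate
    P_e = 1 case returns 1; degenerate-but-imperfect input returns NaN with a
    warning.
    """
    ratings = np.asarray(binary_maps)
    if ratings.ndim != 2:
        ratings = ratings.reshape(ratings.shape[0], -1)
    r, v = ratings.shape
    if r < 2:
        raise ValueError("Fleiss' kappa needs at least 2 raters")
    n1 = ratings.sum(axis=0).astype(float)  # per-item count of category 1
    n0 = r - n1
    p_item = (n1 * (n1 - 1) + n0 * (n0 - 1)) / (r * (r - 1))
    p_bar = p_item.mean()
    p1 = n1.sum() / (r * v)
    p_e = p1 ** 2 + (1.0 - p1) ** 2
    if p_e >= 1.0 - 1e-15:
        if p_bar >= 1.0 - 1e-15:
            return 1.0
        warnings.warn("degenerate marginals (P_e = 1) with imperfect "
                      "agreement; kappa undefined", RuntimeWarning)
        return float("nan")
    return float((p_bar - p_e) / (1.0 - p_e))
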