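"""Reference fingerprints of the three white-matter subtypes.

Published in-vivo reference values (population mean and between-subject SD)
for the track-like (t-WM), frontal-subcortical (f-WM) and central-subcortical
(c-WM) white-matter subtypes, over the seven analysis parameters.  These
values parameterize the default synthetic phantom and anchor several oracle
tests.  Units: relaxation rates s^-1, diffusivities um^2/s, susceptibility
ppb, MPF percent.
"""

from __future__ import annotations

import numpy as np

from .maps import ANALYSIS_PARAMS

#: Canonical subtype order used throughout the package.
SUBTYPES: tuple[str, ...] = ("t-WM", "f-WM", "c-WM")

#: Mean fingerprint of each subtype over the analysis parameters
#: (rows follow SUBTYPES, columns follow ANALYSIS_PARAMS).
SUBTYPE_FINGERPRINTS: dict[str, dict[str, float]] = {
    "t-WM": {"R1": 1.01, "R2": 16.6, "AD": 1066.0, "RD": 441.0,
             "chi_m": -10.4, "R2star": 21.7, "MPF": 12.4},
    "f-WM": {"R1": 1.07, "R2": 17.9, "AD": 863.0, "RD": 497.0,
             "chi_m": -1.3, "R2star": 21.1, "MPF": 13.8},
    "c-WM": {"R1": 0.98, "R2": 17.2, "AD": 859.0, "RD": 482.0,
             "chi_m": -6.3, "R2star": 20.4, "MPF": 12.8},
}

#: Between-subject SD of each subtype's fingerprint.
SUBTYPE_SD: dict[str, dict[str, float]] = {
    "t-WM": {"R1": 0.05, "R2": 1.1, "AD": 40.0, "RD": 31.0,
             "chi_m": 8.7, "R2star": 0.8, "MPF": 0.5},
    "f-WM": {"R1": 0.05, "R2": 0.6, "AD": 22.0, "RD": 26.0,
             "chi_m": 2.7, "R2star": 0.6, "MPF": 0.4},
    "c-WM": {"R1": 0.05, "R2": 0.8, "AD": 26.0, "RD": 31.0,
             "chi_m": 10.9, "R2star": 0.8, "MPF": 0.4},
}

#: Grey-matter-like baseline values for tissue outside the subtype territories.
GM_BASELINE: dict[str, float] = {
    "R1": 0.62, "R2": 12.5, "AD": 950.0, "RD": 750.0,
    "chi_m": 10.0, "R2star": 15.5, "MPF": 7.0,
}


def fingerprint_matrix() -> np.ndarray:
    """(3 subtypes x 7 parameters) mean-fingerprint matrix in canonical order."""
    return np.array(
        [[SUBTYPE_FINGERPRINTS[s][p] for p in ANALYSIS_PARAMS] for s in SUBTYPES]
    )


def subject_sd_vector() -> np.ndarray:
    """Per-parameter between-subject SD, averaged over the three subtypes."""
    return np.array(
        [np.mean([SUBTYPE_SD[s][p] for s in SUBTYPES]) for p in ANALYSIS_PARAMS]
    )


def baseline_vector() -> np.ndarray:
    return np.array([GM_BASELINE[p] for p in ANALYSIS_PARAMS])
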