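"""Containers for quantitative parameter maps and per-subject map sets.

A :class:`ParameterMap` is a single 3-D quantitative volume (one parameter of
one subject) together with the grid metadata needed to compare maps across
subjects.  A :class:`SubjectRecord` bundles a subject's (possibly incomplete)
map set with tissue probability maps and covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

#: Recognised parameter identifiers and their units.
PARAM_UNITS: Mapping[str, str] = {
    "R1": "s^-1",
    "R2": "s^-1",
    "R2star": "s^-1",
    "R2prime": "s^-1",
    "AD": "um^2/s",
    "RD": "um^2/s",
    "ADC": "um^2/s",
    "FA": "1",
    "chi_m": "ppb",
    "MPF": "percent",
    "B1": "1",
    "B0": "Hz",
    "pWM": "1",
    "pGM": "1",
    "S0": "a.u.",
}

#: The seven parameters entering the group decomposition, in canonical order.
ANALYSIS_PARAMS: tuple[str, ...] = ("R1", "R2", "AD", "RD", "chi_m", "R2star", "MPF")

#: Derived metrics extracted from subtype ROIs but not decomposed.
DERIVED_PARAMS: tuple[str, ...] = ("ADC", "FA", "R2prime", "pWM")


@dataclass
class ParameterMap:
    """One quantitative 3-D volume on a regular voxel grid."""

    data: np.ndarray
    param_id: str
    subject_id: str = ""
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"ParameterMap data must be 3-D, got {self.data.ndim}-D")
        if self.param_id not in PARAM_UNITS:
            raise ValueError(f"unknown param_id {self.param_id!r}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)  # type: ignore[assignment]
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be three positive lengths")

    @property
    def units(self) -> str:
        return PARAM_UNITS[self.param_id]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "ParameterMap") -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size_mm, other.voxel_size_mm
        )

    def with_data(self, data: np.ndarray, param_id: str | None = None) -> "ParameterMap":
        return replace(self, data=np.asarray(data, dtype=np.float64),
                       param_id=param_id or self.param_id)


def require_same_grid(*maps: ParameterMap) -> None:
    """Raise ``ValueError`` naming the offending maps if grids differ."""
    ref = maps[0]
    for m in maps[1:]:
        if not ref.same_grid(m):
            raise ValueError(
                f"grid mismatch between {ref.param_id} ({ref.shape}, "
                f"{ref.voxel_size_mm}) and {m.param_id} ({m.shape}, {m.voxel_size_mm})"
                f" for subject {ref.subject_id!r}/{m.subject_id!r}"
            )


@dataclass
class SubjectRecord:
    """A subject's quantitative map set plus tissue probabilities and covariates.

    ``maps`` may be incomplete (missing acquisitions); downstream code treats a
    missing key as a missing map, never as zeros.
    """

    subject_id: str
    maps: dict[str, ParameterMap] = field(default_factory=dict)
    p_wm: ParameterMap | None = None
    p_gm: ParameterMap | None = None
    age: float = float("nan")
    gender: str = ""  # "M" or "F"

    def available_params(self) -> list[str]:
        return [p for p in ANALYSIS_PARAMS if p in self.maps]

    def n_analysis_maps(self) -> int:
        return len(self.available_params())

    @property
    def usable_for_decomposition(self) -> bool:
        """A subject with no analysis map at all cannot enter the group matrix."""
        return self.n_analysis_maps() > 0

    def validate_grids(self) -> None:
        present = [m for m in self.maps.values()]
        if self.p_wm is not None:
            present.append(self.p_wm)
        if self.p_gm is not None:
            present.append(self.p_gm)
        if len(present) > 1:
            require_same_grid(*present)
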