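"""Volume and table I/O (NIfTI-1 via nibabel, TSV via pandas)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .maps import ParameterMap


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    """Read a NIfTI-1 volume; returns (data, voxel_size_mm, affine).

    The affine must be orthogonal (axis-aligned up to sign) to a small
    tolerance — oblique acquisitions are not resampled here.
    """
    img = nib.load(str(path))
    affine = img.affine
    rot = affine[:3, :3]
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    ortho = rot / np.where(zooms == 0, 1.0, zooms)
    if not np.allclose(np.abs(ortho) @ np.abs(ortho).T, np.eye(3), atol=1e-3):
        raise ValueError(f"{path}: affine is not orthogonal")
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    return data, tuple(zooms), affine


def write_volume(data: np.ndarray, path: str | Path,
                 voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
                 affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_zooms(voxel_size_mm)
    nib.save(img, str(path))
    return path


def read_parameter_map(path: str | Path, param_id: str, subject_id: str = ""
                       ) -> ParameterMap:
    data, zooms, _ = read_volume(path)
    return ParameterMap(data, param_id, subject_id, zooms)


def write_parameter_map(pmap: ParameterMap, path: str | Path) -> Path:
    return write_volume(pmap.data, path, pmap.voxel_size_mm)


def check_consistent_grids(paths_maps: dict[str, ParameterMap]) -> None:
    """Hard error naming both files on any shape/voxel mismatch."""
    items = list(paths_maps.items())
    for i in range(1, len(items)):
        ref_name, ref = items[0]
        name, m = items[i]
        if not ref.same_grid(m):
            raise ValueError(
                f"grid mismatch: {ref_name} has {ref.shape}@{ref.voxel_size_mm} "
                f"but {name} has {m.shape}@{m.voxel_size_mm}")


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as TSV with NA for missing cells."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read and validate a subject covariate table (subject_id, age, gender)."""
    table = read_table(path)
    required = {"subject_id", "age", "gender"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"covariate table lacks columns: {sorted(missing)}")
    dup = table["subject_id"][table["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject id(s): {sorted(set(dup))}")
    for i, v in enumerate(table["age"]):
        if pd.notna(v):
            try:
                float(v)
            except (TypeError, ValueError):
                raise ValueError(f"non-numeric age {v!r} in row {i + 1}") from None
    table["age"] = table["age"].astype(float)
    bad = table["gender"].dropna()[~table["gender"].dropna().isin(["M", "F"])]
    if len(bad):
        raise ValueError(f"gender must be M or F, got {sorted(set(bad))}")
    return table
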