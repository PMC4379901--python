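"""Volumetric and tabular I/O with strict grid conventions.

All volumes are carried in memory as :class:`VolumeGrid` / :class:`SeriesGrid`
objects: a float64 lattice plus a 4x4 voxel-to-world affine (mm).  Voxel
indexing is 0-based; the world coordinate of voxel (i, j, k) is
``affine @ (i, j, k, 1)``.  No resampling or reorientation ever happens
implicitly — grids that do not match are an error, because wavelet fusion and
voxelwise statistics require strict voxel correspondence.

On disk, volumes are NIfTI-1 (optionally gzipped) stored as float32;
computation is always float64.  Timecourses and subject tables are TSV.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "SeriesGrid",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "read_series",
    "write_series",
    "read_timecourses",
    "write_timecourses",
    "read_subjects",
]


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got shape {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine upper-left 3x3 block is singular")
    return affine


@dataclass
class VolumeGrid:
    """A 3-D scalar lattice with a voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeGrid expects 3-D data, got {self.data.ndim}-D")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge lengths (mm) of a voxel along each axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def voxel_to_world(self, ijk) -> np.ndarray:
        """World (mm) coordinates of voxel index/indices ``ijk``."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        homog = np.column_stack([ijk, np.ones(len(ijk))])
        world = homog @ self.affine.T
        return world[:, :3].squeeze()

    def same_grid(self, other: "VolumeGrid | SeriesGrid", atol: float = 1e-4) -> bool:
        return self.shape == tuple(other.shape[:3]) and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class SeriesGrid:
    """A 4-D lattice (x, y, z, t) sharing VolumeGrid's spatial conventions."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    t_r: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"SeriesGrid expects 4-D data, got {self.data.ndim}-D")
        if self.data.shape[3] < 1:
            raise ValueError("series must have at least one timepoint")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def volume(self, t: int) -> VolumeGrid:
        return VolumeGrid(self.data[..., t], self.affine)


@dataclass
class LabelVolume:
    """Integer-labeled parcellation on a VolumeGrid lattice; 0 is background."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("label volume must hold integers")
            self.data = np.round(self.data).astype(int)
        if self.data.ndim != 3:
            raise ValueError("LabelVolume expects 3-D data")
        self.affine = _check_affine(self.affine)
        present = set(np.unique(self.data)) - {0}
        missing = present - set(self.label_names)
        if missing:
            # auto-name unnamed labels rather than reject
            for lab in sorted(missing):
                self.label_names[int(lab)] = f"region_{int(lab)}"

    @property
    def labels(self) -> list[int]:
        return sorted(set(np.unique(self.data)) - {0})


def _reject_non_finite(arr: np.ndarray, where: str) -> None:
    n_bad = int((~np.isfinite(arr)).sum())
    if n_bad:
        raise ValueError(f"{where}: {n_bad} non-finite voxel(s)")


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a 3-D NIfTI-1 volume. 4-D files are rejected, not squeezed."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, file is {img.ndim}-D")
    data = np.asarray(img.get_fdata(), dtype=float)
    _reject_non_finite(data, str(path))
    return VolumeGrid(data, np.asarray(img.affine))


def write_volume(vol: VolumeGrid, path: str | Path) -> Path:
    _reject_non_finite(vol.data, "write_volume")
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    path = Path(path)
    nib.save(img, str(path))
    return path


def read_series(path: str | Path) -> SeriesGrid:
    """Read a 4-D NIfTI-1 series. T=1 series are kept 4-D (header decides)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D series, file is {img.ndim}-D")
    data = np.asarray(img.get_fdata(), dtype=float)
    _reject_non_finite(data, str(path))
    zooms = img.header.get_zooms()
    t_r = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else None
    return SeriesGrid(data, np.asarray(img.affine), t_r=t_r)


def write_series(series: SeriesGrid, path: str | Path) -> Path:
    _reject_non_finite(series.data, "write_series")
    img = nib.Nifti1Image(series.data.astype(np.float32), series.affine)
    if series.t_r is not None:
        zooms = list(img.header.get_zooms())
        zooms[3] = series.t_r
        img.header.set_zooms(zooms)
    path = Path(path)
    nib.save(img, str(path))
    return path


def _split_table(text: str, path: Path) -> list[list[str]]:
    rows = [line.split("\t") for line in text.splitlines() if line.strip()]
    if not rows:
        raise ValueError(f"{path}: empty table")
    width = len(rows[0])
    for idx, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(
                f"{path}: row {idx} has {len(row)} fields, expected {width}"
            )
    return rows


def read_timecourses(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read component timecourses from TSV.

    Two layouts are accepted:

    * wide — one file per subject: a ``component`` column followed by one
      column per timepoint; the result maps the file stem to its matrix;
    * long — a ``subject_id`` column, a ``component`` column, then timepoint
      columns; one matrix per subject.

    Returns a dict of subject id -> DataFrame (components x T), with the
    component order of the file preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = _split_table(path.read_text(), path)
    df = pd.read_csv(io.StringIO("\n".join("\t".join(r) for r in rows)), sep="\t")
    if "component" not in df.columns:
        raise ValueError(f"{path}: missing 'component' column")
    out: dict[str, pd.DataFrame] = {}
    if "subject_id" in df.columns:
        groups = [(str(sid), sub) for sid, sub in df.groupby("subject_id", sort=False)]
    else:
        groups = [(path.name.split(".")[0], df)]
    for sid, sub in groups:
        comps = sub["component"].astype(str).tolist()
        dupes = {c for c in comps if comps.count(c) > 1}
        if dupes:
            raise ValueError(f"{path}: duplicate component names {sorted(dupes)}")
        value_cols = [c for c in sub.columns if c not in ("subject_id", "component")]
        mat = sub[value_cols].to_numpy(dtype=float)
        out[sid] = pd.DataFrame(mat, index=comps)
    return out


def write_timecourses(
    timecourses: dict[str, np.ndarray | pd.DataFrame],
    path: str | Path,
    component_names: list[str] | None = None,
) -> Path:
    """Write a subject-indexed set of (components x T) matrices as long TSV."""
    frames = []
    for sid, mat in timecourses.items():
        if isinstance(mat, pd.DataFrame):
            names = [str(c) for c in mat.index]
            arr = mat.to_numpy(dtype=float)
        else:
            arr = np.asarray(mat, dtype=float)
            names = component_names or [f"comp_{i}" for i in range(arr.shape[0])]
        block = pd.DataFrame(arr, columns=[f"t{j}" for j in range(arr.shape[1])])
        block.insert(0, "component", names)
        block.insert(0, "subject_id", sid)
        frames.append(block)
    path = Path(path)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    return path


def read_subjects(path: str | Path) -> pd.DataFrame:
    """Read a subject table (columns: subject_id, group, ...)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing '{col}' column")
    return df
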