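"""Volume containers, NIfTI I/O, affine resampling and cohort manifests.

All grids are 0-based; the NIfTI affine maps voxel indices to world
coordinates in millimetres.  Two coordinate frames are distinguished by a
``space_tag``: the *common* (template-like) frame shared by the atlas and the
network, and each subject's *native* acquisition frame.  Rigid transforms are
stored as 4x4 row-major matrices mapping common-space world coordinates to
native-space world coordinates.
"""

from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Volume3D",
    "BinaryMask3D",
    "Geometry",
    "CohortManifest",
    "read_volume",
    "read_mask",
    "write_volume",
    "read_transform",
    "write_transform",
    "resample_with_affine",
    "load_manifest",
    "save_manifest",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "diagnosis",
    "tiv_cm3",
    "lvv_cm3",
    "t1_path",
    "t2_path",
    "flair_path",
    "mask_path",
    "transform_path",
]


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=np.float64)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is not invertible")
    return affine


@dataclasses.dataclass
class Volume3D:
    """A scalar 3-D grid with voxel spacing and a grid-to-world affine."""

    data: np.ndarray
    affine: np.ndarray
    space_tag: str = "common"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={self.data.ndim}")
        self.affine = _check_affine(self.affine)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size in mm along each axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def geometry(self) -> "Geometry":
        return Geometry(self.shape, self.affine.copy())

    def same_geometry(self, other: "Volume3D | BinaryMask3D", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)


@dataclasses.dataclass
class BinaryMask3D(Volume3D):
    """A boolean 3-D grid sharing :class:`Volume3D` geometry."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != bool:
            # tolerate 255-coded or float masks: any nonzero voxel is foreground
            self.data = self.data != 0
        super().__post_init__()

    def volume_cm3(self) -> float:
        return float(self.data.sum()) * self.voxel_volume_mm3 / 1000.0


@dataclasses.dataclass(frozen=True)
class Geometry:
    """Target grid description for resampling: shape + grid-to-world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(np.asarray(self.affine)[:3, :3], axis=0)


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path: str | os.PathLike, space_tag: str = "native") -> Volume3D:
    """Read a single 3-D volume from a NIfTI file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of error types
        raise ValueError(f"could not read NIfTI volume {path}: {exc}") from exc
    # squeeze trailing singleton dims; true 4-D time series are rejected
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return Volume3D(np.asarray(data, dtype=np.float32), img.affine, space_tag=space_tag)


def read_mask(path: str | os.PathLike, space_tag: str = "native") -> BinaryMask3D:
    v = read_volume(path, space_tag=space_tag)
    return BinaryMask3D(v.data != 0, v.affine, space_tag=space_tag)


def write_volume(v: Volume3D | BinaryMask3D, path: str | os.PathLike) -> None:
    """Write a volume (float32) or mask (uint8 {0,1}) as NIfTI."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if isinstance(v, BinaryMask3D):
        payload = v.data.astype(np.uint8)
    else:
        payload = np.asarray(v.data, dtype=np.float32)
    img = nib.Nifti1Image(payload, v.affine)
    img.header.set_zooms(tuple(v.spacing))
    nib.save(img, str(path))


def read_transform(path: str | os.PathLike) -> np.ndarray:
    """Read a 4x4 row-major rigid/affine world-to-world transform."""
    t = np.loadtxt(path, dtype=np.float64)
    return _check_affine(t)


def write_transform(t: np.ndarray, path: str | os.PathLike) -> None:
    np.savetxt(path, _check_affine(t), fmt="%.17g")


# ---------------------------------------------------------------------------
# Resampling


def resample_with_affine(
    src: Volume3D | BinaryMask3D,
    transform: np.ndarray,
    target: Geometry,
    interp: str = "trilinear",
    space_tag: str | None = None,
) -> Volume3D | BinaryMask3D:
    """Resample ``src`` onto ``target`` under a world-to-world transform.

    ``transform`` maps source-space world coordinates to target-space world
    coordinates.  Each target voxel ``i`` is filled from the source location
    ``A_src^-1 T^-1 A_tgt i`` (pull-back sampling).  Masks must use nearest
    interpolation so no new label values are invented; out-of-field voxels
    are filled with 0.
    """
    is_mask = isinstance(src, BinaryMask3D)
    if interp not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interp!r}")
    if is_mask and interp != "nearest":
        raise ValueError("masks must be resampled with nearest interpolation")
    transform = _check_affine(transform)
    tgt_affine = _check_affine(np.asarray(target.affine))
    M = np.linalg.inv(src.affine) @ np.linalg.inv(transform) @ tgt_affine
    order = 0 if interp == "nearest" else 1
    data = src.data.astype(np.float32) if not is_mask else src.data.astype(np.uint8)
    out = ndimage.affine_transform(
        data,
        M[:3, :3],
        offset=M[:3, 3],
        output_shape=tuple(target.shape),
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    tag = space_tag if space_tag is not None else src.space_tag
    if is_mask:
        return BinaryMask3D(out != 0, tgt_affine, space_tag=tag)
    return Volume3D(out.astype(np.float32), tgt_affine, space_tag=tag)


# ---------------------------------------------------------------------------
# Cohort manifest


@dataclasses.dataclass
class CohortManifest:
    """Typed cohort table; one row per subject.

    ``root`` anchors relative file paths.  File-path columns may be empty for
    purely in-memory cohorts (e.g. phantom subjects that were never written).
    """

    rows: pd.DataFrame
    root: Path = Path(".")

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        self.rows = self.rows.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.rows
        dup = df["subject_id"][df["subject_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate subject_id: {dup.iloc[0]!r}")
        for i, row in df.iterrows():
            if not (0 <= row["age"] <= 120):
                raise ValueError(f"row {i}: age {row['age']} outside [0, 120]")
            if row["sex"] not in ("F", "M"):
                raise ValueError(f"row {i}: sex must be 'F' or 'M', got {row['sex']!r}")
            if not row["tiv_cm3"] > 0:
                raise ValueError(f"row {i}: tiv_cm3 must be positive")
            if not row["lvv_cm3"] > 0:
                raise ValueError(f"row {i}: lvv_cm3 must be positive")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.rows["subject_id"])

    def path(self, subject_id: str, column: str) -> Path:
        row = self.rows.loc[self.rows["subject_id"] == subject_id]
        if row.empty:
            raise KeyError(f"unknown subject_id {subject_id!r}")
        rel = row.iloc[0][column]
        if not isinstance(rel, str) or not rel:
            raise ValueError(f"subject {subject_id}: column {column} has no file path")
        p = Path(rel)
        return p if p.is_absolute() else self.root / p

    def check_files(self) -> None:
        for sid in self.subject_ids:
            for col in ("t1_path", "t2_path", "flair_path", "mask_path", "transform_path"):
                p = self.path(sid, col)
                if not p.exists():
                    raise FileNotFoundError(f"subject {sid}: missing file {p}")


def load_manifest(path: str | os.PathLike, check_files: bool = True) -> CohortManifest:
    """Load a cohort manifest from CSV (or a JSON list of row objects)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            df = pd.DataFrame(json.load(fh))
    else:
        df = pd.read_csv(path, dtype={"subject_id": str})
    df["subject_id"] = df["subject_id"].astype(str)
    man = CohortManifest(df, root=path.parent)
    if check_files:
        man.check_files()
    return man


def save_manifest(man: CohortManifest, path: str | os.PathLike) -> None:
    man.rows[MANIFEST_COLUMNS].to_csv(path, index=False)
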