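"""Probabilistic atlas construction, patch sampling, flipping and stitching.

The atlas is the voxelwise mean of the training plexus masks in common space.
Training patches are centred on voxels drawn from the atlas with probability
proportional to the atlas value (sampling with replacement), which
concentrates the training signal where the structure actually occurs.  At
inference a deterministic grid tiling of the atlas crop box guarantees full
coverage; overlapping patch scores are averaged and thresholded.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .image_io import BinaryMask3D, Volume3D, read_volume, write_volume

__all__ = [
    "ProbAtlas",
    "build_atlas",
    "sample_patch_centers",
    "extract_patch",
    "flip_lr",
    "stitch_and_binarize",
    "grid_tile_centers",
    "save_atlas",
    "load_atlas",
]

UNCOVERED_SCORE = -1.0  # minimum of the tanh output range


@dataclasses.dataclass
class ProbAtlas:
    """Voxelwise plexus frequency map with its support and a crop box."""

    prob: Volume3D
    margin: int
    crop_box: tuple[tuple[int, int, int], tuple[int, int, int]]  # inclusive lo/hi

    def __post_init__(self) -> None:
        p = self.prob.data
        if p.min() < 0 or p.max() > 1:
            raise ValueError("atlas probabilities must lie in [0, 1]")
        if not (p > 0).any():
            raise ValueError("atlas support is empty")
        lo, hi = np.asarray(self.crop_box[0]), np.asarray(self.crop_box[1])
        support_idx = np.argwhere(p > 0)
        if (support_idx.min(0) < lo).any() or (support_idx.max(0) > hi).any():
            raise ValueError("crop_box does not contain the atlas support")

    @property
    def support(self) -> BinaryMask3D:
        return BinaryMask3D(self.prob.data > 0, self.prob.affine,
                            space_tag=self.prob.space_tag)


def build_atlas(masks: list[BinaryMask3D], margin: int = 8) -> ProbAtlas:
    """Average training masks into a probabilistic atlas with a padded crop box."""
    if not masks:
        raise ValueError("need at least one mask")
    ref = masks[0]
    for m in masks[1:]:
        if not ref.same_geometry(m):
            raise ValueError("all atlas masks must share geometry")
    prob = np.mean([m.data for m in masks], axis=0, dtype=np.float64)
    if not (prob > 0).any():
        raise ValueError("all masks are empty; cannot build an atlas")
    idx = np.argwhere(prob > 0)
    lo = np.maximum(idx.min(0) - margin, 0)
    hi = np.minimum(idx.max(0) + margin, np.asarray(ref.shape) - 1)
    return ProbAtlas(
        prob=Volume3D(prob.astype(np.float32), ref.affine, space_tag=ref.space_tag),
        margin=int(margin),
        crop_box=(tuple(int(v) for v in lo), tuple(int(v) for v in hi)),
    )


def sample_patch_centers(atlas: ProbAtlas, n: int = 41, seed: int = 0) -> np.ndarray:
    """Draw ``n`` patch centres from atlas support, weighted by probability."""
    if n < 1:
        raise ValueError("n must be >= 1")
    p = atlas.prob.data
    support_idx = np.argwhere(p > 0)
    if len(support_idx) == 0:
        raise ValueError("atlas support is empty")
    weights = p[tuple(support_idx.T)].astype(np.float64)
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(support_idx), size=n, replace=True, p=weights)
    return support_idx[picks]


def extract_patch(
    vol: Volume3D | BinaryMask3D | np.ndarray,
    center: tuple[int, int, int] | np.ndarray,
    size: int = 64,
    pad_value: float = 0.0,
) -> np.ndarray:
    """Extract a ``size``^3 patch centred at ``center`` (index size//2).

    Out-of-grid voxels are filled with ``pad_value``.
    """
    data = vol.data if isinstance(vol, Volume3D) else np.asarray(vol)
    center = np.asarray(center, dtype=int)
    shape = np.asarray(data.shape)
    if (center < 0).any() or (center >= shape).any():
        raise ValueError(f"center {tuple(center)} outside grid {tuple(shape)}")
    lo = center - size // 2
    hi = lo + size
    src_lo = np.maximum(lo, 0)
    src_hi = np.minimum(hi, shape)
    out = np.full((size, size, size), pad_value,
                  dtype=np.float32 if data.dtype != bool else data.dtype)
    dst_lo = src_lo - lo
    dst_hi = dst_lo + (src_hi - src_lo)
    out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = data[
        src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]
    ]
    return out


def flip_lr(image_patch: np.ndarray, label_patch: np.ndarray | None = None):
    """Mirror patch(es) along the left-right axis (axis 0 in common space)."""
    if label_patch is not None and image_patch.shape != label_patch.shape:
        raise ValueError("image and label patches must share shape")
    flipped = image_patch[::-1].copy()
    if label_patch is None:
        return flipped
    return flipped, label_patch[::-1].copy()


def grid_tile_centers(
    crop_box: tuple[tuple[int, int, int], tuple[int, int, int]],
    grid_shape: tuple[int, int, int],
    size: int,
    stride: int | None = None,
) -> np.ndarray:
    """Deterministic tiling whose patch footprints cover the crop box."""
    stride = stride if stride is not None else max(1, size // 2)
    lo, hi = np.asarray(crop_box[0]), np.asarray(crop_box[1])
    per_axis = []
    for a in range(3):
        starts = list(range(int(lo[a]), int(hi[a]) - size + 2, stride))
        last = max(int(lo[a]), int(hi[a]) - size + 1)
        if not starts or starts[-1] != last:
            starts.append(last)
        centers = sorted({min(max(s + size // 2, 0), grid_shape[a] - 1) for s in starts})
        per_axis.append(centers)
    out = [(i, j, k) for i in per_axis[0] for j in per_axis[1] for k in per_axis[2]]
    return np.asarray(out, dtype=int)


def stitch_and_binarize(
    score_patches: list[np.ndarray] | np.ndarray,
    centers: np.ndarray,
    geometry,
    threshold: float = 0.0,
) -> tuple[Volume3D, BinaryMask3D]:
    """Average overlapping patch scores into a volume and threshold it.

    Each voxel's score is the arithmetic mean of all patch scores covering it;
    voxels covered by no patch get the minimum tanh score (-1).  The mask
    keeps voxels with score strictly greater than ``threshold``.
    """
    score_patches = list(score_patches)
    if not score_patches:
        raise ValueError("no patches to stitch")
    centers = np.asarray(centers, dtype=int)
    if len(centers) != len(score_patches):
        raise ValueError("one center per patch required")
    shape = tuple(geometry.shape)
    acc = np.zeros(shape, dtype=np.float64)
    cnt = np.zeros(shape, dtype=np.int32)
    for patch, center in zip(score_patches, centers):
        patch = np.asarray(patch)
        size = patch.shape[0]
        if patch.shape != (size, size, size):
            raise ValueError("patches must be cubic")
        lo = center - size // 2
        hi = lo + size
        src_lo = np.maximum(lo, 0)
        src_hi = np.minimum(hi, np.asarray(shape))
        p_lo = src_lo - lo
        p_hi = p_lo + (src_hi - src_lo)
        acc[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]] += patch[
            p_lo[0]:p_hi[0], p_lo[1]:p_hi[1], p_lo[2]:p_hi[2]
        ]
        cnt[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]] += 1
    covered = cnt > 0
    score = np.full(shape, UNCOVERED_SCORE, dtype=np.float32)
    score[covered] = (acc[covered] / cnt[covered]).astype(np.float32)
    affine = np.asarray(geometry.affine)
    vol = Volume3D(score, affine, space_tag="common")
    mask = BinaryMask3D(score > threshold, affine, space_tag="common")
    return vol, mask


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            name = name[: -len(ext)]
            break
    return path.with_name(name + ".json")


def save_atlas(atlas: ProbAtlas, path: str | Path) -> None:
    """Persist as a NIfTI probability map plus a JSON sidecar."""
    path = Path(path)
    write_volume(atlas.prob, path)
    sidecar = {"margin": atlas.margin,
               "crop_box": [list(atlas.crop_box[0]), list(atlas.crop_box[1])]}
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh)


def load_atlas(path: str | Path) -> ProbAtlas:
    path = Path(path)
    prob = read_volume(path, space_tag="common")
    with open(_sidecar_path(path)) as fh:
        sidecar = json.load(fh)
    return ProbAtlas(
        prob=prob,
        margin=int(sidecar["margin"]),
        crop_box=(tuple(sidecar["crop_box"][0]), tuple(sidecar["crop_box"][1])),
    )
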