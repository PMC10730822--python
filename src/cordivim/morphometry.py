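"""Cord morphometry: cross-sectional areas, diameters, compression ratios
and lesion-frequency maps.

Masks are non-negative volumes thresholded at > 0 on the package's common
grid (axis 0 left-right, axis 1 anterior-posterior, axis 2 slice); voxel
indices are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SegmentationSet",
    "SagittalDiameters",
    "compute_csa",
    "compute_extents",
    "compute_compression_ratio",
    "lesion_frequency_map",
]


@dataclass
class SegmentationSet:
    """Cord / white-matter / grey-matter / lesion masks on one grid.

    ``wm_mask`` is white matter proper (disjoint from grey matter);
    grey and white matter together partition the cord.  ``level_labels``
    tags every slice with its vertebral level (e.g. "C1").
    """

    cord_mask: np.ndarray
    wm_mask: np.ndarray
    gm_mask: np.ndarray
    lesion_mask: np.ndarray
    level_labels: tuple[str, ...]
    voxel_dims: tuple[float, float, float]

    def __post_init__(self) -> None:
        masks = [self.cord_mask, self.wm_mask, self.gm_mask, self.lesion_mask]
        shapes = {m.shape for m in masks}
        if len(shapes) != 1:
            raise ValueError(f"all masks must share one grid, got {shapes}")
        self.cord_mask = self.cord_mask > 0
        self.wm_mask = self.wm_mask > 0
        self.gm_mask = self.gm_mask > 0
        self.lesion_mask = self.lesion_mask > 0
        if len(self.level_labels) != self.cord_mask.shape[2]:
            raise ValueError(
                f"{len(self.level_labels)} level labels for "
                f"{self.cord_mask.shape[2]} slices"
            )
        if np.any(self.gm_mask & ~self.cord_mask):
            raise ValueError("gm_mask must lie within cord_mask")
        if np.any(self.wm_mask & ~self.cord_mask):
            raise ValueError("wm_mask must lie within cord_mask")
        if np.any(self.gm_mask & self.wm_mask):
            raise ValueError("gm_mask and wm_mask must be disjoint")
        if any(d <= 0 for d in self.voxel_dims):
            raise ValueError(f"voxel_dims must be positive, got {self.voxel_dims}")

    def slices_at_levels(self, levels: Iterable[str]) -> list[int]:
        wanted = set(levels)
        return [i for i, lab in enumerate(self.level_labels) if lab in wanted]


@dataclass(frozen=True)
class SagittalDiameters:
    """Mid-sagittal diameters for a compression / compromise ratio.

    d_i is the diameter at the site of maximal compression; d_a and d_b
    the non-compressed reference diameters above and below it.
    ``target`` says whether the diameters describe the cord (for MSCC)
    or the spinal canal (for MCC).
    """

    d_i: float
    d_a: float
    d_b: float
    target: str = "cord"

    def __post_init__(self) -> None:
        for name, v in (("d_i", self.d_i), ("d_a", self.d_a), ("d_b", self.d_b)):
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.d_i > max(self.d_a, self.d_b):
            raise ValueError(
                f"d_i ({self.d_i}) exceeds both references "
                f"(d_a={self.d_a}, d_b={self.d_b}); no meaningful compression ratio"
            )
        if self.target not in ("cord", "canal"):
            raise ValueError(f"target must be 'cord' or 'canal', got {self.target!r}")


def compute_csa(
    mask: np.ndarray,
    voxel_dims: Sequence[float],
    slice_range: Sequence[int],
) -> float:
    """Mean cross-sectional area (mm^2) of a mask over the given slices.

    Per slice: in-mask voxel count x in-plane voxel area; the result is
    the unweighted mean across the selected slices.  A slice with an
    empty mask contributes 0 with a warning.
    """
    slices = list(slice_range)
    if not slices:
        raise ValueError("slice_range is empty")
    mask = np.asarray(mask) > 0
    area = float(voxel_dims[0]) * float(voxel_dims[1])
    per_slice = []
    for z in slices:
        n = int(mask[:, :, z].sum())
        if n == 0:
            warnings.warn(f"mask empty on slice {z}; contributes 0 to the CSA mean")
        per_slice.append(n * area)
    if not any(per_slice):
        raise ValueError("mask is empty on every selected slice")
    return float(np.mean(per_slice))


def _centroid_extents(slice_mask: np.ndarray, voxel_dims: Sequence[float]) -> tuple[float, float]:
    xs, ys = np.nonzero(slice_mask)
    cx = int(round(xs.mean()))
    cy = int(round(ys.mean()))
    # extent of the mask along AP through the centroid LR column, and
    # along LR through the centroid AP row
    col = np.nonzero(slice_mask[cx, :])[0]
    row = np.nonzero(slice_mask[:, cy])[0]
    ap = (col.max() - col.min() + 1) * float(voxel_dims[1])
    lr = (row.max() - row.min() + 1) * float(voxel_dims[0])
    return ap, lr


def compute_extents(
    mask: np.ndarray,
    voxel_dims: Sequence[float],
    slice_range: Sequence[int] | int,
) -> tuple[float, float]:
    """Anterior-posterior diameter and left-right width (mm) of a mask.

    Extents are measured through the mask centroid (AP along the
    centroid column, LR along the centroid row), which is robust to
    small boundary protrusions, and averaged over the requested slices.

    Returns (ap_diameter, lr_width).
    """
    slices = [slice_range] if np.isscalar(slice_range) else list(slice_range)
    mask = np.asarray(mask) > 0
    aps, lrs = [], []
    for z in slices:
        sl = mask[:, :, z]
        if not sl.any():
            raise ValueError(f"mask empty on slice {z}")
        ap, lr = _centroid_extents(sl, voxel_dims)
        aps.append(ap)
        lrs.append(lr)
    return float(np.mean(aps)), float(np.mean(lrs))


def compute_compression_ratio(d: SagittalDiameters) -> float:
    """Compression / compromise ratio in percent.

    MSCC (cord) or MCC (canal): 100 * [1 - d_i / ((d_a + d_b)/2)] — the
    percentage reduction of the compressed diameter relative to the
    mean of the non-compressed references above and below.  0 when the
    compressed diameter equals the reference mean; at most 100.
    """
    return float(100.0 * (1.0 - d.d_i / ((d.d_a + d.d_b) / 2.0)))


def lesion_frequency_map(lesion_masks: Sequence[np.ndarray]) -> np.ndarray:
    """Voxel-wise lesion frequency (percent) over aligned binary masks.

    Each voxel's value is the percentage of subjects whose lesion mask
    covers it: 100 x mean of the binary indicators, in [0, 100].
    """
    if len(lesion_masks) == 0:
        raise ValueError("need at least one lesion mask")
    shapes = {np.asarray(m).shape for m in lesion_masks}
    if len(shapes) != 1:
        raise ValueError(f"lesion masks must share one grid, got shapes {shapes}")
    stack = np.stack([np.asarray(m) > 0 for m in lesion_masks])
    return stack.mean(axis=0) * 100.0
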