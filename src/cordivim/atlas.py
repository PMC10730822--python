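"""Atlas regions of interest in the cord cross-section.

ROIs follow the standard cord parcellation: white-matter funiculi
(ventral, lateral) and dorsal columns; grey-matter ventral and dorsal
horns.  All ROIs are eroded at the cord periphery before statistics are
extracted, to limit partial-volume contamination from cerebrospinal
fluid at the cord surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

__all__ = ["AtlasROISet", "ROIStat", "erode_periphery", "roi_statistic"]

# 4-connected in-plane structuring element
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

WM_SUBREGIONS = ("ventral_funiculi", "lateral_funiculi", "dorsal_columns")
GM_SUBREGIONS = ("ventral_horns", "dorsal_horns")


@dataclass
class AtlasROISet:
    """Named ROI masks on one grid.

    Funiculi/columns lie within white matter; horns within grey matter;
    subregions of one tissue are mutually disjoint.  ``provenance``
    records whether the set was generated with a phantom or imported.
    """

    white_matter: np.ndarray
    grey_matter: np.ndarray
    ventral_funiculi: np.ndarray
    lateral_funiculi: np.ndarray
    dorsal_columns: np.ndarray
    ventral_horns: np.ndarray
    dorsal_horns: np.ndarray
    provenance: str = "phantom"

    def __post_init__(self) -> None:
        for name in self._names():
            setattr(self, name, np.asarray(getattr(self, name)) > 0)
        shapes = {getattr(self, n).shape for n in self._names()}
        if len(shapes) != 1:
            raise ValueError(f"ROI masks must share one grid, got {shapes}")
        for name in WM_SUBREGIONS:
            if np.any(getattr(self, name) & ~self.white_matter):
                raise ValueError(f"{name} must lie within white_matter")
        for name in GM_SUBREGIONS:
            if np.any(getattr(self, name) & ~self.grey_matter):
                raise ValueError(f"{name} must lie within grey_matter")
        for group in (WM_SUBREGIONS, GM_SUBREGIONS):
            for a in group:
                for b in group:
                    if a < b and np.any(getattr(self, a) & getattr(self, b)):
                        raise ValueError(f"subregions {a} and {b} overlap")

    @staticmethod
    def _names() -> tuple[str, ...]:
        return ("white_matter", "grey_matter") + WM_SUBREGIONS + GM_SUBREGIONS

    def items(self):
        for name in self._names():
            yield name, getattr(self, name)

    def eroded(self, cord_mask: np.ndarray, iterations: int = 1) -> "AtlasROISet":
        """Return a copy with every ROI eroded at the cord periphery."""
        kw = {
            name: erode_periphery(mask, cord_mask, iterations, roi_name=name)
            for name, mask in self.items()
        }
        return AtlasROISet(provenance=self.provenance, **kw)


class ROIStat(NamedTuple):
    """Mean of a map over an ROI with the voxel count that entered it."""

    mean: float
    n_voxels: int


def erode_periphery(
    roi_mask: np.ndarray,
    cord_mask: np.ndarray,
    iterations: int = 1,
    roi_name: str = "ROI",
) -> np.ndarray:
    """Remove ROI voxels within ``iterations`` of the cord boundary.

    Erosion is 2D (per slice) with a 4-connected structuring element:
    the cord mask is eroded ``iterations`` times and the ROI is
    intersected with the result, so interior ROI voxels are untouched
    and ``iterations=0`` is the identity.

    Raises if the eroded ROI is empty on every slice where the input
    ROI was non-empty.
    """
    roi = np.asarray(roi_mask) > 0
    cord = np.asarray(cord_mask) > 0
    if roi.shape != cord.shape:
        raise ValueError(f"roi grid {roi.shape} does not match cord grid {cord.shape}")
    if np.any(roi & ~cord):
        raise ValueError(f"{roi_name} must lie within the cord mask")
    if iterations < 0:
        raise ValueError(f"iterations must be >= 0, got {iterations}")
    if iterations == 0:
        return roi.copy()
    interior = np.zeros_like(cord)
    for z in range(cord.shape[2]):
        interior[:, :, z] = ndimage.binary_erosion(
            cord[:, :, z], structure=_CROSS, iterations=iterations
        )
    out = roi & interior
    if roi.any() and not out.any():
        raise ValueError(
            f"eroding {roi_name} by {iterations} iteration(s) emptied it on every slice"
        )
    return out


def roi_statistic(
    map_volume: np.ndarray,
    roi_mask: np.ndarray,
    qc_mask: np.ndarray | None = None,
) -> ROIStat:
    """Arithmetic mean of a parameter map over ROI ∩ QC voxels.

    Voxels outside the QC mask and voxels holding NaN (failed fits) are
    excluded; they are never treated as zeros.  Raises when no valid
    voxel remains.
    """
    vol = np.asarray(map_volume, dtype=float)
    roi = np.asarray(roi_mask) > 0
    sel = roi if qc_mask is None else roi & (np.asarray(qc_mask) > 0)
    sel = sel & np.isfinite(vol)
    n = int(sel.sum())
    if n == 0:
        raise ValueError("ROI ∩ QC intersection is empty: no valid voxels to average")
    return ROIStat(mean=float(vol[sel].mean()), n_voxels=n)
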