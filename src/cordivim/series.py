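"""4D diffusion-weighted series bound to an acquisition scheme.

Axis convention throughout the package: axis 0 = left-right (x), axis 1 =
anterior-posterior (y, increasing towards dorsal), axis 2 = slice
(inferior-superior), axis 3 = volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scheme import BValueScheme

__all__ = ["DwiSeries"]


@dataclass
class DwiSeries:
    """A 4D DWI signal volume with its scheme and voxel geometry.

    ``signal`` has shape (nx, ny, nz, n_volumes) with volumes ordered
    repetition-fastest, then direction, then b-value (the order of
    ``scheme.volume_table()``).  ``voxel_dims`` is (dx, dy, dz) in mm.
    """

    signal: np.ndarray
    scheme: BValueScheme
    voxel_dims: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError(f"signal must be 4D, got {self.signal.ndim}D")
        if self.signal.shape[3] != self.scheme.n_volumes:
            raise ValueError(
                f"series has {self.signal.shape[3]} volumes but the scheme "
                f"implies {self.scheme.n_volumes} "
                f"({self.scheme.n_bvalues} b x {self.scheme.n_directions} dir "
                f"x {self.scheme.n_repetitions} rep)"
            )
        if np.any(self.signal < 0):
            raise ValueError("signal intensities must be non-negative")
        if any(d <= 0 for d in self.voxel_dims):
            raise ValueError(f"voxel_dims must be positive, got {self.voxel_dims}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    def volume_index(self) -> np.ndarray:
        """(n_volumes, 3) rows of (b, direction, repetition)."""
        return self.scheme.volume_table()

    def by_b_dir_rep(self) -> np.ndarray:
        """Reshape to (nx, ny, nz, n_b, n_dir, n_rep)."""
        nx, ny, nz, _ = self.signal.shape
        s = self.scheme
        return self.signal.reshape(nx, ny, nz, s.n_bvalues, s.n_directions, s.n_repetitions)

    def average_repetitions(self) -> np.ndarray:
        """Arithmetic mean over repetitions: (nx, ny, nz, n_b, n_dir)."""
        return self.by_b_dir_rep().mean(axis=5)
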