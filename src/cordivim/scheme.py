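"""Diffusion acquisition schemes for IVIM imaging of the cervical cord.

A scheme is the list of diffusion weightings (b-values, s/mm^2) together
with the number of in-plane encoding directions and the number of
repetitions acquired per (b, direction) pair.  The default scheme is the
cardiac-gated cord protocol used throughout this package: fourteen
b-values from 0 to 650 s/mm^2 in steps of 50, three in-plane directions,
twenty repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["BValueScheme", "default_scheme", "read_btable", "write_btable"]


@dataclass(frozen=True)
class BValueScheme:
    """Diffusion-weighting protocol.

    Parameters
    ----------
    b_values
        Strictly increasing b-values in s/mm^2; the first must be 0.
    n_directions
        Number of in-plane diffusion-encoding directions (>= 1).
    n_repetitions
        Repetitions per b-value per direction (>= 1).
    """

    b_values: tuple[float, ...]
    n_directions: int = 3
    n_repetitions: int = 20

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("scheme needs at least two b-values")
        if b[0] != 0.0:
            raise ValueError(f"first b-value must be 0, got {b[0]}")
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b-values must be strictly increasing")
        if self.n_directions < 1:
            raise ValueError(f"n_directions must be >= 1, got {self.n_directions}")
        if self.n_repetitions < 1:
            raise ValueError(f"n_repetitions must be >= 1, got {self.n_repetitions}")
        object.__setattr__(self, "b_values", tuple(float(x) for x in b))

    @property
    def n_bvalues(self) -> int:
        return len(self.b_values)

    @property
    def n_volumes(self) -> int:
        """Total 4D volumes: b-values x directions x repetitions."""
        return self.n_bvalues * self.n_directions * self.n_repetitions

    def b_array(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)

    def volume_table(self) -> np.ndarray:
        """(n_volumes, 3) array of (b, direction, repetition) per volume.

        Volume ordering is repetition-fastest within direction within
        b-value, matching how the series generator lays out volumes.
        """
        rows = [
            (b, d, r)
            for b in self.b_values
            for d in range(self.n_directions)
            for r in range(self.n_repetitions)
        ]
        return np.asarray(rows, dtype=float)


def default_scheme() -> BValueScheme:
    """The 14-b cervical-cord protocol: b = 0,50,...,650; 3 directions; 20 reps."""
    return BValueScheme(tuple(np.arange(0.0, 651.0, 50.0)), n_directions=3, n_repetitions=20)


def write_btable(path: str | Path, scheme: BValueScheme) -> None:
    """Write a whitespace-delimited b-table, one row per 4D volume."""
    table = scheme.volume_table()
    header = "b direction repetition"
    np.savetxt(path, table, fmt=["%.1f", "%d", "%d"], header=header, comments="")


def read_btable(path: str | Path) -> BValueScheme:
    """Reconstruct a scheme from a b-table written by :func:`write_btable`."""
    table = np.loadtxt(path, skiprows=1, ndmin=2)
    if table.shape[1] != 3:
        raise ValueError(f"b-table must have 3 columns, got {table.shape[1]}")
    b_values = tuple(sorted(set(table[:, 0])))
    n_dir = int(table[:, 1].max()) + 1
    n_rep = int(table[:, 2].max()) + 1
    scheme = BValueScheme(b_values, n_directions=n_dir, n_repetitions=n_rep)
    if scheme.n_volumes != table.shape[0]:
        raise ValueError(
            f"b-table has {table.shape[0]} rows but implies "
            f"{scheme.n_volumes} volumes ({scheme.n_bvalues} b x {n_dir} dir x {n_rep} rep)"
        )
    return scheme
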