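"""File I/O: NIfTI volumes, cohort tables, YAML config, provenance.

Volumes are written as NIfTI-1 in RAS orientation with an explicit
diagonal affine built from the voxel dimensions; nothing is ever
resampled silently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_table",
    "load_table",
    "load_yaml",
    "config_hash",
    "write_provenance",
]


def save_nifti(path: str | Path, data: np.ndarray, voxel_dims) -> None:
    """Write an array as NIfTI-1 with a diagonal RAS affine."""
    affine = np.diag(list(voxel_dims[:3]) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns (data, voxel_dims in mm)."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.dataobj, dtype=float), tuple(float(z) for z in zooms)


def save_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    return out or {}


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_hash(config) -> str:
    """Stable short hash of a configuration (dataclass or dict)."""
    payload = json.dumps(_jsonable(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_provenance(out_dir: str | Path, config, seed: int, stage: str) -> None:
    """Record config hash, seed and package version next to an artifact."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "stage": stage,
        "config_hash": config_hash(config),
        "seed": int(seed),
        "version": __version__,
    }
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(meta, fh, indent=2)
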