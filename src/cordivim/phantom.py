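"""Synthetic cervical-cord subjects for end-to-end verification.

This module generates seeded, ground-truthed stand-ins for an IVIM cord
study: a cord-shaped phantom (elliptical cord, butterfly grey matter)
voxelized on a template-like grid, tissue-specific IVIM parameters drawn
from configurable cohort distributions, a Rician-noisy multi-b DWI
series synthesized with the forward model, segmentation masks, atlas
ROIs, sagittal diameter profiles and a clinical-score table.

Default distributions emulate a two-cohort degenerative cervical
myelopathy (DCM) study: ~30 healthy controls and ~29 patients, with the
patient cohort carrying a multiplicative pseudo-diffusion deficit and
cord atrophy, a configurable fraction of patients showing a focal
T2-hyperintense lesion, and clinical scores sampled within their
instrument ranges.  Every random draw descends from one seed, so a
(config, subject_id, seed) triple reproduces bit-identical output.

The phantom lives in its own template space by construction; no
registration is simulated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .atlas import AtlasROISet
from .ivim import IvimMaps, ivim_signal, IvimParams
from .morphometry import SagittalDiameters, SegmentationSet
from .scheme import BValueScheme, default_scheme
from .series import DwiSeries

__all__ = [
    "TissueIvim",
    "PhantomConfig",
    "PhantomSubject",
    "CohortStudy",
    "add_rician_noise",
    "generate_phantom",
    "generate_cohort",
]


@dataclass(frozen=True)
class TissueIvim:
    """Cohort distribution (mean, between-subject SD) of one tissue's
    IVIM parameters.  Rates in mm^2/s; f is a fraction."""

    f: float
    f_sd: float
    d: float
    d_sd: float
    d_star: float
    d_star_sd: float

    def __post_init__(self) -> None:
        for name in ("f_sd", "d_sd", "d_star_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# healthy-control group means/SDs of the emulated study
_HC_WM = TissueIvim(f=0.064, f_sd=0.015, d=4.0e-4, d_sd=0.6e-4, d_star=20.1e-3, d_star_sd=3.9e-3)
_HC_GM = TissueIvim(f=0.104, f_sd=0.017, d=4.3e-4, d_sd=0.6e-4, d_star=14.3e-3, d_star_sd=3.1e-3)

# subregion pseudo-diffusion means (mm^2/s) in the healthy cohort
_SUBREGION_D_STAR = {
    "ventral_funiculi": 19.9e-3,
    "lateral_funiculi": 22.1e-3,
    "dorsal_columns": 19.0e-3,
    "ventral_horns": 16.7e-3,
    "dorsal_horns": 17.5e-3,
}

_CLINICAL_RANGES = {
    "mjoa": (12, 18),
    "nurick": (0, 2),
    "uems": (45, 50),
    "clt": (24, 28),
    "cpp": (20, 28),
    "grassp": (108, 132),
}

_STENOSIS_LEVELS = ("C3-C4", "C4-C5", "C5-C6", "C6-C7")
_STENOSIS_PROBS = (0.172, 0.276, 0.517, 0.035)


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for the synthetic cohort.

    Geometry is per slice: an elliptical cord (semi-axes from the
    group's left-right width and anterior-posterior diameter) with a
    butterfly grey-matter template, voxelized on ``grid_shape`` at
    ``voxel_dims`` (mm).  Cross-sectional-area targets are hit by
    calibrating the shape scales against the voxelized area.

    ``snr`` is the b = 0 tissue signal (s0) divided by the Rician noise
    sigma; ``snr=None`` disables noise.  ``seed`` fixes every
    downstream draw.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 9)
    voxel_dims: tuple[float, float, float] = (0.5, 0.5, 5.0)
    scheme: BValueScheme = field(default_factory=default_scheme)
    s0: float = 1000.0
    snr: float | None = 50.0
    seed: int = 0

    # healthy-control morphometry (mm^2 / mm) and cohort variability
    wm_csa: float = 63.5
    wm_csa_sd: float = 8.0
    gm_csa: float = 14.4
    gm_csa_sd: float = 1.0
    hc_ap_diameter: float = 8.2
    hc_lr_width: float = 12.1
    dcm_ap_diameter: float = 7.6
    dcm_lr_width: float = 11.9

    # tissue IVIM cohort distributions (healthy reference)
    wm: TissueIvim = _HC_WM
    gm: TissueIvim = _HC_GM
    subregion_d_star: Mapping[str, float] = field(
        default_factory=lambda: dict(_SUBREGION_D_STAR)
    )
    within_subject_cv: float = 0.05  # voxel-level texture around subject means

    # patient-cohort effect multipliers
    dcm_d_star_mult: float = 0.9
    dcm_f_mult: float = 1.0
    dcm_d_mult: float = 1.0
    dcm_wm_csa_mult: float = 57.6 / 63.5
    dcm_gm_csa_mult: float = 13.5 / 14.4

    # lesions (patients with radiological myelopathy)
    lesion_fraction: float = 11.0 / 29.0
    lesion_radius_mm: float = 2.0

    # stenosis severity (percent) for patients
    mscc_mean: float = 25.7
    mscc_sd: float = 10.4
    mcc_mean: float = 39.5
    mcc_sd: float = 10.8
    canal_diameter: float = 14.0

    # demographics and clinical scores
    hc_age_mean: float = 55.4
    hc_age_sd: float = 12.1
    dcm_age_mean: float = 56.9
    dcm_age_sd: float = 11.3
    hc_female_fraction: float = 16.0 / 30.0
    dcm_female_fraction: float = 11.0 / 29.0
    missing_clinical_fraction: float = 3.0 / 29.0

    def __post_init__(self) -> None:
        if self.snr is not None and not self.snr > 0:
            raise ValueError(f"snr must be positive or None, got {self.snr}")
        if self.within_subject_cv < 0:
            raise ValueError("within_subject_cv must be >= 0")
        for name in ("dcm_d_star_mult", "dcm_f_mult", "dcm_d_mult",
                     "dcm_wm_csa_mult", "dcm_gm_csa_mult"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.lesion_fraction <= 1.0:
            raise ValueError("lesion_fraction must be in [0, 1]")

    @classmethod
    def smoke(cls, **overrides) -> "PhantomConfig":
        """A small, fast configuration for smoke tests and examples."""
        defaults = dict(
            grid_shape=(26, 26, 3),
            voxel_dims=(0.9, 0.9, 5.0),
            scheme=BValueScheme(
                tuple(np.arange(0.0, 651.0, 50.0)), n_directions=1, n_repetitions=2
            ),
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class PhantomSubject:
    """One generated subject: images, masks, ROIs, truth and a table row."""

    subject_id: str
    group: str
    dwi: DwiSeries | None
    seg: SegmentationSet | None
    rois: AtlasROISet | None
    truth: IvimMaps | None
    diameters: dict[str, SagittalDiameters] | None
    record: dict


@dataclass
class CohortStudy:
    """A generated cohort: per-subject table plus optional image data."""

    table: pd.DataFrame
    subjects: list[PhantomSubject]
    seed: int


def add_rician_noise(signal, sigma: float, seed=None) -> np.ndarray:
    """Corrupt a magnitude signal with Rician noise.

    Returns sqrt((S + n1)^2 + n2^2) with n1, n2 independent zero-mean
    Gaussians of SD ``sigma`` (the magnitude of a complex signal with
    Gaussian noise in both channels).  ``sigma=0`` returns the input
    unchanged.  ``seed`` may be an int or a numpy Generator.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


# ---------------------------------------------------------------------------
# geometry


def _grid_coords(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """In-plane mm coordinates; grid center offset by a sub-voxel amount
    so voxelized areas grow in ~single-voxel steps under scaling."""
    nx, ny, _ = config.grid_shape
    dx, dy, _ = config.voxel_dims
    cx = (nx - 1) / 2 + 0.217
    cy = (ny - 1) / 2 + 0.133
    x = (np.arange(nx) - cx) * dx
    y = (np.arange(ny) - cy) * dy
    return np.meshgrid(x, y, indexing="ij")


def _butterfly(u: np.ndarray, v: np.ndarray, t: float) -> np.ndarray:
    """Grey-matter butterfly in cord-normalized coordinates (anterior =
    negative v), scaled by t about the cord center."""

    def lobe(cx, cy, ax, ay):
        return ((u / t - cx) / ax) ** 2 + ((v / t - cy) / ay) ** 2 <= 1.0

    m = (
        lobe(0.40, -0.32, 0.27, 0.40)
        | lobe(-0.40, -0.32, 0.27, 0.40)
        | lobe(0.25, 0.42, 0.16, 0.38)
        | lobe(-0.25, 0.42, 0.16, 0.38)
        | lobe(0.0, 0.05, 0.50, 0.15)
    )
    return m & (u**2 + v**2 <= 0.93**2)


def _calibrate(area_fn, target: float, s_lo: float, s_hi: float, n: int = 1401) -> float:
    """Scale factor whose voxelized area is closest to ``target``."""
    scales = np.linspace(s_lo, s_hi, n)
    best_s, best_err = scales[0], np.inf
    for s in scales:
        err = abs(area_fn(s) - target)
        if err < best_err:
            best_s, best_err = s, err
    return float(best_s)


def _build_geometry(
    config: PhantomConfig,
    group: str,
    wm_csa_target: float,
    gm_csa_target: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelize cord and grey-matter masks (2D) hitting the CSA targets."""
    X, Y = _grid_coords(config)
    vox_area = config.voxel_dims[0] * config.voxel_dims[1]
    if group == "DCM":
        a0, b0 = config.dcm_lr_width / 2, config.dcm_ap_diameter / 2
    else:
        a0, b0 = config.hc_lr_width / 2, config.hc_ap_diameter / 2
    cord_target = wm_csa_target + gm_csa_target

    max_half = min(
        (config.grid_shape[0] - 2) * config.voxel_dims[0] / 2,
        (config.grid_shape[1] - 2) * config.voxel_dims[1] / 2,
    )
    s_guess = np.sqrt(cord_target / (np.pi * a0 * b0))
    if s_guess * max(a0, b0) > max_half:
        raise ValueError(
            f"cord semi-axis {s_guess * max(a0, b0):.1f} mm does not fit the "
            f"grid half-extent {max_half:.1f} mm; enlarge grid_shape"
        )

    def cord_area(s):
        return np.count_nonzero((X / (s * a0)) ** 2 + (Y / (s * b0)) ** 2 <= 1.0) * vox_area

    s_c = _calibrate(cord_area, cord_target, 0.85 * s_guess, 1.15 * s_guess)
    cord = (X / (s_c * a0)) ** 2 + (Y / (s_c * b0)) ** 2 <= 1.0

    U, V = X / (s_c * a0), Y / (s_c * b0)

    def gm_area(t):
        return np.count_nonzero(_butterfly(U, V, t) & cord) * vox_area

    t_g = _calibrate(gm_area, gm_csa_target, 0.35, 1.05)
    gm = _butterfly(U, V, t_g) & cord
    if not gm.any():
        raise ValueError("grey-matter template vanished at this grid resolution")
    return cord, gm


def _build_rois(cord2d: np.ndarray, gm2d: np.ndarray, config: PhantomConfig, nz: int):
    """Stack 2D masks into 3D volumes and carve atlas subregions."""
    X, Y = _grid_coords(config)
    wm2d = cord2d & ~gm2d
    # angle from the anterior axis (anterior = negative Y)
    ang = np.degrees(np.abs(np.arctan2(X, -Y)))
    vf2d = wm2d & (ang <= 50.0)
    dc2d = wm2d & (ang >= 130.0)
    lf2d = wm2d & ~vf2d & ~dc2d
    # horns split by the anterior-posterior coordinate, leaving a thin
    # commissural band unlabeled
    band = 0.08 * np.ptp(Y[gm2d]) if gm2d.any() else 0.0
    cy = Y[gm2d].mean()
    vh2d = gm2d & (Y < cy - band / 2)
    dh2d = gm2d & (Y > cy + band / 2)

    def stack(m):
        return np.repeat(m[:, :, None], nz, axis=2)

    rois = AtlasROISet(
        white_matter=stack(wm2d),
        grey_matter=stack(gm2d),
        ventral_funiculi=stack(vf2d),
        lateral_funiculi=stack(lf2d),
        dorsal_columns=stack(dc2d),
        ventral_horns=stack(vh2d),
        dorsal_horns=stack(dh2d),
        provenance="phantom",
    )
    return stack(cord2d), stack(gm2d), stack(wm2d), rois


def _level_labels(nz: int) -> tuple[str, ...]:
    """Split slices evenly into C1, C2, C3 (inferior slices last)."""
    thirds = np.array_split(np.arange(nz), 3)
    labels = []
    for level, idxs in zip(("C1", "C2", "C3"), thirds):
        labels.extend([level] * len(idxs))
    return tuple(labels)


# ---------------------------------------------------------------------------
# subject-level draws


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(subject_id.encode())])


def _truncnorm(rng, mean, sd, lo, hi):
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _draw_tissue_means(rng, tissue: TissueIvim, f_mult, d_mult, ds_mult) -> dict:
    f = _truncnorm(rng, tissue.f * f_mult, tissue.f_sd, 0.005, 0.5)
    d = _truncnorm(rng, tissue.d * d_mult, tissue.d_sd, 5e-5, 3e-3)
    ds = _truncnorm(rng, tissue.d_star * ds_mult, tissue.d_star_sd, max(3 * d, 1e-3), 0.09)
    return {"f": f, "d": d, "d_star": ds}


def _draw_subject(config: PhantomConfig, subject_id: str, group: str,
                  myelopathy: bool, rng: np.random.Generator) -> dict:
    """Subject-level ground truth: tissue means, morphometry targets,
    demographics and clinical scores (one table row)."""
    dcm = group == "DCM"
    f_m = config.dcm_f_mult if dcm else 1.0
    d_m = config.dcm_d_mult if dcm else 1.0
    ds_m = config.dcm_d_star_mult if dcm else 1.0
    wm_means = _draw_tissue_means(rng, config.wm, f_m, d_m, ds_m)
    gm_means = _draw_tissue_means(rng, config.gm, f_m, d_m, ds_m)

    sub_means = {}
    for name, ds_mean in config.subregion_d_star.items():
        tissue = wm_means if name in ("ventral_funiculi", "lateral_funiculi",
                                      "dorsal_columns") else gm_means
        ref = config.wm.d_star if tissue is wm_means else config.gm.d_star
        sub_means[name] = dict(tissue)
        sub_means[name]["d_star"] = tissue["d_star"] * (ds_mean / ref)

    wm_csa_t = _truncnorm(
        rng, config.wm_csa * (config.dcm_wm_csa_mult if dcm else 1.0),
        config.wm_csa_sd, 20.0, 120.0)
    gm_csa_t = _truncnorm(
        rng, config.gm_csa * (config.dcm_gm_csa_mult if dcm else 1.0),
        config.gm_csa_sd, 5.0, 30.0)
    if dcm:
        a0, b0 = config.dcm_lr_width / 2, config.dcm_ap_diameter / 2
        age = _truncnorm(rng, config.dcm_age_mean, config.dcm_age_sd, 18, 75)
        female = rng.random() < config.dcm_female_fraction
    else:
        a0, b0 = config.hc_lr_width / 2, config.hc_ap_diameter / 2
        age = _truncnorm(rng, config.hc_age_mean, config.hc_age_sd, 18, 75)
        female = rng.random() < config.hc_female_fraction
    s = np.sqrt((wm_csa_t + gm_csa_t) / (np.pi * a0 * b0))

    record = {
        "subject_id": subject_id,
        "group": group,
        "age": round(age, 1),
        "sex": "F" if female else "M",
        "myelopathy": bool(myelopathy),
        "wm_csa": wm_csa_t,
        "gm_csa": gm_csa_t,
        "ap_diameter": 2 * b0 * s,
        "lr_width": 2 * a0 * s,
    }
    for tissue, means in (("wm", wm_means), ("gm", gm_means)):
        record[f"f_{tissue}"] = means["f"] * 100.0  # reported in percent
        record[f"d_{tissue}"] = means["d"]
        record[f"dstar_{tissue}"] = means["d_star"]
        record[f"fdstar_{tissue}"] = means["f"] * means["d_star"]
    for name, means in sub_means.items():
        record[f"dstar_{name}"] = means["d_star"]
        record[f"fdstar_{name}"] = means["f"] * means["d_star"]

    if dcm:
        mscc = _truncnorm(rng, config.mscc_mean, config.mscc_sd, 2.0, 60.0)
        mcc = _truncnorm(rng, config.mcc_mean, config.mcc_sd, 2.0, 70.0)
        record["mscc"] = mscc
        record["mcc"] = mcc
        record["stenosis_level"] = str(
            rng.choice(_STENOSIS_LEVELS, p=np.asarray(_STENOSIS_PROBS) /
                       sum(_STENOSIS_PROBS))
        )
        missing = rng.random() < config.missing_clinical_fraction
        for score, (lo, hi) in _CLINICAL_RANGES.items():
            record[score] = np.nan if missing else int(rng.integers(lo, hi + 1))
    else:
        record["mscc"] = np.nan
        record["mcc"] = np.nan
        record["stenosis_level"] = ""
        for score in _CLINICAL_RANGES:
            record[score] = np.nan

    record["_wm_means"] = wm_means
    record["_gm_means"] = gm_means
    record["_sub_means"] = sub_means
    return record


def _sample_diameters(record: dict, config: PhantomConfig, rng) -> dict[str, SagittalDiameters]:
    """Mid-sagittal diameters consistent with the drawn MSCC/MCC."""
    out = {}
    ap = record["ap_diameter"]
    for target, ref, key in (("cord", ap, "mscc"), ("canal", config.canal_diameter, "mcc")):
        ratio = record[key]
        ratio = 0.0 if np.isnan(ratio) else ratio
        d_a = ref * (1 + rng.normal(0, 0.02))
        d_b = ref * (1 + rng.normal(0, 0.02))
        d_i = (1 - ratio / 100.0) * (d_a + d_b) / 2.0
        out[target] = SagittalDiameters(d_i=d_i, d_a=d_a, d_b=d_b, target=target)
    return out


# ---------------------------------------------------------------------------
# voxel synthesis


def _voxel_truth_maps(config, record, cord, gm, rois, rng) -> IvimMaps:
    """Per-voxel ground-truth parameter maps: subject means plus
    multiplicative within-subject texture."""
    shape = cord.shape
    cv = config.within_subject_cv

    f = np.full(shape, np.nan)
    d = np.full(shape, np.nan)
    ds = np.full(shape, np.nan)

    def fill(mask, means):
        n = int(mask.sum())
        if n == 0:
            return
        for arr, key, lo, hi in (
            (f, "f", 1e-3, 0.5),
            (d, "d", 5e-5, 3e-3),
            (ds, "d_star", 1e-3, 0.099),
        ):
            vals = means[key] * (1.0 + cv * rng.standard_normal(n))
            arr[mask] = np.clip(vals, lo, hi)

    # tissue background first, then subregion-specific pseudo-diffusion
    fill(rois.white_matter, record["_wm_means"])
    fill(rois.grey_matter, record["_gm_means"])
    for name, means in record["_sub_means"].items():
        mask = getattr(rois, name)
        n = int(mask.sum())
        if n:
            ds[mask] = np.clip(
                means["d_star"] * (1.0 + cv * rng.standard_normal(n)), 1e-3, 0.099
            )
    ds = np.where(np.isfinite(ds) & np.isfinite(d), np.maximum(ds, 2.0 * d), ds)

    s0 = np.where(cord, config.s0, np.nan)
    return IvimMaps(
        s0_map=s0, f_map=f, d_map=d, d_star_map=ds, fd_star_map=f * ds, qc_mask=cord
    )


def _synthesize_dwi(config: PhantomConfig, truth: IvimMaps, cord, rng) -> DwiSeries:
    scheme = config.scheme
    shape = cord.shape
    nvol = scheme.n_volumes
    signal = np.zeros(shape + (nvol,), dtype=float)

    b_arr = scheme.b_array()
    f, d, ds, s0 = truth.f_map, truth.d_map, truth.d_star_map, truth.s0_map
    base = np.zeros(shape + (scheme.n_bvalues,), dtype=float)
    for ib, b in enumerate(b_arr):
        sb = np.zeros(shape)
        sb[cord] = (
            s0[cord]
            * np.exp(-b * d[cord])
            * (f[cord] * np.exp(-b * ds[cord]) + 1.0 - f[cord])
        )
        base[..., ib] = sb

    sigma = 0.0 if config.snr is None else config.s0 / config.snr
    table = scheme.volume_table()
    for vi in range(nvol):
        ib = int(np.searchsorted(b_arr, table[vi, 0]))
        signal[..., vi] = add_rician_noise(base[..., ib], sigma, seed=rng)
    return DwiSeries(signal=signal, scheme=scheme, voxel_dims=config.voxel_dims)


def _lesion_mask(config, cord, gm, myelopathy: bool) -> np.ndarray:
    lesion = np.zeros_like(cord)
    if not myelopathy:
        return lesion
    X, Y = _grid_coords(config)
    nz = cord.shape[2]
    gm2d = gm[:, :, 0]
    cx, cy = X[gm2d].mean(), Y[gm2d].mean()
    blob2d = ((X - cx) ** 2 + (Y - cy) ** 2 <= config.lesion_radius_mm**2) & cord[:, :, 0]
    z_mid = list(range(nz // 3, nz - nz // 3)) or [nz // 2]
    for z in z_mid:
        lesion[:, :, z] = blob2d
    return lesion


def generate_phantom(
    config: PhantomConfig,
    subject_id: str = "HC01",
    group: str = "HC",
    myelopathy: bool = False,
) -> PhantomSubject:
    """Generate one fully imaged synthetic subject.

    Returns a :class:`PhantomSubject` carrying the noisy DWI series, the
    segmentation masks (grey matter strictly inside the cord, white
    matter = cord minus grey matter), the atlas ROI set, the voxel-wise
    ground-truth IVIM maps, sagittal diameters for MSCC/MCC, and the
    subject's table row.  Identical (config, subject_id) input
    reproduces bit-identical output.
    """
    if group not in ("HC", "DCM"):
        raise ValueError(f"group must be 'HC' or 'DCM', got {group!r}")
    rng = _subject_rng(config.seed, subject_id)
    record = _draw_subject(config, subject_id, group, myelopathy, rng)

    cord2d, gm2d = _build_geometry(config, group, record["wm_csa"], record["gm_csa"])
    nz = config.grid_shape[2]
    cord, gm3d, wm3d, rois = _build_rois(cord2d, gm2d, config, nz)
    lesion = _lesion_mask(config, cord, gm3d, myelopathy)
    seg = SegmentationSet(
        cord_mask=cord,
        wm_mask=wm3d,
        gm_mask=gm3d,
        lesion_mask=lesion,
        level_labels=_level_labels(nz),
        voxel_dims=config.voxel_dims,
    )
    truth = _voxel_truth_maps(config, record, cord, gm3d, rois, rng)
    dwi = _synthesize_dwi(config, truth, cord, rng)
    diameters = _sample_diameters(record, config, rng)
    return PhantomSubject(
        subject_id=subject_id,
        group=group,
        dwi=dwi,
        seg=seg,
        rois=rois,
        truth=truth,
        diameters=diameters,
        record=record,
    )


def _public_record(record: dict) -> dict:
    return {k: v for k, v in record.items() if not k.startswith("_")}


def generate_cohort(
    config: PhantomConfig,
    n_hc: int,
    n_dcm: int,
    seed: int | None = None,
    images: bool = False,
) -> CohortStudy:
    """Generate a two-cohort study.

    With ``images=False`` (the default) only subject-level ground truth
    is drawn — tissue/subregion means, morphometry targets,
    demographics, stenosis metrics and clinical scores — which is what
    the statistics layer consumes; with ``images=True`` each subject
    additionally carries its full phantom (DWI, masks, ROIs, truth
    maps).  A configurable fraction of patients carries a lesion.
    """
    if n_hc < 1 or n_dcm < 1:
        raise ValueError(f"need at least one subject per group, got {n_hc}/{n_dcm}")
    seed = config.seed if seed is None else seed
    cfg = replace(config, seed=seed)
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xC0F0])
    n_lesion = int(round(cfg.lesion_fraction * n_dcm))
    lesion_ids = set(rng.choice(n_dcm, size=n_lesion, replace=False).tolist())

    subjects: list[PhantomSubject] = []
    rows = []
    for gi, (group, n) in enumerate((("HC", n_hc), ("DCM", n_dcm))):
        for i in range(n):
            sid = f"{group}{i + 1:02d}"
            myelo = group == "DCM" and i in lesion_ids
            if images:
                subj = generate_phantom(cfg, sid, group, myelopathy=myelo)
                subjects.append(subj)
                rows.append(_public_record(subj.record))
            else:
                sr = _subject_rng(cfg.seed, sid)
                rows.append(_public_record(_draw_subject(cfg, sid, group, myelo, sr)))
    table = pd.DataFrame(rows)
    return CohortStudy(table=table, subjects=subjects, seed=seed)
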