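"""Biexponential intravoxel-incoherent-motion (IVIM) model and fitting.

The IVIM signal model separates slow tissue-water diffusion from the fast
pseudo-diffusion of blood moving through randomly oriented capillaries:

    S(b) = S0 * exp(-b*D) * [ F*exp(-b*D*) + 1 - F ]

where F is the microvascular volume fraction, D the tissue diffusion
coefficient (mm^2/s) and D* the pseudo-diffusion coefficient (mm^2/s),
interpreted as a blood-velocity index.  The product F*D* serves as a
blood-flow index.

Fitting strategy
----------------
D and D* differ by roughly two orders of magnitude, which makes a naive
joint fit poorly conditioned.  The solver therefore uses the segmented
approach: (1) log-linear fit of D and intercept on the high-b regime
(b >= ``high_b_threshold``, default 300 s/mm^2) where the perfusion
compartment has decayed away; (2) bounded nonlinear least squares for F
and D* on all b with D fixed and S0 taken from the b = 0 signal; and by
default (3) a bounded joint refinement of all four parameters started
from the segmented estimate.  The refinement removes the small bias the
segmented stages inherit from residual perfusion signal above the high-b
threshold while keeping the segmented stages' robustness as
initialization.  Pure segmented output is available with
``refine=False``; a joint fit from generic starting values with
``mode="full"``.

D* >= D is enforced through the parameterization (the refinement fits
delta = D* - D >= 0), since a pseudo-diffusion slower than tissue
diffusion is not identifiable as a perfusion compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .scheme import BValueScheme
from .series import DwiSeries

__all__ = [
    "IvimParams",
    "IvimMaps",
    "FitOptions",
    "VoxelFit",
    "ivim_signal",
    "fit_ivim_voxel",
    "fit_ivim_volume",
]


@dataclass(frozen=True)
class IvimParams:
    """One voxel's IVIM parameters.

    s0 : unweighted signal amplitude (arbitrary units), > 0
    f : microvascular volume fraction, in [0, 1] (dimensionless; report as %)
    d : diffusion coefficient, mm^2/s, > 0
    d_star : pseudo-diffusion coefficient, mm^2/s, >= d
    """

    s0: float
    f: float
    d: float
    d_star: float

    def __post_init__(self) -> None:
        if not self.s0 > 0:
            raise ValueError(f"s0 must be positive, got {self.s0}")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must be in [0, 1], got {self.f}")
        if not self.d > 0:
            raise ValueError(f"d must be positive, got {self.d}")
        if self.d_star < self.d:
            raise ValueError(
                f"d_star ({self.d_star}) must be >= d ({self.d}); a perfusion "
                "compartment slower than tissue diffusion is not identifiable"
            )

    @property
    def fd_star(self) -> float:
        """Blood-flow index F*D* (mm^2/s)."""
        return self.f * self.d_star


@dataclass
class IvimMaps:
    """Voxel-wise IVIM parameter maps sharing one grid.

    Maps hold NaN outside ``qc_mask`` (voxels with no converged,
    in-bounds fit); ``fd_star_map`` is the voxel-wise product of
    ``f_map`` and ``d_star_map`` wherever qc is true.
    """

    s0_map: np.ndarray
    f_map: np.ndarray
    d_map: np.ndarray
    d_star_map: np.ndarray
    fd_star_map: np.ndarray
    qc_mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {
            m.shape
            for m in (
                self.s0_map,
                self.f_map,
                self.d_map,
                self.d_star_map,
                self.fd_star_map,
                self.qc_mask,
            )
        }
        if len(shapes) != 1:
            raise ValueError(f"all maps must share one grid, got shapes {shapes}")
        self.qc_mask = self.qc_mask.astype(bool)


@dataclass(frozen=True)
class FitOptions:
    """Configuration of the voxel-wise IVIM fit.

    mode : "segmented" (default) or "full".  Segmented = log-linear D on
        the high-b regime then (F, D*) with D fixed; full = joint
        4-parameter fit from generic starting values.
    refine : run the bounded joint 4-parameter refinement after the
        segmented stages (ignored for mode="full").
    high_b_threshold : b-value (s/mm^2) above which the perfusion
        compartment is treated as fully decayed in stage 1.
    Bounds: F in [f_min, f_max], D in [d_min, d_max], D* in
        [max(D, d_star_min), d_star_max], all rates in mm^2/s.
    """

    mode: str = "segmented"
    refine: bool = True
    high_b_threshold: float = 300.0
    f_min: float = 0.0
    f_max: float = 0.5
    d_min: float = 1e-5
    d_max: float = 3e-3
    d_star_min: float = 1e-4
    d_star_max: float = 1e-1

    def __post_init__(self) -> None:
        if self.mode not in ("segmented", "full"):
            raise ValueError(f"mode must be 'segmented' or 'full', got {self.mode!r}")
        if self.high_b_threshold <= 0:
            raise ValueError("high_b_threshold must be positive")


@dataclass
class VoxelFit:
    """Result of one voxel fit: parameters, residuals and a QC verdict.

    ``success`` is False for non-converged fits and for fits whose D*
    is pinned at the upper bound (an unidentifiable perfusion
    compartment); such voxels are excluded via the qc mask downstream,
    never zero-filled.
    """

    params: IvimParams
    rss: float
    rss_mono: float
    success: bool
    message: str = ""


def ivim_signal(b, params: IvimParams):
    """Evaluate the biexponential IVIM model S(b).

    Parameters
    ----------
    b : scalar or array of b-values (s/mm^2), non-negative.
    params : IvimParams (validated on construction).

    Returns
    -------
    Signal of the same shape as ``b``; S(0) = s0 and the signal is
    strictly decreasing in b for d > 0.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError(f"b-values must be non-negative, got min {b.min()}")
    out = params.s0 * np.exp(-b * params.d) * (
        params.f * np.exp(-b * params.d_star) + 1.0 - params.f
    )
    return out if out.ndim else float(out)


def _model(b: np.ndarray, s0: float, f: float, d: float, d_star: float) -> np.ndarray:
    return s0 * np.exp(-b * d) * (f * np.exp(-b * d_star) + 1.0 - f)


def _fit_mono(b: np.ndarray, s: np.ndarray, opts: FitOptions) -> tuple[float, float, float]:
    """Monoexponential S0*exp(-b*D) fit; returns (s0, d, rss)."""
    coeff = np.polyfit(b, np.log(s), 1)
    d0 = float(np.clip(-coeff[0], opts.d_min, opts.d_max))
    s00 = float(np.exp(coeff[1]))

    def resid(x):
        return x[0] * np.exp(-b * x[1]) - s

    sol = least_squares(
        resid,
        x0=[max(s00, 1e-12), d0],
        bounds=([1e-12, opts.d_min], [np.inf, opts.d_max]),
        method="trf",
    )
    return float(sol.x[0]), float(sol.x[1]), float(np.sum(sol.fun**2))


def fit_ivim_voxel(
    signal_by_b,
    scheme: BValueScheme | np.ndarray,
    options: FitOptions | None = None,
) -> VoxelFit:
    """Fit the IVIM model to one voxel's per-b-value signal.

    Parameters
    ----------
    signal_by_b
        One (repetition-averaged) positive signal value per b-value.
    scheme
        A :class:`BValueScheme` or a bare array of b-values.
    options
        :class:`FitOptions`; defaults to the segmented fit with joint
        refinement.

    Returns
    -------
    VoxelFit
        Fitted parameters with the residual sum of squares of the IVIM
        fit and of the nested monoexponential (F = 0) fit.  The IVIM
        residual never exceeds the monoexponential one: if the
        biexponential solver ends worse, the monoexponential solution
        (f = 0, d_star = d) is returned instead.
    """
    opts = options or FitOptions()
    b = scheme.b_array() if isinstance(scheme, BValueScheme) else np.asarray(scheme, float)
    s = np.asarray(signal_by_b, dtype=float)
    if s.shape != b.shape:
        raise ValueError(f"need one signal per b-value: signal {s.shape}, b {b.shape}")
    if len(np.unique(b)) < 4:
        raise ValueError("at least 4 distinct b-values are required (4 free parameters)")
    if np.any(s <= 0):
        raise ValueError("signals must be strictly positive for fitting")

    s0_obs = float(s[b == b.min()].mean()) if b.min() == 0 else float(s.max())
    s0_mono, d_mono, rss_mono = _fit_mono(b, s, opts)

    if opts.mode == "segmented":
        x0, message = _segmented_start(b, s, s0_obs, opts)
        if opts.refine:
            fit = _joint_fit(b, s, x0, opts)
        else:
            fit = x0
    else:
        d0 = float(np.clip(d_mono, opts.d_min, opts.d_max))
        generic = np.array([s0_obs, 0.1, d0, max(10 * d0 - d0, opts.d_star_min)])
        fit = _joint_fit(b, s, generic, opts)
        message = "full joint fit"

    s0_hat, f_hat, d_hat, delta_hat = fit
    d_star_hat = d_hat + delta_hat
    rss = float(np.sum((_model(b, s0_hat, f_hat, d_hat, d_star_hat) - s) ** 2))

    # nesting guarantee: never return a fit worse than the F=0 model
    if rss > rss_mono:
        params = IvimParams(s0=s0_mono, f=0.0, d=d_mono, d_star=d_mono)
        return VoxelFit(params, rss_mono, rss_mono, True, "fell back to monoexponential")

    pinned = d_star_hat >= 0.98 * opts.d_star_max
    params = IvimParams(s0=s0_hat, f=f_hat, d=d_hat, d_star=d_star_hat)
    if pinned:
        return VoxelFit(params, rss, rss_mono, False, "d_star pinned at upper bound")
    return VoxelFit(params, rss, rss_mono, True, message)


def _segmented_start(
    b: np.ndarray, s: np.ndarray, s0_obs: float, opts: FitOptions
) -> tuple[np.ndarray, str]:
    """Stages 1-2 of the segmented fit; returns (s0, f, d, delta) and a note."""
    high = b >= opts.high_b_threshold
    if high.sum() < 2:
        raise ValueError(
            f"need >= 2 b-values above the high-b threshold "
            f"({opts.high_b_threshold} s/mm^2), got {int(high.sum())}"
        )
    slope, intercept = np.polyfit(b[high], np.log(s[high]), 1)
    d0 = float(np.clip(-slope, opts.d_min, opts.d_max))
    # S_high ~ S0*(1-F)*exp(-bD)  =>  F = 1 - exp(intercept)/S0
    f0 = float(np.clip(1.0 - np.exp(intercept) / s0_obs, opts.f_min, opts.f_max))
    ds0 = float(np.clip(10.0 * d0, max(opts.d_star_min, d0 * 1.01), opts.d_star_max))

    def resid_stage2(x):
        f, d_star = x
        return _model(b, s0_obs, f, d0, d_star) - s

    sol = least_squares(
        resid_stage2,
        x0=[f0, ds0],
        bounds=([opts.f_min, d0], [opts.f_max, opts.d_star_max]),
        method="trf",
    )
    f1, d_star1 = sol.x
    return (
        np.array([s0_obs, float(f1), d0, max(float(d_star1) - d0, 0.0)]),
        "segmented fit",
    )


def _joint_fit(b: np.ndarray, s: np.ndarray, x0: np.ndarray, opts: FitOptions) -> np.ndarray:
    """Bounded joint fit of (s0, f, d, delta) with d_star = d + delta."""

    def resid(x):
        s0, f, d, delta = x
        return _model(b, s0, f, d, d + delta) - s

    lo = [1e-12, opts.f_min, opts.d_min, 0.0]
    hi = [np.inf, opts.f_max, opts.d_max, opts.d_star_max]
    x0 = np.clip(x0, lo, hi)
    sol = least_squares(resid, x0=x0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14)
    return sol.x


def fit_ivim_volume(
    dwi: DwiSeries,
    mask: np.ndarray,
    options: FitOptions | None = None,
) -> IvimMaps:
    """Fit the IVIM model over a masked volume.

    Repetitions are arithmetically averaged per (b, direction); each
    direction's averaged signal is fitted independently and the
    parameter maps are then averaged across directions (over the
    directions whose fit converged).  ``qc_mask`` is true only where
    every direction converged; maps hold NaN elsewhere and failed
    voxels are never zero-filled.
    """
    mask = np.asarray(mask) > 0
    if mask.shape != dwi.shape:
        raise ValueError(f"mask grid {mask.shape} does not match series grid {dwi.shape}")
    if not mask.any():
        raise ValueError("mask is empty: no voxels to fit")
    opts = options or FitOptions()

    avg = dwi.average_repetitions()  # (nx, ny, nz, n_b, n_dir)
    n_dir = dwi.scheme.n_directions
    b = dwi.scheme.b_array()

    shape = dwi.shape
    acc = {k: np.full(shape, np.nan) for k in ("s0", "f", "d", "d_star")}
    n_ok = np.zeros(shape, dtype=int)
    failures: list[tuple[tuple[int, int, int], str]] = []

    idx = np.argwhere(mask)
    for (i, j, k) in idx:
        sums = {key: 0.0 for key in acc}
        ok = 0
        for di in range(n_dir):
            sig = avg[i, j, k, :, di]
            if np.any(sig <= 0):
                failures.append(((i, j, k), f"direction {di}: non-positive signal"))
                continue
            try:
                fit = fit_ivim_voxel(sig, b, opts)
            except ValueError as exc:
                failures.append(((i, j, k), f"direction {di}: {exc}"))
                continue
            if not fit.success:
                failures.append(((i, j, k), f"direction {di}: {fit.message}"))
                continue
            ok += 1
            p = fit.params
            sums["s0"] += p.s0
            sums["f"] += p.f
            sums["d"] += p.d
            sums["d_star"] += p.d_star
        n_ok[i, j, k] = ok
        if ok == n_dir:
            for key in acc:
                acc[key][i, j, k] = sums[key] / ok

    qc = n_ok == n_dir
    qc &= mask
    if not qc.any():
        lines = "; ".join(f"{pos}: {msg}" for pos, msg in failures[:10])
        raise RuntimeError(
            f"IVIM fit failed in every one of the {int(mask.sum())} masked voxels. "
            f"First diagnostics: {lines}"
        )
    for key in acc:
        acc[key][~qc] = np.nan
    return IvimMaps(
        s0_map=acc["s0"],
        f_map=acc["f"],
        d_map=acc["d"],
        d_star_map=acc["d_star"],
        fd_star_map=acc["f"] * acc["d_star"],
        qc_mask=qc,
    )
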