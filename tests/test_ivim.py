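"""IVIM signal model and voxel-wise fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cordivim import (
    BValueScheme,
    FitOptions,
    IvimParams,
    add_rician_noise,
    default_scheme,
    fit_ivim_voxel,
    ivim_signal,
)
from conftest import HC_GM, HC_WM


valid_params = st.builds(
    IvimParams,
    s0=st.floats(0.5, 2000.0),
    f=st.floats(0.0, 0.4),
    d=st.floats(1e-4, 3e-3),
    d_star=st.floats(5e-3, 5e-2),
)


class TestIvimSignal:
    @given(valid_params)
    @settings(derandomize=True, max_examples=50)
    def test_unweighted_signal_is_s0(self, p):
        assert ivim_signal(0.0, p) == pytest.approx(p.s0, rel=1e-12)

    @given(valid_params)
    @settings(derandomize=True, max_examples=50)
    def test_strictly_decreasing_in_b(self, p):
        b = np.linspace(0, 650, 14)
        s = ivim_signal(b, p)
        assert np.all(np.diff(s) < 0)
        assert np.all(s > 0) and np.all(s <= p.s0)

    def test_monoexponential_limit(self):
        # F = 0 reduces the model to S0 * exp(-b D)
        p = IvimParams(s0=1.0, f=0.0, d=1e-3, d_star=1e-3)
        assert ivim_signal(650.0, p) == pytest.approx(np.exp(-0.65), rel=1e-12)

    def test_healthy_grey_matter_value_at_b50(self):
        # closed-form oracle: S0 e^{-bD} [F e^{-bD*} + 1 - F] at b = 50
        assert ivim_signal(50.0, HC_GM) == pytest.approx(0.9267354, abs=5e-7)

    def test_negative_b_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ivim_signal(-1.0, HC_GM)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(s0=0.0, f=0.1, d=1e-3, d_star=1e-2),
            dict(s0=1.0, f=1.1, d=1e-3, d_star=1e-2),
            dict(s0=1.0, f=0.1, d=-1e-3, d_star=1e-2),
            dict(s0=1.0, f=0.1, d=1e-2, d_star=1e-3),  # d_star < d
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            IvimParams(**kwargs)


class TestVoxelFit:
    @pytest.mark.parametrize("truth", [HC_GM, HC_WM], ids=["gm", "wm"])
    def test_noiseless_round_trip(self, truth):
        scheme = default_scheme()
        signal = ivim_signal(scheme.b_array(), truth)
        fit = fit_ivim_voxel(signal, scheme)
        assert fit.success
        p = fit.params
        assert p.f == pytest.approx(truth.f, rel=1e-4)
        assert p.d == pytest.approx(truth.d, rel=1e-4)
        assert p.d_star == pytest.approx(truth.d_star, rel=1e-4)
        assert p.s0 == pytest.approx(truth.s0, rel=1e-4)

    def test_pure_monoexponential_gives_zero_f(self):
        scheme = default_scheme()
        p = IvimParams(s0=1.0, f=0.0, d=4e-4, d_star=4e-4)
        fit = fit_ivim_voxel(ivim_signal(scheme.b_array(), p), scheme)
        assert fit.success
        assert fit.params.f <= 1e-3

    def test_biexponential_never_worse_than_monoexponential(self):
        # nesting: the returned residual is bounded by the F=0 fit's
        scheme = default_scheme()
        rng = np.random.default_rng(3)
        clean = ivim_signal(scheme.b_array(), IvimParams(1000.0, 0.064, 4.0e-4, 20.1e-3))
        for _ in range(25):
            noisy = add_rician_noise(clean, 1000.0 / 30.0, seed=rng)
            fit = fit_ivim_voxel(noisy, scheme)
            assert fit.rss <= fit.rss_mono * (1 + 1e-12)

    def test_grid_search_oracle_agreement(self):
        # brute-force lattice search over (F, D, D*) as independent oracle
        scheme = default_scheme()
        b = scheme.b_array()
        truth = IvimParams(s0=1.0, f=0.10, d=5e-4, d_star=15e-3)
        signal = ivim_signal(b, truth)

        f_grid = np.linspace(0.0, 0.3, 61)
        d_grid = np.linspace(1e-4, 1e-3, 91)
        ds_grid = np.linspace(5e-3, 3e-2, 101)
        F, D, DS = np.meshgrid(f_grid, d_grid, ds_grid, indexing="ij")
        pred = np.exp(-b[None, None, None, :] * D[..., None]) * (
            F[..., None] * np.exp(-b[None, None, None, :] * DS[..., None])
            + 1.0
            - F[..., None]
        )
        sse = ((pred - signal) ** 2).sum(axis=-1)
        i, j, k = np.unravel_index(np.argmin(sse), sse.shape)

        fit = fit_ivim_voxel(signal, scheme).params
        assert abs(fit.f - f_grid[i]) <= f_grid[1] - f_grid[0]
        assert abs(fit.d - d_grid[j]) <= d_grid[1] - d_grid[0]
        assert abs(fit.d_star - ds_grid[k]) <= ds_grid[1] - ds_grid[0]

    def test_monte_carlo_f_recovery_at_snr50(self):
        # 1000 Rician replicates of the repetition-averaged white-matter
        # signal at SNR 50; median microvascular fraction within 20%
        scheme = default_scheme()
        truth = IvimParams(s0=1000.0, f=0.064, d=4.0e-4, d_star=20.1e-3)
        clean = ivim_signal(scheme.b_array(), truth)
        rng = np.random.default_rng(42)
        estimates = []
        for _ in range(1000):
            reps = add_rician_noise(
                np.tile(clean, (scheme.n_repetitions, 1)), 1000.0 / 50.0, seed=rng
            )
            fit = fit_ivim_voxel(reps.mean(axis=0), scheme)
            if fit.success:
                estimates.append(fit.params.f)
        assert len(estimates) > 900
        assert np.median(estimates) == pytest.approx(truth.f, rel=0.2)

    def test_too_few_bvalues_rejected(self):
        with pytest.raises(ValueError, match="4 distinct b-values"):
            fit_ivim_voxel([1.0, 0.9, 0.8], np.array([0.0, 100.0, 300.0]))

    def test_nonpositive_signal_rejected(self):
        b = np.array([0.0, 100.0, 300.0, 500.0, 650.0])
        with pytest.raises(ValueError, match="positive"):
            fit_ivim_voxel([1.0, 0.9, 0.0, 0.5, 0.4], b)

    def test_segmented_without_refinement_close_but_biased(self):
        # the pure segmented fit carries a small D bias from residual
        # perfusion signal above the high-b threshold
        scheme = default_scheme()
        signal = ivim_signal(scheme.b_array(), HC_GM)
        fit = fit_ivim_voxel(signal, scheme, FitOptions(refine=False))
        assert fit.success
        assert fit.params.d == pytest.approx(HC_GM.d, rel=0.05)

    def test_full_mode_recovers_noiseless(self):
        scheme = default_scheme()
        signal = ivim_signal(scheme.b_array(), HC_WM)
        fit = fit_ivim_voxel(signal, scheme, FitOptions(mode="full"))
        assert fit.success
        assert fit.params.d_star == pytest.approx(HC_WM.d_star, rel=1e-3)
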