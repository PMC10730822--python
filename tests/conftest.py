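import dataclasses

import numpy as np
import pytest

from cordivim import BValueScheme, IvimParams, PhantomConfig, generate_phantom

# healthy-control group-mean IVIM parameters used as ground truth
HC_GM = IvimParams(s0=1.0, f=0.104, d=4.3e-4, d_star=14.3e-3)
HC_WM = IvimParams(s0=1.0, f=0.064, d=4.0e-4, d_star=20.1e-3)


@pytest.fixture(scope="session")
def hc_params():
    return {"gm": HC_GM, "wm": HC_WM}


def small_config(**overrides) -> PhantomConfig:
    """A fast phantom configuration for tests: small grid, single
    direction/repetition, no noise, no between-subject variability
    (tissue parameters sit exactly at the group means)."""
    base = PhantomConfig()
    defaults = dict(
        wm=dataclasses.replace(base.wm, f_sd=0.0, d_sd=0.0, d_star_sd=0.0),
        gm=dataclasses.replace(base.gm, f_sd=0.0, d_sd=0.0, d_star_sd=0.0),
        grid_shape=(26, 26, 3),
        voxel_dims=(0.9, 0.9, 5.0),
        scheme=BValueScheme(
            tuple(np.arange(0.0, 651.0, 50.0)), n_directions=1, n_repetitions=1
        ),
        snr=None,
        wm_csa_sd=0.0,
        gm_csa_sd=0.0,
        within_subject_cv=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom subject with exact tissue parameters."""
    return generate_phantom(small_config(), "HC01", "HC")


@pytest.fixture(scope="session")
def noisy_phantom():
    """SNR-50 phantom with the full 3-direction, 20-repetition scheme."""
    cfg = small_config(
        grid_shape=(26, 26, 2),
        scheme=BValueScheme(
            tuple(np.arange(0.0, 651.0, 50.0)), n_directions=3, n_repetitions=20
        ),
        snr=50.0,
        within_subject_cv=0.05,
    )
    return generate_phantom(cfg, "HC01", "HC")
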