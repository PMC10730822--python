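"""Biexponential IVIM signal and voxel-wise fitting.

Synthesizes a single voxel's diffusion-decay curve with healthy
grey-matter parameters, fits it back noiselessly, then repeats with
Rician noise at SNR 50 on repetition-averaged data — the round trip
shows what the fitter recovers under ideal and realistic conditions.
"""

import numpy as np

from cordivim import (
    IvimParams,
    add_rician_noise,
    default_scheme,
    fit_ivim_voxel,
    ivim_signal,
)

truth = IvimParams(s0=1000.0, f=0.104, d=4.3e-4, d_star=14.3e-3)
scheme = default_scheme()
b = scheme.b_array()
clean = ivim_signal(b, truth)

print("b [s/mm^2] :", " ".join(f"{x:4.0f}" for x in b))
print("S(b)/S0    :", " ".join(f"{x:4.2f}" for x in clean / truth.s0))

fit = fit_ivim_voxel(clean, scheme).params
print(f"\nnoiseless fit : F = {fit.f * 100:.2f} %, "
      f"D = {fit.d * 1e4:.2f} x 1e-4 mm^2/s, D* = {fit.d_star * 1e3:.2f} x 1e-3 mm^2/s")

rng = np.random.default_rng(0)
reps = add_rician_noise(np.tile(clean, (scheme.n_repetitions, 1)), truth.s0 / 50, seed=rng)
noisy_fit = fit_ivim_voxel(reps.mean(axis=0), scheme).params
print(f"SNR-50 fit    : F = {noisy_fit.f * 100:.2f} %, "
      f"D = {noisy_fit.d * 1e4:.2f} x 1e-4 mm^2/s, "
      f"D* = {noisy_fit.d_star * 1e3:.2f} x 1e-3 mm^2/s")
print("\nF is the microvascular volume fraction, D tissue diffusion and D*")
print("the pseudo-diffusion (blood-velocity index); noiseless recovery is")
print("exact to solver tolerance, noisy recovery scatters around the truth.")
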