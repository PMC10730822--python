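# cordivim

Quantitative perfusion analysis of the cervical spinal cord with
intravoxel incoherent motion (IVIM) diffusion MRI, built for studies of
degenerative cervical myelopathy (DCM) and similar compressive cord
pathologies. The package is aimed at researchers who want a tested,
fully synthetic-verifiable implementation of the cord IVIM pipeline:
signal modelling and voxel-wise fitting, cord morphometry, atlas-ROI
extraction and the two-cohort statistical plan — plus a ground-truthed
cord phantom generator that makes every stage testable without patient
data.

## The model

Microvascular blood moving through randomly oriented capillaries adds a
fast-decaying "pseudo-diffusion" component to the diffusion-weighted
signal. The biexponential IVIM model separates it from tissue water
diffusion:

```
S(b) = S0 · exp(−b·D) · [ F·exp(−b·D*) + 1 − F ]
```

* `F` — microvascular volume fraction (reported in %),
* `D` — tissue diffusion coefficient (mm²/s),
* `D*` — pseudo-diffusion coefficient, a blood-velocity index (mm²/s),
* `F·D*` — blood-flow index (mm²/s).

Voxel-wise fitting uses the segmented strategy (log-linear `D` on the
high-b regime, bounded nonlinear `(F, D*)` with `D` fixed) followed by a
bounded joint refinement of all four parameters; see
`docs/methods.md`. The default acquisition scheme is a cervical-cord
protocol with fourteen b-values (0–650 s/mm² in steps of 50), three
in-plane diffusion-encoding directions and twenty repetitions;
repetitions are averaged per (b, direction), directions are fitted
separately and the parameter maps averaged.

Around the fit, the package provides cord morphometry (cross-sectional
areas, anterior–posterior diameter and left–right width, MSCC/MCC
compression ratios, lesion-frequency maps), peripheral ROI erosion with
atlas substructures (ventral/lateral funiculi, dorsal columns,
ventral/dorsal horns), and the group statistics layer (percent
differences, one/two-tailed t-tests, two-way ANOVA with post-hoc tests,
regression with Pearson correlation, Mann–Whitney U and Fisher's exact
demographics tests).

## Worked example

```
python examples/01_ivim_signal_and_fit.py
```

```
b [s/mm^2] :    0   50  100  150  200  250  300  350  400  450  500  550  600  650
S(b)/S0    : 1.00 0.93 0.88 0.85 0.83 0.81 0.79 0.77 0.75 0.74 0.72 0.71 0.69 0.68

noiseless fit : F = 10.40 %, D = 4.30 x 1e-4 mm^2/s, D* = 14.30 x 1e-3 mm^2/s
SNR-50 fit    : F = 8.84 %, D = 4.59 x 1e-4 mm^2/s, D* = 15.40 x 1e-3 mm^2/s
```

The decay curve drops steeply over the first ≈100 s/mm² — that is the
perfusion compartment (`F`, `D*`) — then settles onto the slower tissue
decay governed by `D`. The noiseless fit returns exactly the grey-matter
parameters that generated the curve; the Rician-noisy fit at SNR 50
(repetition-averaged, as acquired) scatters around them.

The other examples cover phantom generation and parameter recovery
(`02`), morphometry and lesion-frequency mapping (`03`) and the full
group study (`04`). A thin CLI exposes the same stages
(`cordivim simulate|fit|morph|roi|stats|run-all`); try

```
cordivim run-all --out scratch/demo --n-hc 3 --n-dcm 3 --seed 7
```

for an end-to-end smoke run on a small phantom cohort.

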