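# Methods

## Signal model and fitting

The package models the diffusion-weighted magnitude signal of a voxel
as the biexponential intravoxel-incoherent-motion (IVIM) decay

S(b) = S0 · e^(−bD) · [ F·e^(−bD*) + 1 − F ],

with microvascular volume fraction F ∈ [0, 1], tissue diffusion
coefficient D and pseudo-diffusion coefficient D* (both mm²/s). The
model assumes two well-separated compartments in each voxel, Gaussian
diffusion within each (no kurtosis term), and D* ≫ D; the constraint
D* ≥ D is built into the solver's parameterization because a perfusion
compartment slower than tissue diffusion is not identifiable.

D and D* differ by roughly two orders of magnitude, so a joint fit from
generic starting values is poorly conditioned. The default solver
therefore proceeds in stages:

1. **High-b log-linear stage.** For b ≥ 300 s/mm² (configurable,
   `high_b_threshold`) the perfusion term has decayed to ≲0.2% of the
   signal; a straight-line fit of log S against b gives D and, through
   the intercept, an initial F = 1 − exp(intercept)/S0.
2. **Perfusion stage.** Bounded nonlinear least squares for (F, D*) on
   all b-values with D fixed and S0 taken from the b = 0 signal;
   D* is initialized at 10·D.
3. **Joint refinement** (default on, `refine=False` disables). A
   bounded trust-region fit of all four parameters, parameterized as
   (S0, F, D, Δ) with D* = D + Δ ≥ D, started from the segmented
   estimate.

Stage 3 exists because the segmented stages are slightly biased on
exact biexponential data: the residual perfusion signal above the
high-b threshold leaks into the log-linear slope (≈1% relative error in
D for grey-matter-like parameters at this scheme). The refinement
removes that bias — the noiseless round trip recovers parameters to
better than 10⁻⁴ relative — while inheriting the segmented stages'
robust initialization, which is what makes the joint fit safe under
noise. A joint fit from generic starting values remains available as
`mode="full"`.

Bounds: F ∈ [0, 0.5], D ∈ [10⁻⁵, 3×10⁻³] mm²/s,
D* ∈ [D, 10⁻¹] mm²/s — physiologically generous ranges for cord tissue.
A voxel fails quality control when the optimizer does not converge or
when D* lands at (within 2% of) its upper bound, which signals an
unidentifiable perfusion compartment; failed voxels propagate as NaN
and are excluded from ROI means, never zero-filled. The solver also
computes the nested monoexponential (F = 0) fit; if the biexponential
solution ends with a larger residual the monoexponential solution
(f = 0, d_star = d) is returned instead, so the fitted residual never
exceeds the nested model's.

Volume fitting averages the repetitions arithmetically per
(b, direction), fits each direction's averaged signal independently,
and averages the parameter maps over directions; the QC mask requires
every direction to converge. F is stored as a fraction everywhere and
converted to percent only in reporting layers (cohort tables, CLI
output).

## Synthetic cord cohort

The phantom emulates a two-cohort cervical-cord IVIM study at C1–C3:

* **Geometry.** Per slice, an elliptical cord whose axes follow the
  group's left–right width and anterior–posterior diameter
  (healthy 12.1 × 8.2 mm; patients 11.9 × 7.6 mm), containing a
  parametric butterfly grey matter (two ventral and two dorsal horn
  lobes joined by a commissural band). Masks are voxelized on a
  0.5 × 0.5 × 5 mm grid (9 slices labelled C1–C3). Shape scales are
  calibrated by scanning against the voxelized area so the grey-matter
  and white-matter cross-sectional areas hit their configured targets
  (defaults 14.4 and 63.5 mm² for controls; 13.5 and 57.6 mm² for
  patients) to within about one voxel-area; the grid center is offset
  by a sub-voxel amount so voxel counts grow in ~single-voxel steps
  under scaling. White matter is the cord minus the grey matter, so
  the partition is exact by construction. Funiculi are angular sectors
  of the white matter (ventral |θ| ≤ 50° from the anterior axis,
  dorsal columns |θ| ≥ 130°, lateral the remainder); horns split the
  grey matter at its anterior–posterior midline.
* **Tissue parameters.** Subject-level tissue means are drawn from
  configurable normal distributions whose defaults are the healthy
  group means ± SD (white matter F 6.4 ± 1.5%, D 4.0 ± 0.6 × 10⁻⁴,
  D* 20.1 ± 3.9 × 10⁻³; grey matter F 10.4 ± 1.7%, D 4.3 ± 0.6 × 10⁻⁴,
  D* 14.3 ± 3.1 × 10⁻³ mm²/s). Subregion pseudo-diffusion is the
  subject's tissue value scaled by the ratio of the subregion's
  configured mean to the tissue mean — subregion values are therefore
  perfectly correlated with their tissue within a subject, a deliberate
  simplification (see Limitations). Voxel values add a multiplicative
  Gaussian texture (default CV 5%) and are clipped to the physical
  bounds with D* ≥ 2D.
* **Patient effects.** Patients carry multiplicative effects:
  D* × 0.9 (≈ the −10% deficit regime the statistics layer is meant to
  detect), cross-sectional areas scaled to the printed patient means,
  F and D unchanged by default (the emulated study found no group
  difference in either). A configurable fraction (default 11/29)
  carries a contiguous lesion blob centered on the grey matter in the
  middle third of slices, echoing the grey-matter concentration of
  lesion-frequency maps in compressive myelopathy.
* **Noise.** Magnitude images receive Rician noise,
  sqrt((S+n₁)² + n₂²) with n₁, n₂ ~ N(0, σ²) and σ = S0/SNR (default
  SNR 50 at b = 0).
* **Clinical table.** Patient scores are drawn uniformly within the
  instrument ranges observed in the emulated cohort (mJOA 12–18,
  Nurick 0–2, UEMS 45–50, CLT 24–28, CPP 20–28, GRASSP 108–132), with
  a configurable fraction (default 3/29) missing; no perfusion–clinical
  link is induced by default, matching the emulated study's null
  finding. MSCC/MCC are drawn from N(25.7, 10.4) / N(39.5, 10.8)% and
  the sagittal diameters are constructed to reproduce the drawn ratio
  exactly. Ages and sex follow the cohort demographics (controls
  55.4 ± 12.1 y, 16/30 female; patients 56.9 ± 11.3 y, 11/29 female).

Everything descends from one seed: a subject's stream is
`default_rng([seed, crc32(subject_id)])`, so cohorts are reproducible
subject-by-subject and `images=False` table generation agrees
bit-for-bit with full image generation.

What the phantom does **not** emulate: partial-volume mixing with CSF
at the cord boundary (masks are crisp), motion/distortion/Gibbs
artefacts, registration error, B0/B1 inhomogeneity, cardiac-cycle
signal fluctuation, anatomical curvature along the cord, and
between-slice variation of the cross-section. Tests passing on the
phantom therefore validate the estimator and statistics pipeline under
the stated noise model, not robustness to acquisition artefacts — on
real data those are handled by preprocessing upstream of this package.

## Morphometry and ROI statistics

Cross-sectional area is voxel count × in-plane voxel area per slice,
averaged unweighted over the requested slices (empty slices contribute
zero with a warning). Extents are measured through the mask centroid
(anterior–posterior along the centroid column, left–right along the
centroid row) rather than bounding-box extents, which is robust to
single-voxel protrusions. The compression/compromise ratio is
100 × [1 − d_i / mean(d_a, d_b)] with caller-supplied reference
diameters, since reference selection on sagittal images is a manual
step. Lesion-frequency maps are 100 × the voxel-wise mean of aligned
binary masks.

ROI erosion removes ROI voxels within n iterations of the cord
boundary (per-slice 2D erosion of the cord with a 4-connected cross,
then intersection), so interior ROIs are untouched; the default is one
iteration, a minimal CSF-partial-volume trim at sub-millimetre in-plane
resolution. ROI statistics are arithmetic means over ROI ∩ QC voxels
with NaN (failed-fit) voxels excluded, reporting the voxel count used.

## Statistics

Group comparisons use the classical pooled-variance independent
two-sample t-test (Welch available via `equal_var=False`); one-tailed
tests take the direction "patients below controls" for perfusion
indices. Percent differences are 100 × (test − reference)/reference,
reported rounded half-away-from-zero to one decimal. The two-way
ANOVA (group × subregion) is an OLS fit with type-II sums of squares
(designs here are balanced, where type II equals the classical
decomposition) followed by per-subregion one-tailed t-tests as
post-hoc analysis, uncorrected by default to match the emulated
analysis plan; Benjamini–Hochberg adjustment is available as a switch.
Regression reports the OLS slope/intercept with Pearson's R and its
t-transform p-value. Demographics use Mann–Whitney U (age) and
Fisher's exact test (sex × group). Missing clinical scores are dropped
pairwise per test. The study driver reports degenerate comparisons
(n < 2, zero variance) with an NA status instead of raising.

## Verification surface and problem sizes

The package's correctness claims are backed by: exact closed-form and
hand-arithmetic oracles (signal values, compression ratios, sums of
squares, hypergeometric enumeration); a brute-force lattice search as
an independent check of the voxel fitter on noiseless input; Rician
closed forms (Rayleigh mean at S = 0, the high-SNR series expansion)
for the noise generator; and Monte-Carlo properties — type-I error of
the one-tailed group test within the 95% binomial interval of α = 0.05
over 1000 null cohorts of 29/26 subjects, and bias/RMSE of F̂, D̂, D̂*
decreasing over SNR ∈ {20, 50, 100, 200} with 500 repetition-averaged
voxels per level. The SNR sweep uses common random numbers across
levels (one Gaussian draw set, σ scaled), a variance-reduction choice
made so the monotonicity comparison reflects the estimator rather than
replicate sampling noise; |bias| comparisons carry an allowance of
twice their own Monte-Carlo standard error because once the estimator
is essentially unbiased (high SNR) the sign of a ~0.1% measured bias is
sampling noise. Simulation sizes (500–1000 replicates, small phantom
grids in unit tests) were chosen as the package's own trade-off between
statistical resolution and a test suite that runs in minutes.

## Known limitations

* Subregion pseudo-diffusion values are scaled tissue values within a
  subject, so subregion-level group tests on phantom cohorts are
  perfectly correlated with the tissue-level test; subregion-specific
  effect simulation requires configuring per-subregion multipliers or
  constructing long-format data directly (as the ANOVA tests do).
* The segmented-plus-refinement fitter is one defensible choice among
  several in the IVIM literature; no claim is made that it matches any
  specific toolbox's estimates on real data.
* The NIfTI importer for external atlas label volumes assumes label
  conventions compatible with `AtlasROISet` and is not validated
  against any specific template distribution.
* MSCC/MCC reference diameters are caller-supplied; the package does
  not automate reference-slice selection.
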