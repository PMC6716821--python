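# Methods

This note documents the models, algorithms, parameter choices and
known limitations of `dtipipe`.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Signal model and tensor estimation

The diffusion-weighted signal is modeled per voxel as
`S_k = S0 · exp(−b_k · gᵀ_k D g_k)` with a symmetric positive tensor D.
The default acquisition mirrors a single-shell rodent protocol:
30 directions at b = 1000 s/mm² plus 5 b = 0 volumes, native voxels of
102 × 102 × 250 µm.  Vendor gradient tables are generally unpublished,
so the shipped direction set was generated once by minimizing the
antipodally symmetric electrostatic energy of 30 points on the sphere
(worst-case inter-direction angle ≈ 25.7°); the test suite checks that
tensor recovery is invariant under arbitrary rotations of the scheme,
i.e. results do not depend on the exact table.

Estimation is ordinary least squares on `ln(S_k/S0)` with S0 the
arithmetic mean of the b = 0 volumes — deterministic and adequate at a
single moderate shell.  A signal-squared-weighted fit is available
behind `weighted_fit` but is not the default.  Numerical choices:
signal ratios are floored at 1e−12 before the log; voxels with
S0 ≤ `s0_floor` (default 1e−8) are masked invalid instead of raising;
negative eigenvalues are clamped to zero before metric computation
(keeps FA ≤ 1) and the clamped-voxel count is reported for QC.

Scalar metrics use the standard definitions: FA from the normalized
eigenvalue dispersion, MD the eigenvalue mean, AD = λ1,
RD = (λ2 + λ3)/2.  MD = (AD + 2·RD)/3 holds identically.

## Synthetic cohorts

The simulator is the package's substitute for unshareable scanner
data: it emulates the two-genotype (wildtype/mutant), two-timepoint
(baseline/follow-up, 150 ± 10 days apart) longitudinal design with
n = 9 per group by default.  The default phantom contains an isotropic
background (0.7·10⁻³ mm²/s, roughly parenchymal diffusivity), two
mildly anisotropic "cortex" boxes (λ = (1.0, 0.55, 0.45)·10⁻³, FA
≈ 0.41), a midline "corpus callosum" cylinder joining them
(λ = (1.7, 0.3, 0.3)·10⁻³, FA ≈ 0.80) and a separate descending
"corticospinal" cylinder of the same composition.  Structure placement
scales with grid extent, so the same anatomy can be rendered at any
desk-scale grid.

Lesions are multiplicative eigenvalue perturbations (default factors
(1.0, 1.35, 1.25)) applied to one genotype at one timepoint, restricted
to anisotropic tissue: radial inflation moves tissue toward isotropy,
so FA falls while RD and MD rise together — the co-occurrence pattern
that distinguishes demyelination-like damage.  The default lesion is a
sphere over the right cortex/callosal junction in the mutant group at
follow-up, which encodes an affected transcallosal pathway with a
spared corticospinal tract.  Perturbed eigenvalues must keep the
λ1 ≥ λ2 ≥ λ3 > 0 ordering or the spec is rejected at construction.

Noise is Rician, `S̃ = √((S + ε1)² + ε2²)` with ε ~ N(0, σ²), the
magnitude-MR law; the default σ = 0.02 relative to S0 = 1 represents a
high-SNR cryo-coil acquisition and was chosen so single-subject FA maps
are visually stable (no SNR figure is available to match).  Each scan
receives a random rigid pose offset within ±1 native voxel and ±3°, so
normalization has real work to do; motion corruption (≥2-voxel
displacement plus slice-intensity dropout of selected volumes) is a
separate operation providing positive controls for the quality check.

What the generator does not emulate: real mouse anatomy, eddy-current
or susceptibility artifacts, spatially varying coil sensitivity,
physiological noise, crossing fibers.  Passing tests therefore
demonstrate the correctness and statistical calibration of the
pipeline, not its robustness to every artifact of real scanners.

## Normalization

Native volumes are resampled to a 50 µm isotropic grid sized
`ceil(extent / spacing)` (nearest neighbor by default, which preserves
the value set — important for masks).  The stereotaxic frame puts
bregma at a designated voxel (grid center by default); reported
coordinates are (coronal, horizontal, sagittal) mm offsets of voxel
centers, positive toward increasing index, with +sagittal the right
hemisphere.

Template building is iterative: (1) per-scan affine from ≥ 4
non-coplanar landmark pairs by linear least squares, warped maps
arithmetically averaged into first b0/FA templates; (2+) demons-style
nonlinear refinement of each subject against the current FA template,
re-averaging, until the minimum per-subject Pearson correlation
(computed on a b0-derived brain mask) exceeds 0.7 or `template_max_iter`
(10) is reached.  The nonlinear step is a two-level (half/full
resolution) gradient descent on SSD with Gaussian smoothing (σ = 2
voxels) of each *update* before accumulation — smoothing the
accumulated field instead provably contracts it toward zero, which
systematically under-recovers displacement.  If refinement fails to
improve the correlation, the zero (or initial) field is returned, so
the operation never degrades alignment.  The transform model is not
diffeomorphic and no tensor reorientation is applied; since tensors
are fitted in native space and only scalar maps are warped (pose
offsets between scans are small rigid transforms), this is benign.  A
`fit_after_warp` flag exposes the alternative order (fit after
nearest-neighbor resampling of the DWI) for comparison.

The motion quality check fits the tensor to the whole stack and scores
each DW volume by median-RMSE/RMSE of its residual against the model
prediction (capped at 1).  Clean volumes differ from their prediction
only by noise and score near 1; displaced or dropout volumes disagree
spatially with the consensus fit and score low.  Volume-to-volume
correlation scores were rejected during development: anisotropic
structures reverse contrast between gradient directions, so clean
volumes can correlate near zero (or negatively) with a median volume.
A scan fails when more than `qc_max_bad_fraction` (10%) of volumes
score below `qc_score_threshold` (0.8); among repeated acquisitions
the passing scan with the highest mean score is kept.

## Voxelwise statistics (WBSS)

Metric maps are smoothed with a Gaussian of 200 µm FWHM
(σ = FWHM/2.355 ≈ 1.70 voxels at 50 µm) using masked-normalized
convolution inside the analysis mask, so off-mask zeros never dilute
edge voxels.  The mask is FA-template ≥ 0.2 — built once from the
template, not per subject, so all contrasts share one deterministic
voxel pool.  Four pre-specified contrasts: (a) mutant vs wildtype at
baseline, (b) at follow-up, (c) mutant follow-up vs baseline — paired
by subject, the natural reading of an intra-subject comparison, with an
unpaired flag — and (d) the per-day change ΔDM between genotypes.
Tests are two-sided equal-variance Student t (Welch behind a flag);
zero-variance voxels with equal means give t = 0, p = 1.  Multiple
comparisons are controlled by Benjamini–Hochberg at q = 0.05 over all
mask voxels, then clusters below 256 voxels (26-connectivity;
6-connectivity by flag) are discarded — the spatial correction is
exactly this minimum size, no random-field theory.  Cluster peaks are
minimum-p voxels reported in stereotaxic mm; effect direction is the
sign of the cluster's mean t.

## Tractography and TFAS

An averaged dataset is built by voxelwise arithmetic averaging of the
subjects' template-space tensor components followed by
eigen-decomposition.  Deterministic streamlines integrate the
trilinearly interpolated principal eigenvector bidirectionally from
every seed-region voxel center with FA ≥ 0.2; each contributing voxel's
eigenvector is sign-aligned to the running direction before
interpolation (the eigenvector sign is arbitrary).  Defaults, all in
config: step 25 µm (half a voxel), turning-angle limit 45°, FA stop
0.2, minimum length 0.5 mm.  Tract selection keeps streamlines that
traverse every must-pass region and terminate in both endpoint regions
(order-free).  TFAS averages a metric over the tract's voxel-occupancy
mask per subject, excluding voxels where that subject's FA < 0.2
(matching the WBSS masking convention; per-streamline averaging is
deliberately not used), and compares genotypes per timepoint with a
two-sample t-test, reporting means and SEM.

## ROI analysis and histology ANOVA

Spherical ROIs are defined in stereotaxic mm (voxel-center membership,
no partial-volume weighting); bilateral ROIs are the union of the
sphere and its sagittal mirror.  The histology analysis is a 2 × 2
between-subjects ANOVA with Type III sums of squares, chosen because
the design of interest is unbalanced (n = 3/3/3/4): main effects are
contrasts of unweighted marginal means, the interaction contrast is
m11 − m12 − m21 + m22, the error term pools within-cell variances, and
Tukey–Kramer corrects the six pairwise cell comparisons against the
studentized range with k = 4.  The summary-statistics path (n, mean,
SD per cell) is exact, not an approximation, because every Type III
quantity in a 2 × 2 design is a function of cell means, variances and
counts; the test suite verifies raw-path/summary-path agreement to
1e−10 and the balanced-design reduction against statsmodels.
Published tables print `mean ± value` without naming the dispersion;
treating the value as a per-cell SD is the package's default
(`dispersion_kind="sd"`), with SEM selectable.

## Problem sizes in the shipped checks

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes at which each property is meaningfully exercised:
module-level cohorts on 24 × 24 × 10 native grids (≈ 49³ isogrid);
type-I calibration over 20 null cohorts of n = 5/group at that size;
detection, ROI and tract dissociation at study-like conditions on a
48 × 48 × 20 native grid (≈ 98² × 100 isogrid) with n = 9/group;
tensor recovery on a 64³ phantom.  At the smallest grids the phantom
structures are only a few native voxels thick, so partial-volume
variation between differently posed subjects dominates between-subject
variance and voxelwise detection power is limited; the
study-condition grid restores the interior-dominated regime and is
where the detection claims are made.

## Known limitations

Single-shell, single-tensor only — no kurtosis, no crossing-fiber
models, no probabilistic tractography.  The registration is
small-deformation and not diffeomorphic.  Anatomical labels for
clusters are free-text pass-throughs (no atlas is shipped).  The
quality-check scoring reconstructs the *purpose* of the original
procedure (flag motion-corrupted volumes and scans), not its exact
unpublished algorithm.
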