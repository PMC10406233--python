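# Methods

## Motion model and censoring

The motion measure is the Euclidean norm (Enorm) of the frame-to-frame
differences of the six rigid-body realignment parameters, rotations in
degrees and translations in millimeters combined at unit weight. The unit
weight is a geometric convention: a 1° rotation displaces tissue by an arc of
57·π/180 ≈ 0.995 mm at a 57 mm radius, roughly the distance from the head's
center of mass to the edge of the brain, so degrees and millimeters are
treated as commensurate. The first time point has no predecessor and its
Enorm is defined as 0; mean and max Enorm are taken over the T−1 defined
differences, deliberately over *all* of them (not just retained ones) so they
summarize the subject independently of any censoring choice.

Censoring removes every volume whose Enorm strictly exceeds the threshold
and the volume immediately before it (the difference straddles both).
"Strictly" means a point exactly at threshold is kept, consistent with
criteria phrased as "> 3 mm". Where the convention "the preceding time
points" could be read as more than one, we take exactly one, the common
practice.

## Nuisance model and degrees-of-freedom accounting

All denoising is one general linear model fit by least squares on retained
rows only:

* **Drift**: Legendre polynomials of degree 0..2 on [−1, 1] (3 columns).
  "Two polynomials beyond the constant" is the only reading consistent with
  the reference degrees-of-freedom values (140 − 21 = 119, 720 − 21 = 699)
  given 18 nuisance-plus-derivative columns.
* **Nuisance**: mean whole-brain (optional — the GSR toggle), eroded white
  matter and CSF signals, the 6 motion parameters, and the backward-difference
  derivative of each (first element 0; any offset is absorbed by the
  constant).
* **Band-pass as regression**: for a pass band (f_lo, f_hi), sine and cosine
  columns at every DFT frequency k/(T·TR), 1 ≤ k ≤ T/2, lying outside the
  inclusive band; the Nyquist frequency contributes only a cosine (its sine
  vanishes on the grid) and zero frequency is the constant polynomial.
  Projecting these out is algebraically identical to a hard frequency-domain
  filter on uncensored data, but unlike an FFT filter it composes exactly
  with censoring and makes the cost in degrees of freedom explicit.

Residual degrees of freedom are `#retained rows − rank(design on retained
rows)`, never negative; rank is the numerical matrix rank, so collinearity
(e.g. a motion parameter that is itself nearly a sinusoid) is charged only
once. Under rank deficiency the projection uses the minimum-norm
least-squares solution and reports the effective rank. Censored rows are
excluded from the fit rather than interpolated, and are zero-filled in the
stored residuals with an explicit retained-row mask that all downstream
correlations honor.

Band edges are inclusive (a DFT frequency exactly at 0.01 or 0.1 Hz is
retained). The band may extend up to Nyquist in the design builder; run
configurations validate the stricter f_hi < Nyquist.

## Image-quality metrics

**TSNR** is per-voxel temporal mean over temporal SD (ddof = 1), computed on
the *original* series (before nuisance regression); zero-variance voxels are
excluded from the in-mask mean and counted.

**Spatial smoothness** uses the classical Gaussian-autocorrelation
first-difference estimator. For a field with Gaussian ACF, the variance of
first spatial differences at spacing Δ satisfies σ²_Δ = 2σ²(1 − ρ(Δ)), so

    FWHM_d = Δ_d · sqrt(−2 ln 2 / ln(1 − σ²_Δ/(2σ²))) ,

clamped to 0 when σ²_Δ ≥ 2σ² ("rougher than white noise"). Per-direction
estimates are formed at each time point (after per-voxel mean+linear
detrending for 4D input, so static anatomy does not masquerade as
smoothness) using only voxel pairs fully inside the mask, then averaged;
the combined value is the geometric mean over the three axes. Note the
estimator measures the *correlation length* of the field: for spatially
independent noise it tends to 0, not to the voxel size, and for noise
convolved with a known Gaussian kernel it returns that kernel's FWHM (the
property the tests exercise). **Blur-to-target** iterates: estimate, then
apply an in-mask normalized Gaussian blur whose width closes the quadrature
gap σ²_step = σ²_target − σ²_current (step capped at σ_target to avoid
overshoot inside bounded masks), stopping within a 5% tolerance by default;
it refuses if the data are already smoother than the target.

**Dice** is 2|A∩B|/(|A|+|B|) on a shared grid.

**FCS** is each voxel's Pearson correlation with the scaled global signal —
the average of variance-normalized voxel time courses. This equals the
voxel's mean correlation to *all* brain voxels (self included) divided by
one positive per-dataset scalar (the norm of the mean unit-normalized
series), so the map ranks voxels exactly as the brute-force all-pairs
average. Including the self term keeps the identity exact; excluding it
would change values by O(1/V). FCS is computed on post-regression
residuals, restricted to retained rows.

**Left-right flip check**: the EPI-to-T1 match cost (negative Pearson
correlation within the mask; a contrast-insensitive absolute-correlation
variant is available) is evaluated for the T1 and for the T1 mirrored about
the mid-sagittal plane of the axis the orientation code maps to left-right,
each after an exhaustive integer-voxel translation search within ±10 mm.
The scan is called flipped when the mirrored cost is better by more than
the margin; ties go to "not flipped". Full affine registration is out of
scope — inputs must be pre-aligned.

## Connectivity-level QC

Seed membership is decided by voxel-center Euclidean distance in world
millimeters (a 4 mm sphere on a 3 mm grid centered on a voxel contains 7
voxels). World coordinates always come from the NIfTI affine, so axis order
and polarity on disk are irrelevant; seed coordinates are interpreted in
the volume's world frame and any sign convention mismatch must be resolved
explicitly by the caller (the bundled canonical seed table is stored as
printed by its source protocol, whose hemisphere signs are knowingly
ambiguous).

FC matrices are pairwise Pearson correlations of region-mean time courses
on retained rows; Fisher-Z is atanh with r clipped to ±(1 − 1e−7), diagonal
excluded from every vectorization. Because projection and region averaging
are both linear, projecting region means equals averaging projected voxels
exactly — the sweep exploits this. Group means, similarity and QC-FC all
operate in Fisher-Z space (the variance-stabilizing companion of edgewise
averaging); the group mean includes the subject itself by default with a
leave-one-out option — at cohort size ≈ 40 the two give per-subject
similarities correlating > 0.99. Similarity is Pearson over the
upper-triangle edge vector; dissimilarity is the Euclidean distance over
the same vector.

QC-FC correlates each edge's Fisher-Z value with mean Enorm across
subjects (≥ 3 required; zero-variance edges excluded and counted), with a
101-bin histogram on [−1, 1]. Distance dependence is the Pearson
correlation of the per-edge QC-FC with inter-centroid distance, with a 95%
Fisher interval using n = number of edges. Treating edges as independent is
*anti-conservative*: edges sharing a region are correlated, so the interval
under-covers somewhat; it reproduces the field's reporting convention and
is labeled as such.

## The synthetic cohort generator

Each phantom subject is `anatomy + Σ_n map_n·tc_n + region signals +
thermal noise`, with optional multiplicative global spikes:

* **Geometry**: an ellipsoidal brain on a 16×16×12 grid of 3 mm voxels;
  six networks tile the superior half (each split into 4 parcel regions,
  24 regions total); an eroded inferior core plays white matter, a small
  central block CSF. Deterministic given the grid.
* **Time courses**: sums of sinusoids drawn from 0.01–0.08 Hz — inside the
  0.01–0.1 Hz pass band, because resting-state fluctuations of interest
  live below 0.1 Hz — unit variance, T = 200 volumes at TR 2.5 s (a 500 s
  run, in the range where band-pass regression leaves a meaningfully small
  dof budget). Each region additionally carries an independent in-band
  fluctuation (amplitude 0.6): regional heterogeneity that keeps the
  cohort's FC edges from being degenerate copies of one another, which the
  edge-independence assumption of the QC-FC interval needs.
* **Noise and artifacts**: white Gaussian thermal noise (σ = 0.5 against a
  baseline of 100, TSNR ≈ 170); global spikes multiply all in-mask voxels
  by (1 + gain) at chosen volumes, the signature of an RF coil spike, which
  raises FCS and lowers TSNR.
* **Motion**: parameter increments are iid Gaussian scaled so the expected
  Enorm equals the requested level exactly (E[χ₆] normalization), with a
  shared lognormal per-frame amplitude modulation (σ = 0.8, unit mean) that
  gives traces the heavy-tailed excursions real subjects show — without it,
  the χ₆ distribution is so narrow that censoring switches from "nothing"
  to "everything" over a tiny range of motion levels. Exact single-axis
  spikes can be injected on top. Cohort motion levels default to a
  log-spaced 0.02–0.25 mm span.
* **Motion-coupled FC** is injected at truth level: for a designated
  network edge (i, j), tc_i ← (tc_i + α·tc_j)/√(1+α²) with α = slope ×
  mean Enorm, giving an analytic target for QC-FC recovery without
  simulating image-space motion artifacts.
* **Reproducibility**: one integer seed; subject substreams derive from
  `SeedSequence(seed, spawn_key=(subject_index,))`, and within a subject
  separate spawn keys feed image noise and motion.

What the phantom does *not* emulate: EPI physics (B0 distortion, dropout,
slice timing, spin history), image-space rigid-body resampling (motion
corrupts data only through censoring, nuisance-regressor structure, and the
optional truth-level coupling), spatially correlated physiological noise,
and realistic anatomy. Passing cohort tests therefore demonstrates the
*mechanisms* — dof loss under censoring, QC-FC null behavior, coupling
recovery — not performance on real scanner data.

## Problem sizes and numerical choices

Cohort analyses use 40 subjects × 24 regions × 200 volumes, chosen so a
full 3-threshold × 2-band sweep completes in seconds while the dof budget
(≈ 72 with band-pass, ≈ 179 without) reproduces the qualitative regime of
interest: under 0.2 mm censoring the highest movers drop to 0 dof and
mid-range movers land between 0 and 15, so similarity-vs-motion R² is
large at 0.2 mm and near zero at 1.0 mm, and removing the band-pass
returns ≈ 107 stop-band columns' worth of dof and raises similarity most
for high movers.

Rank and least squares use LAPACK via numpy (`matrix_rank` at its default
tolerance; `lstsq` minimum-norm). Orthogonality of residuals to the design
holds to ≤ 1e−8 relative; projection is idempotent to 1e−10; stop-band
residual power is < 1e−10 of input power. Fisher-Z clips r at ±(1 − 1e−7).
Zero-variance voxels/regions/edges are excluded and counted, never silently
imputed. The criterion-E outlier rule uses median ± 4 MAD within site, with
equality-to-median as the degenerate-MAD fallback; sites need ≥ 3 subjects
with the metric for the screen to be evaluable.

## Known limitations

* The QC-FC distance-dependence interval treats edges as independent and
  under-covers under strong network structure (documented above); with a
  finite cohort a small negative distance dependence also arises
  mechanically when effective sample size varies with motion, because
  autocorrelated series bias high correlations downward more when fewer
  effective samples remain.
* The flip check searches translations only; residual rotational
  misalignment degrades both costs symmetrically but is not corrected.
* The smoothness estimator assumes a Gaussian ACF; heavy-tailed spatial
  correlation (e.g. from interpolation) biases the estimate.
* Reference with-band-pass dof values for specific external subjects cannot
  be checked without their site TR, and are not asserted anywhere.
* Criteria F–H are inherently visual; the package carries them as explicit
  placeholders plus advisory aids (montage export, cohort mask-overlap
  scores) rather than pretending to automate them.
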