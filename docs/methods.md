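# Methods

This note documents the models implemented in `wmfp`, the parameter choices
that matter, what the synthetic cohort does and does not emulate, and the
numerical decisions a maintainer should know about.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Quantitative map estimation

**R2\* (multi-echo gradient echo).**  Magnitude decay is modelled as
S(TE) = S0·exp(−TE·R2\*); the estimator is per-voxel ordinary least squares
on ln S against TE (default eight echoes, TE = 2.21…28.11 ms, ΔTE =
3.7 ms), with the slope negated and clipped at zero.  Voxels with any
non-positive magnitude are invalid (NaN), never exceptions: masked
background must not abort a whole-volume fit.

**R1 (two-point VFA).**  The ideally spoiled SPGR equation
S = M0 sinθ (1−E1)/(1−E1 cosθ), E1 = exp(−TR·R1), is linearized as
S/sinθ = E1·S/tanθ + M0(1−E1) and solved from the two flip angles
(defaults 4°/25°, TR 20 ms).  The per-voxel flip angles are scaled by the
relative transmit field B1 before fitting.  Imperfect spoiling corrections
published for specific protocols are multiplicative corrections on T1; the
fitter exposes that as a pluggable callable with identity default, because
published coefficient sets are protocol-specific.  E1 outside (0, 1) marks
the voxel invalid.

**B1 (AFI).**  The dual-TR spoiled GRE pair in the short-TR regime gives
r = S2/S1 = (1 + n cosθ)/(n + cosθ) with n = TR2/TR1 (default 5); inversion
is cosθ = (rn − 1)/(n − r), B1 = θ/θnom.  Ratios at or beyond n, or cosines
outside [−1, 1], are invalid voxels.

**B0 (two-echo phase).**  B0[Hz] = Δφ/(2π·ΔTE) with Δφ wrapped to the
(−π, π] convention (the convention is a free choice; it is fixed and
tested).  Default TE pair 2.25/6.90 ms.

**MPF (single-point constrained two-pool MT).**  The model is a free water
pool and a macromolecular bound pool with longitudinal exchange.  The
off-resonant shaped saturation pulse (12 ms Gaussian, 560° nominal, 6 kHz
offset, TR 28 ms, 6° readout) is treated in the continuous-wave
power-equivalent approximation: during the pulse the bound pool saturates
at W_b = π·ω1rms²·g_SL(Δ, T2b) with a super-Lorentzian lineshape (512-point
Gauss–Legendre quadrature) and the free pool at the Lorentzian rate; the
coupled longitudinal dynamics over one TR (saturation interval, readout
rotation of the free pool, free recovery) are solved exactly with closed-
form 2×2 matrix exponentials, and the steady state is the fixed point of
the affine cycle map.  With the standard single-point constraints —
T2b = 9.7 µs, T2f = 0.022·T1, bound-to-free exchange rate k(1−f)/f =
19 s⁻¹, R1f = R1b = R1 from the R1 map — the normalized ratio S_MT/S_ref
is a strictly decreasing function of the bound-pool fraction f alone.  The
fit inverts it by vectorized bisection on f ∈ [0, 0.35] (the ratio is
monotone, so bisection is globally convergent) to width 10⁻⁶ with one
secant refinement; MPF = 100·f.  B0 shifts the effective offset, B1 scales
the saturation and readout angles.  A ratio outside (0, 1.2] or a residual
without a sign change on the bracket is an invalid voxel.

**R2 (pSSFP).**  Two RF-spoiled gradient-echo acquisitions differing only
in the quadratic RF-phase increment (1° and 20°; TR/TE 7/3 ms, 60°) have a
signal ratio that grows monotonically with T2, because the small increment
preserves transverse coherences that ideal spoiling destroys.  Rather than
an approximate closed form, the forward model is a direct Bloch simulation
of the pseudo steady state (128 isochromats across the per-TR spoiler
dephasing, 1536 TRs, last 256 averaged, fixed assumed T1 = 1.25 s), tabled
on a log-spaced T2 grid (5–600 ms, 56 points) per quantized B1 value and
inverted by monotone interpolation.  T2 is capped at 150 ms before
conversion to R2 (long-T2 voxels are CSF-contaminated and uninformative
for white matter); ratios below the curve's admissible range are invalid,
ratios beyond its long-T2 end are assigned the cap.  Round-trip error of
the tabled inversion is < 0.1 % over 20–150 ms.

**DTI scalars.**  Log-linear least squares for the six-component symmetric
tensor from ≥ 1 b=0 volume and ≥ 6 non-collinear directions (default: 20
spherical-Fibonacci directions at b = 1500 s/mm²); eigenvalues sorted
descending and clipped at zero before AD = λ1, RD = (λ2+λ3)/2, ADC = λ̄ and
the standard FA formula.  Collinear schemes are rejected as rank-deficient.
Scalars are invariant under joint rotation of scheme and tensor (tested to
1e−9).

**Smoothing.**  Isotropic Gaussian, σ = FWHM/2.3548 per axis (default
5 mm), kernel truncated at 8 σ so the discrete semigroup property holds to
1e−6.  NaN voxels are handled by normalized convolution: the pipeline marks
brain-exterior voxels as undefined before smoothing, so boundary voxels are
averages of brain tissue only, not of tissue and zeros.  (Smoothing
unmasked zero-filled volumes creates a strong shared brain-edge gradient
that the decomposition then isolates as spurious high-variance components.)

**R2′.**  Voxelwise R2\* − R2 on a common grid.  Negative values are
physically possible under noise and are retained, with the count logged on
the map for QC.

## The synthetic cohort

The phantom emulates the statistical structure the decomposition assumes,
not anatomy.  On a 32³ grid (2 mm): an ellipsoidal brain; a white-matter
interior (pWM ≈ 0.95 inside ~0.7 of the brain radius) with a grey-matter
rim; three smooth plateau territories inside the white matter — track-like
(deep, elongated), frontal-subcortical (anterior) and central-subcortical
(superior) — with pairwise spatial correlation ≤ 0.2 and support overlap
≤ 10 %.  For subject s and parameter p the map is

    baseline_p + Σ_c w_c(v)·(F_cp + jitter_csp + cov_cp(s) − baseline_p)
               + a_p·G(v)·m_rim(v) + common_sp + cov_global_p(s) + noise

with F the 3×7 fingerprint matrix of published subtype reference values
(e.g. track AD 1066 µm²/s, frontal MPF 13.8 %), baseline grey-matter-like
values outside the territories, and zero outside the brain.

Parameter choices that matter, with rationale:

- **Between-subject variance is calibrated to the published SDs**: the
  published per-subtype SD is treated as the *total* between-subject spread
  of a subtype's ROI mean, decomposed into a shared subject effect, a
  component-specific jitter, and the covariate-driven part.  The
  component-specific fraction (`component_jitter_frac`, default 0.8) and
  the territory volumes were calibrated against the reported subtype
  variance fractions (≈ 5/8/2.5 % of total matrix variance) and
  inter-parameter/inter-subject loading ratios (≈ 2.5–6.7): with a mostly
  shared subject effect the frontal/central contrast falls below the PCA
  noise floor and cannot be separated at desk scale.
- **Anatomical texture** (`anatomy_contrast_frac` 0.35, FWHM 10 mm): one
  smooth random field per cohort, identical across subjects, modulated by
  the grey-matter rim.  It stands in for the cortical/partial-volume
  heterogeneity that dominates the spatial variance of real maps; without
  it the group ±4 SD intensity clamp truncates the subtype cores (their
  contrast exceeds 4 group-SD on an implausibly homogeneous background).
  Being shared, it adds no between-subject ROI variance; being
  rim-confined, it forms one high-variance non-WM component that the
  white-matter-overlap criterion rejects — a useful stand-in for the
  grey-matter/CSF components of a real decomposition.
- **Noise** is additive Gaussian per voxel with SD = 20 % of each
  parameter's between-subtype spread — real map noise is unreported, and
  this keeps per-voxel contrast-to-noise plausible after 5-mm smoothing.
- **Covariates**: age ~ Uniform[20, 58] years, gender balanced.  Planted
  effects: a global MPF decline (−0.03 %/y), opposite R1 age slopes
  (−0.003/y frontal vs +0.002/y track and central — a subtype × age
  interaction), and higher diffusivity in women in the track territory
  (+20 µm²/s on AD and RD — a subtype × gender interaction on ADC).
  Magnitudes are a few percent over the age range, in line with reported
  aging effect sizes, and sized so the interaction is detectable in a
  20-subject cohort.
- **Missingness**: seven maps over four subjects (susceptibility/R2\*/MPF
  for two, R1 and R2 for one each), giving the 20·7−7 = 133-row group
  matrix.

What passing on the phantom does **not** show about real data: the phantom
has no real anatomy, no registration error, no field-dependent artifacts,
no correlated (physiological) noise, territories are exact plateaus rather
than graded tissue mixtures, and the susceptibility map is drawn directly
(no dipole inversion).  Recovery of the planted structure validates the
machinery, not the biology.

## Group decomposition

Normalization computes one mean/SD per parameter over all in-mask voxels
of all subjects (preserving inter-subject level differences), then clamps
to ±4 SD.  The matrix keeps rows only for non-missing maps and columns only
for voxels finite in every row.

The ICA is natural-gradient Infomax with the logistic nonlinearity and a
bias term, run on seeded random mini-batches (block ≈ 5·ln n) after
row-centered PCA whitening to the model order; the learning rate anneals
(×0.9) when the per-pass weight update turns by more than 60°, divergence
restarts at half the rate (bounded), and convergence is a relative per-pass
weight change below 1e−7 (max 512 passes).  Sources are z-scored over the
analysis mask and sign-fixed to non-negative skewness; components are
ordered by variance explained.  An extended (kurtosis-switched) variant is
available.  On the default phantom the sources agree with an independent
FastICA implementation at |r| ≥ 0.95 after matching (tested).

Selection implements the two published criteria with the one unspecified
constant made explicit: WM overlap is the fraction of positive z ≥ 2 voxels
with pWM > 0.5, threshold 0.5 by default; the loading ratio is SD over
parameters of parameter-wise mean loadings divided by SD over subjects of
subject-wise means (ε-guarded), threshold 1.5.  Model orders default to
N ∈ {6, 8, 10, 12}: the desk-scale matrix has 133 rows, so the published
orders (20…140, designed for 175 rows at 2-mm whole-brain resolution) are
scaled to keep N well below the row count while still spanning a factor of
two.  Matching across orders is Hungarian assignment on |spatial r| against
a reference run — the smallest model order among runs with the *modal*
selection count, so one borderline extra selection at a single order cannot
redefine the subtypes.  Fleiss' κ treats decompositions as raters and
analysis-mask voxels as items (all mask voxels, not only ever-selected
ones; the alternative is a flag) at both z ≥ 2 and z ≥ 3.2.  Cluster-extent
filtering (k ≥ 200 voxels, 26-connectivity) applies to display masks only.

Recovery is scored against the ground-truth weight fields smoothed to the
pipeline's 5-mm resolution: sources are estimated from smoothed maps, so
the resolution-matched truth is the correct comparator.

## Fingerprints and statistics

Extraction averages *unsmoothed* maps over atlas ROI voxels (z ≥ 3.2)
passing the subject's pWM > 0.8 gate; cells with fewer than 10 eligible
voxels are NaN; casewise deletion applies per test thereafter.  The ROI
values are mildly diluted toward baseline relative to the planted plateau
values (the z-threshold admits a thin smoothed rim); the dilution is a few
percent of the subtype-baseline contrast and symmetric across subtypes, so
orderings and separations are preserved.

Paired t-tests per parameter and subtype pair use subject-wise means; the
significance flag applies standard Bonferroni α/m (m = parameters × pairs
by default; the corrected cutoffs printed in some reports do not equal
α/m, so the package reports its own).  Cohen's d uses the equal-n pooled
SD √((s1²+s2²)/2) (the groups are the same subjects); the distance between
two subtypes is Σ|d| over parameters and contributions are |d|/Σ|d|,
summing to 1 whenever defined.  Cross-correlations report Pearson r with
two exploratory flag tiers (|r| ≥ 0.38 and ≥ 0.48, stored explicitly with
n rather than re-derived from α).

The GLM uses the multivariate repeated-measures formulation: between-
subject terms (centered age, centered gender) act on subject means across
subtypes; within-subject terms (subtype, subtype × age, subtype × gender)
act on the K−1 difference contrasts; every hypothesis has one degree of
freedom, where Wilks' Λ has the exact transform F = ((n_e−p+1)/p)(1−Λ)/Λ
with (p, n_e−p+1) df.  The omnibus analysis stacks all seven parameters
(14 contrast columns), which requires ≥ 17 complete subjects — the default
cohort keeps 16 after casewise deletion, so the omnibus refuses there by
contract and is exercised on complete cohorts; per-parameter tests carry
the planted-effect validation.  Null calibration of the type × age test is
verified by simulation (rejection ≈ 5 % at α = 0.05).

Tract overlap is |tract ∩ {z > 2}| / |tract| per subtype; rows may sum
above 1 (subtypes may overlap) or below 1 (unassigned voxels).  The bundled
tract fixtures are two tubes: one routed through the central and track
territories (a fasciculus crossing subtypes), one confined to the track
core.

## Numerical and degenerate-input conventions

Invalid voxels are always NaN and excluded downstream, never exceptions;
structurally invalid inputs (too few echoes, collinear gradients, grid
mismatches, unknown config keys, duplicate subject ids) raise immediately
with the offending names.  Fleiss' κ returns 1 for perfect degenerate
agreement and NaN (with a warning) otherwise-degenerate marginals.  Zero
group SD rejects a parameter rather than producing infinities.  All
randomness flows from explicit seeds (cohort seed, ICA seed); fixed seeds
give byte-identical cohorts and identical reports.

## Problem sizes

Default experiment sizes — 32³ grid, 20 subjects, model orders 6–12,
10 000-voxel noise Monte-Carlos, 100-replicate GLM experiments — are chosen
so the full suite and the acceptance script each complete in minutes on a
single CPU while keeping every statistical check comfortably powered.

## Known limitations

- The pSSFP forward model is a simulation-tabled inversion, not the
  original closed-form relation; absolute T2 calibration against scanner
  data has not been performed.
- The MPF model uses the CW power equivalent and a readout that rotates
  only the free pool; very short TR or high duty-cycle protocols would need
  a finer pulse discretization.
- The spoiling correction for VFA ships as identity; users of specific
  protocols should supply their published correction.
- Susceptibility maps are consumed as inputs; no QSM reconstruction.
- The omnibus doubly multivariate GLM needs more complete subjects than
  the default missing-data pattern leaves; this mirrors its real power
  constraints rather than a software limit.
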