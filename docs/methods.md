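# Methods

This note documents the models implemented by `glymphdti`, the numerical
choices behind them, what the synthetic data emulate (and do not), and the
known limits of the methods — in particular the identifiability limit of
single-shell free-water estimation, which bounds what any test on noisy
data can show.

## Acquisition model and conventions

All volumes are NIfTI with an RAS+ world frame; voxel indices are 0-based
and every ROI is specified in world millimetres. Gradient tables use the FSL
bval/bvec text dialect (3 rows × q columns; a transposed q×3 layout is
detected by shape). b-values below 50 s/mm² are treated as b=0, since
scanners emit small nominal values. The reference protocol is one b=0 volume
plus a 32-direction shell at b = 1000 s/mm² on a 2 mm isotropic grid;
everything works for any single shell with ≥ 6 non-collinear directions.
Preprocessing (denoising, unringing, eddy/motion correction) and
registration estimation are assumed done upstream; the package only
*applies* a user-supplied world-space affine (`resample_affine`, trilinear
for continuous maps, nearest-neighbour for masks).

## Quality screening (tSNR)

Per voxel, temporal SNR is the mean over the selected volumes divided by the
sample standard deviation (n−1); the subject summary is the mask-mean of the
per-voxel values, and a subject passes when it exceeds a configurable cutoff
(default 6.47, a published screening threshold for poor diffusion data).
Which volumes constitute "time" is ambiguous for b0+shell protocols; the
default is the shell only, because a single b0 volume contributes no
variance of its own, and the selector used is recorded in the report. Note
that for diffusion data this statistic deliberately mixes thermal noise with
angular contrast: strongly anisotropic voxels have lower tSNR than isotropic
ones at the same noise level. Zero-variance voxels are excluded and counted
rather than mapped to infinity.

## Single-tensor fit

The log-linear model ln S_q = ln S₀ − b_q g_qᵀ D g_q is solved per voxel by
least squares over the 6 unique tensor elements plus ln S₀. The default is
WLS with weights equal to the squared predicted signal of a first OLS pass,
the standard correction for the heteroscedasticity the log transform induces
on magnitude data. Choices that matter:

- multiple b=0 volumes are averaged before fitting;
- non-positive samples are floored at (smallest positive observed) × 10⁻³
  before the log;
- eigenvalues are sorted descending and negatives clamped to 0 with a
  per-voxel degeneracy flag — never reordered by magnitude — which keeps
  FA within [0, 1];
- a gradient design with condition number above 10⁶ is rejected with the
  condition number in the message.

FA uses the standard normalised eigenvalue-dispersion formula; the
degenerate all-zero case is defined as FA = 0. Axis diffusivities
(Dxx, Dyy, Dzz) are the diagonal tensor elements in image axes, *not*
eigenframe values — this is what the ALPS ratio requires.

## DTI-ALPS

Four spherical ROIs (default diameter 5 mm) sample the projection-fibre and
association-fibre bundles in each hemisphere. A voxel belongs to a sphere
iff its centre lies within the radius (no partial-volume weighting —
deterministic and conventional). Lesion voxels are excluded from every
ingredient mean, and an ROI whose voxels are all lesion-excluded is an
error naming that ROI. Per hemisphere,

ALPS = (mean Dxx_proj + mean Dxx_assoc) / (mean Dyy_proj + mean Dzz_assoc),

and the reported index is the mean of the two hemispheres. Shipped atlas-
space ROI centres are documented approximations at the level of the
lateral-ventricle body (the package does not redistribute any atlas);
`phantom_roi_spec` derives exact centres for synthetic phantoms. Left/right
follow the sign of world x under RAS+.

The index is invariant under uniform scaling of the diffusivity maps, and
perturbations strictly inside the lesion mask provably cannot change it —
both properties are regression-tested.

## Free-water (bi-tensor) fit

Model per voxel: S_q/S₀ = (1−f)·exp(−b_q g_qᵀ D g_q) + f·exp(−b_q d_w),
with tissue tensor D, free-water fraction f ∈ [0, 1] and fixed
d_w = 3.0×10⁻³ mm²/s (free water at body temperature; configurable).

**Ill-posedness.** From a single shell, f and D trade off along a nearly
flat ridge: for a wide range of f one can find a tissue tensor that fits
one shell almost exactly (exactly, for isotropic tissue). Estimation
therefore needs (a) a deterministic resolution of exact ridges and (b)
spatial regularisation for noisy data.

**Scheme.** The estimator is a variable-projection profile search with a
spatial prior:

1. *f step* — per voxel, 1-D bounded minimisation of the profile objective
   J(f) = Σ_q (A_q − (1−f)·e_t(f) − f·e_w)², where the tissue tensor inside
   e_t(f) is re-fit (WLS log-linear, eigenvalues clamped to the tissue
   bounds [0.1, 2.5]×10⁻³ mm²/s) for every candidate f. A 17-point coarse
   grid brackets the minimum and golden-section refines it. Profiling the
   tensor out is essential: a plain coordinate alternation between a tensor
   step and an f step creeps along the ridge and does not reach the joint
   minimum in any practical number of iterations.
2. *Ridge handling* — when several grid values of f fit equally well
   (within 10⁻⁹ of the data power), the smallest f is chosen (parsimony
   tie-break) and the voxel is flagged `ridge` rather than masked out, so
   downstream means are computed over a known voxel set.
3. *Spatial step* — the f map is regularised by a damped fixed-point
   iteration f ← S(½f + ½f_data) with Gaussian smoother S (default
   σ = 1 voxel; σ = 0 disables), which solves a smoothness-penalised
   problem with geometric convergence; the stopping rule is
   max |Δf| < 10⁻⁴ or 50 iterations. The tissue tensor is re-fit at the
   final f and reported as the water-corrected tensor.

Because all attenuations are taken relative to the per-voxel mean b0, the
estimate is invariant to global signal scaling. On noise-free anisotropic
phantoms the scheme recovers f to ~10⁻⁷ per voxel; f ∈ [0, 1] is a hard
postcondition.

**Information limit at realistic SNR.** The ridge makes per-voxel f
essentially unidentifiable from noisy single-shell data. Concretely, for a
tissue tensor diag(1.7, 0.2, 0.2)×10⁻³ and f = 0.3 at SNR 30, the residual
signal distinguishing the true f from f ≈ 0 (after the tensor absorbs what
it can) is ~0.03 noise-standard-deviations per voxel; even pooling 200
identical voxels, the distinguishing feature is ~0.5 σ, and the exact
pooled profile-likelihood maximiser collapses to f = 0 under both Gaussian
and Rician noise. No estimator can locate f to ±0.05 from such data; the
spatial prior reduces variance (regression-tested) but cannot remove the
ridge-induced bias, and the package's noisy-recovery median error at SNR 30
is around 0.13. Users who need quantitatively unbiased f maps should
acquire a second shell. Skeleton-*mean* FW remains a usable, reproducible
index because its bias is stable across subjects scanned with one protocol,
but absolute values should not be compared across protocols.

## White-matter skeleton

A deliberately simplified stand-in for a full tract-based spatial statistics
pipeline (no group-wise nonlinear registration or perpendicular-search
projection): voxels with FA above a threshold (default 0.2, the common
convention) form the WM mask, and the skeleton is the ridge of its Euclidean
distance transform — voxels whose distance value is ≥ every 6-neighbour and
strictly > at least one. For a plate of odd thickness this is exactly the
1-voxel medial plane; even thickness yields a 2-voxel ridge. Out-of-grid
space counts as foreground so slabs spanning the grid keep their medial
plane. The operator is deterministic and idempotent. (Curve-thinning
skeletonizers are unsuitable here: they reduce plates to curves or nothing,
whereas the white-matter skeleton is a medial *surface*.) The FW index is
the arithmetic mean of f over skeleton voxels outside the lesion mask, with
used/excluded counts reported; flagged non-converged or ridge voxels are
included by default.

## Bayesian model-averaged ANCOVA

For response y (FW index or mean ALPS) and predictors {age, EDSS, group},
all 2³ additive submodels (including the null) get a uniform prior 1/8.
Design conventions: intercept always included; continuous covariates
standardised (mean 0, sample sd 1); the 2-level factor coded −½/+½ by
sorted level order and then mean-centred so every column is orthogonal to
the intercept; the response stays on its raw scale.

Each model's Bayes factor against the null is

BF₁₀ = ∫₀^∞ (1+g)^{(n−1−k)/2} [1 + g(1−R²)]^{−(n−1)/2} π(g) dg,

with k design columns, R² the model's coefficient of determination, and
π(g) an inverse-gamma(½, n·r²/2) Zellner–Siow mixing density. Prior scales
follow the conventional ANOVA defaults — Cauchy r = 0.5 for the factor and
r = √2/4 for covariates — with a single shared g per model and effective
r² equal to the mean of the included terms' r². (Implementations that use
one g per term class can differ in the second decimal; the shared-g choice
is simpler and exactly reproducible against a one-dimensional quadrature
oracle.) Note that with the −½/+½ coding the implied effect-size scale for
the factor is r·n/√(n₁n₂), i.e. wider than r for unbalanced groups.

Numerics: the integral is evaluated on the log-g axis after locating and
subtracting the integrand's peak (bounded scalar minimisation), then
adaptive quadrature on a finite window far beyond both tails; all model
averaging is done with log-sum-exp, so Bayes factors up to e±700 are
representable. Every model's BF is regression-tested to 10⁻⁶ relative
against an independent dense-grid trapezoid oracle, and the group-only
model against an independently-derived two-sample t-statistic form of the
same prior.

Model-averaged outputs: posterior model probabilities
P(M|D) ∝ P(M)·BF₁₀(M); BF_M = posterior odds / prior odds per model; and
per-predictor inclusion Bayes factors (prior-to-posterior change of
inclusion odds), in both the "all models" and "matched models" variants —
which provably coincide on an additive-only space and are reported anyway
for transparency. Rows with missing modelled values are dropped listwise
with a reported count; the analysis is invariant to row order.

## Synthetic data

**Phantoms** (`build_phantom`): a 40×40×20 voxel grid at 2 mm (small enough
for routine CI, same shell structure and voxel size as the reference
protocol), centred on the world origin, containing a projection-fibre slab
(principal axis z), an association-fibre slab (principal axis y), isotropic
background, an optional CSF rim (f = 1), and spherical lesions that
override their host region. Default slab tensors diag(1.2, 0.6, 1.7)×10⁻³
and diag(1.2, 1.7, 0.6)×10⁻³ mm²/s imply an analytic ALPS of exactly 2.0;
background is isotropic 0.8×10⁻³. Signals are assembled voxelwise from the
bi-tensor forward model, so a noise-free phantom is *exactly* consistent
with its ground truth. Noise is Rician by default (magnitude MRI;
sqrt((S+ε₁)² + ε₂²) with ε ~ N(0, S₀/SNR)), Gaussian available for analytic
tests, default SNR 30 (a typical clinical DWI value). Directions come from
an electrostatic-repulsion design with a fixed seed; everything is
byte-reproducible under the spec's seed. Not emulated: EPI distortion,
motion, multi-shell protocols, crossing fibres, partial-volume gradients —
so passing phantom tests demonstrates correctness of the estimators under
the stated model, not robustness to real-world artefacts.

**Cohorts** (`simulate_cohort`): two groups sized 42 (MS) and 21 (NMOSD)
with Gaussian age (33.97 ± 7.52 vs 47.23 ± 11.18 years) and EDSS
(1.48 ± 1.65 vs 2.95 ± 2.79) — the clinical profile of the motivating study
population. Covariates are left untruncated so sample moments converge to
the stated values (occasional negative EDSS draws are accepted as the price
of exact moments in a linear-Gaussian emulator). Outcomes follow
outcome = intercept + δ·group + β_age·age + β_EDSS·EDSS + N(0, sd), group
coded MS = 0 / NMOSD = 1. The group effect δ defaults to 0 (the null
scenario). The remaining coefficients are field-realistic choices fixed
once: FW intercept 0.15, β_age 0.001/yr, β_EDSS 0.005, sd 0.02 (skeleton FW
≈ 0.2 with a moderate positive age trend); ALPS intercept 1.75, β_age
−0.005/yr, β_EDSS −0.02, sd 0.12 (ALPS ≈ 1.5, declining with age and
disability, standardised age correlations ≈ 0.3–0.5 as reported in the
ageing/ALPS literature).

A consequence worth understanding: because the groups differ in age and
EDSS *and* those covariates drive the outcomes, the group factor is a proxy
for age in models that omit age. Under δ = 0 the confounded models
({group}, {EDSS, group}) therefore carry genuine evidence, and the
model-averaged group inclusion BF concentrates around ~0.35 rather than
falling below 1/3 in most replicates. This is a property of the simulated
epidemiology, not of the inference engine: with weaker covariate effects
(or age-matched groups) the inclusion BF drops well below 1/3 under the
null, and it grows monotonically with the simulated group effect
(regression-tested).

**Image-level cohorts**: when phantom specs are requested, each subject's
slab diffusivities and free-water fractions are back-solved so the pipeline
measures approximately the tabled ALPS (Dperp = Dxx/ALPS) and FW values;
under noise the measured FW is biased low relative to the table for the
identifiability reasons above.

## Pipeline

`run_pipeline` processes each subject (phantom synthesis → tSNR screen →
tensor fit → FW fit + skeleton mean → ALPS) and then runs the two ANCOVAs
on the surviving cohort. Subjects below the tSNR cutoff are flagged, kept
in the output table with NaN outcomes, and excluded from inference
(configurable); the run aborts if fewer than 3 usable subjects remain in
either group. Per-subject seeds derive from the master seed as
SeedSequence([master, subject_index]) folded below 2³¹ and are recorded per
row; a re-run with the same config is byte-identical, which the tests
assert on the serialized JSON.

## Known limitations

- Single-shell FW estimation is ridge-limited (see above); noisy per-voxel
  f values are regularisation-dependent.
- The skeleton is a geometric stand-in; it does not reproduce TBSS's
  registration-based projection, so its voxel sets are not comparable to a
  TBSS skeleton on real multi-subject data.
- Shipped ALPS ROI centres are placeholders for atlas-registered data;
  study-grade use requires label-derived centres.
- The Bayes engine covers additive fixed-effect models only — no
  interactions, random effects, or posterior summaries of coefficients —
  and its shared-g prior is a documented simplification of per-term-class
  g mixtures.
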