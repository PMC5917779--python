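# Methods

`handsight` re-implements, over synthetic cohorts, an individual-differences
fMRI analysis that relates everyday prosthesis usage in people with one hand
(congenital or acquired) to two brain measures: the response of visual
hand-selective cortex (lateral occipitotemporal cortex, LOTC) to prosthesis
images, and resting-state functional connectivity between LOTC and the
missing hand's sensorimotor (S1/M1) territory. This note documents the
models, the synthetic data, the parameter choices and their limits.

## Behavioural model

Prosthesis usage is measured by a 27-item Motor Activity Log (MAL; each item
0 = never, 1 = sometimes, 2 = very often) normalized by the maximum score
(54) to a fraction in [0, 1], plus an ordinal wear-time rating 0–5. The
composite usage score is the sum of the two z-transformed measures. We use
the sample (n−1) standard deviation; the cohort-mean composite is 0 by
construction. Controls answer the analogous prosthesis observation log
(POL); their composite is standardized within controls, because the two
instruments are distinct questionnaires answered by disjoint groups.
Subjects with incomplete questionnaires are dropped with a logged warning.
Whether standardization should run over all one-handers or only prosthesis
owners is genuinely open; we standardize over all scored one-handers, and
the choice is confined to `behaviour.usage_table`.

## First-level GLM

Task runs are modelled by ordinary least squares per voxel. Condition
regressors are boxcars at microtime resolution (TR/16) convolved with the
canonical double-gamma HRF (gamma-density difference; response peak 6 s,
undershoot peak 16 s, dispersions 1 s, undershoot ratio 1/6, kernel
peak-normalized). Nuisance columns: six demeaned motion parameters; a
one-hot spike regressor for every volume whose maximum absolute
frame-to-frame parameter change exceeds 1 mm (rotations converted to arc
displacement on a 50 mm sphere, a common convention when the threshold is
stated in parameter space); discrete-cosine drift terms for periods longer
than the 100 s high-pass cutoff; an intercept. The cosine basis replaces the
Gaussian-weighted running-line filter of the original analysis software —
closed-form, testable, and equivalent at these problem sizes.

Contrast maps carry COPE (contrast of parameter estimates), its variance,
and a Z statistic obtained by mapping the t statistic (dof = T − rank X)
through matched tail probabilities, capped at |Z| = 40 where noiseless
voxels would diverge. Runs are combined by fixed effects with
inverse-variance weights; the exact run weighting of the original analysis
is not documented, and inverse-variance weighting is the standard default.
No prewhitening is applied: the synthetic noise is white by construction,
and temporal autocorrelation modelling is out of scope.

## ROI selection and mirror projection

The bilateral visual hand-selective ROI is the union of per-hemisphere
selections: the 250 highest-Z voxels of the hands-versus-objects contrast
with Z > 2, restricted to an occipitotemporal anatomical label (a synthetic
stand-in for the atlas gyri used with real data; the atlas itself is not
bundled). Ties at the cutoff rank break toward the smaller row-major linear
index, which makes selection deterministic and invariant to monotone
transforms of the Z map. The intact-hand sensorimotor ROI is the 200
highest-Z voxels of the hand-versus-feet localizer contrast in the
contralateral pericentral label; the missing-hand ROI is its reflection
across the mid-sagittal plane, x → 2·x_mid − x (x_mid may be half-integral
on even grids). Flip validation correlates, across controls, the
non-dominant-hand COPE sampled under the mirrored dominant-hand ROI versus
a directly localized non-dominant ROI. On the synthetic grid, which is
exactly mirror-symmetric, this correlation is ≈ 1.0 — higher than in real
brains, where anatomical asymmetry attenuates it; the check here guards the
flipping machinery, not anatomical realism. Substitute group-map ROIs for
subjects lacking a localizer are not implemented; such subjects are flagged
and excluded from connectivity analyses.

## Nuisance regression (aCompCor)

The WM compartment: intensity map restricted to a standard WM mask, top
30 000 voxels kept (scaled to 400 on the synthetic grid), then one pass of
morphological erosion with the 6-connectivity (face-adjacency) element. The
CSF compartment: the 2000 lowest-intensity voxels of the subject's CSF map
(150 on the synthetic grid), no erosion. On a real brain the CSF map is
dark only in CSF, so the lowest-intensity rule stays inside CSF; the
synthetic analysis restricts the rule to the CSF compartment explicitly,
since a small grid offers too few candidate voxels for the rule to be
self-restricting. "Eigenvectors" are time-course principal components (left
singular vectors of the column-demeaned T×V block) — only T-length vectors
can enter a T-length regression; signs are fixed by making each component's
largest-magnitude sample positive. The nuisance model is 5 WM + 5 CSF
components + 6 demeaned motion traces = 16 regressors (motion is demeaned
only, not filtered; the original report does not state more). Residuals are
z-scored per voxel; zero-variance voxels are flagged and excluded from ROI
means.

## Connectivity

Per subject, Pearson correlations between the mean cleaned time series of
each sensorimotor hand ROI and the bilateral visual ROI are Fisher
z-transformed (arctanh). Because the two hand territories share
resting-state variance, the missing-hand measure is adjusted across the
cohort by regressing out intact-hand visuomotor connectivity (OLS with
intercept). The covariate is removed from the brain measure only — a
semi-partial ("part") correlation convention, matching how object-related
activity is removed from prosthesis-image activity in the task analysis.

## Statistics

* **Part correlation**: Pearson r between the score and covariate-adjusted
  measure; df reported as n − 2.
* **Permutation test**: the score vector is permuted B = 10 000 times; the
  two-sided p is the add-one estimator (1 + #{|r*| ≥ |r_obs|})/(B + 1),
  never exactly zero, resolution 1/(B+1). Sampling with replacement over
  the permutation group is used rather than exhaustive enumeration.
* **Fisher r-to-z**: Z = (arctanh r₁ − arctanh r₂)/√(1/(n₁−3) + 1/(n₂−3)).
  The within-group active-versus-cosmetic comparison uses this
  independent-samples formula even though the two correlations share
  subjects — this reproduces the published arithmetic (Z = 0.82); a
  Steiger-type dependent-correlations variant is provided but non-default.
  Group comparisons are one-tailed (one-handers > controls), matching the
  directional hypothesis.
* **Commonality analysis**: full-model R² from two-predictor OLS (or the
  closed form (r²ₓᵧ + r²ᵤᵧ − 2rₓᵧrᵤᵧrₓᵤ)/(1 − r²ₓᵤ) when given summary
  R² values, positive-root convention); unique_x = R²_full − R²_z,
  unique_z = R²_full − R²_x, shared = R²_x + R²_z − R²_full. ΔR² F tests:
  F = ΔR²/((1 − R²_full)/(n − 3)) on (1, n−3) df.
* **ANCOVA**: y ~ usage + subgroup with Type-III partial F per term.
* **Group tests**: Shapiro-Wilk, two-tailed t, Mann-Whitney U,
  two-sample Kolmogorov-Smirnov (the classical Z = D√(n₁n₂/(n₁+n₂)) is
  reported alongside D), and a 2×2 group-by-prosthesis-type ANOVA.
* No multiple-testing correction is applied at the ROI level (none is
  applied in the emulated analysis); every seed and B is recorded in the
  output table.

## Synthetic cohorts

The generator emulates the study conditions end to end: 31
analysis-eligible one-handers and 24 controls (3 controls lack
questionnaires, 2 lack the motor localizer — the latter a subset of the
former, so the analyzed control cohort is n = 21 throughout); a
four-condition event-related visual task (hands, objects, active and
cosmetic prostheses; 1.5 s stimuli, 2.5 s fixation, 9 trials per condition
per run, 4 runs, TR 1.3 s); a 12 s on/off block localizer (hand and feet;
controls also move the non-dominant hand; TR 2 s); a 230-volume rest run
(TR 1.3 s); WM/CSF intensity maps; and motion traces (random walk with
~2%/volume probability of a >1 mm jump). Volumes are emitted already
"preprocessed": motion files are nuisance covariates only and never corrupt
the data, since preprocessing proper is out of scope.

Usage questionnaires follow a zero-inflated distribution: ~30% of
one-handers never wear the prosthesis (wear 0, MAL mostly 0 — this
exercises tie handling in the permutation machinery), the rest roughly
uniform; MAL items are Binomial(2, f) draws around the subject's target
fraction. Effects are planted after the behavioural cohort exists: a latent
vector is mixed with the standardized composite as
y = ρ·z(score) + √(1−ρ²)·e⊥ with e⊥ empirically orthogonalized, so the
within-cohort correlation equals ρ exactly. The latents scale (a) the
active-prosthesis response amplitude (planted ρ = 0.5 by default; cosmetic
0.33) on top of a shared "visual load" component that also drives the
object response (removed downstream by the part correlation), and (b) the
subject's missing-hand↔visual coupling, via per-subject correlation
tanh(0.35 + 0.40·latent) between the blob's shared time courses (planted
ρ = 0.55). One-handers additionally receive a +0.20 amplitude offset on
prosthesis images, producing the group difference in mean activity.
Controls' planted correlations default to 0. Rest data include a weak
global component (amplitude 0.3 everywhere, 1.2 in WM) plus WM- and
CSF-specific components, which CompCor must remove; rest voxel noise SD is
0.5, task noise SD 1.0, baseline 100.

One master seed drives everything; per-subject noise streams derive from a
SHA-256 hash of the subject id, so a subject's data are unchanged when the
cohort is resized. Outputs are byte-identical across reruns of the same
config.

What the generator does **not** emulate: MR physics, spatial autocorrelation
and smoothing, physiological noise spectra, anatomical asymmetry,
between-run registration error, and subject-level correspondence to any
real participant (only distributional structure is emulated, since no
subject-level imaging values are published). Passing tests therefore
validate the estimators and their wiring, not robustness to real-data
artefacts.

## Problem sizes and numerical choices

The default grid is 24×24×16 voxels with mirror-symmetric anatomical boxes
(per-hemisphere visual blobs of 180 voxels, sensorimotor blobs of 120, a
756-voxel WM block, a 252-voxel CSF block); ROI requests of 250/200 voxels
then select the whole supra-threshold blob core. The replicate-recovery
suite runs 100 cohorts of 31 one-handers on a 16×16×10 grid, a size chosen
so the full pipeline's estimate distribution can be measured with ~100
replicates in minutes; planted-effect recovery there is attenuated only by
estimation noise (predicted < 0.02 absolute, confirmed by the suite).
Degenerate inputs fail loudly: zero-variance scores, rank-deficient
designs, empty masks, mirror projections leaving the grid, |r| ≥ 1 before
arctanh. Selection and mask ties always resolve toward the smaller linear
index. Permutation p-values use the add-one estimator. The Z statistic cap
(|Z| ≤ 40) only binds for noiseless synthetic voxels.

## Known limitations

* The flip-validation correlation is ≈ 1 on symmetric synthetic grids
  (published value with real anatomy: 0.82); it validates code, not the
  anatomical premise.
* The independent-samples Fisher comparison of overlapping-sample
  correlations is anticonservative; the dependent variant
  (`stats.fisher_rz_compare_dependent`) is the statistically stricter
  choice.
* Group-map substitute ROIs for subjects without a localizer are not
  implemented; those subjects are excluded from connectivity analyses.
* The GLM assumes white noise and a known HRF; neither assumption is
  stressed by the generator.
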