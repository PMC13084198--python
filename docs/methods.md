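# Methods

This note documents the models, numerical choices and open design
decisions behind `thalafc`, in the spirit of a statistical-software
methods appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The phantom's generative model

The synthetic module is the package's ground-truth instrument; it is a
*minimal* model — each distributional choice exists so that one pipeline
stage has matching structure to detect or remove.

**Geometry.** On a cubic grid (default 24³ voxels of 3 mm), seven compact
nucleus blobs cluster centrally (thalamus-like), ten network blobs sit on
a peripheral spherical Fibonacci lattice (cortex-like), and WM and CSF
occupy thin outer shells. The analysis brain mask is the grey-matter-like
sphere containing nuclei, networks and unstructured background voxels;
the compartments lie outside it. Layout is deterministic given the grid;
a grid too small to host all 19 regions disjointly raises an error.

**Signals.** Each network region shares an AR(1) latent u_k(t) with unit
marginal variance and autocorrelation φ (default 0.3). Nucleus i's voxels
carry Σ_k L[i,k]·u_k plus iid Gaussian voxel noise (sd 0.7); network
voxels carry u_k plus the same noise. Under the designated unconscious
condition/group, L[target, modulated] shifts additively by the effect
size. The modulated set defaults to the higher-order networks
{DMN, ECN, FPN1, FPN2}; the presets plant the effect on Pu
("anaesthesia-like", within-subject) or VLV ("DOC-like", between-group),
and the DOC preset scales the effect by 1.6 for imagery-task
non-responders (the more severely impaired subgroup).

**Nuisance.** A shared AR(1) compartment signal fills WM/CSF voxels and
leaks into every brain voxel with coefficient 0.3 (what aCompCor must
remove); per-voxel linear and half-cosine drifts (amplitude 0.5) feed the
detrend/band-pass stage; motion traces are slow random walks with
0.3 mm spikes at probability 0.02 per volume, mirrored by one-volume
image glitches (what spike regressors must absorb).

**The "strong" effect setting.** Defaults are base loading 0.1, effect
size +0.9, noise sd 0.7. The sizing rule: because raising four loadings
simultaneously also inflates the seed's variance, the per-voxel
correlation gain saturates; these values put the planted per-voxel
Fisher-z change at roughly twice its sampling standard deviation at ~100
effective volumes, i.e. individually detectable at small group sizes —
the regime a planted-truth phantom should occupy. The analytic
model-implied correlation (used as the generator's oracle in tests) is

  r(seed_i, voxel_k) = (L[i,k] + λ²) / sqrt((Σ_k L[i,k]² + λ² + σ²/m)(1 + λ² + σ²)),

with leak λ, noise sd σ and m seed voxels.

**What the phantom does not emulate.** No haemodynamic response, no
cardiac/respiratory cycles, no lesions, no spatial autocorrelation beyond
region structure and smoothing, and network regions far smaller than real
ICNs. Passing recovery tests therefore demonstrates that the *inference
machinery* finds what was planted under realistic nuisance — not that the
pipeline's effect sizes transfer to real BOLD data.

## Denoising

Order (fixed in `preprocess_subject`): drop the first 5 volumes →
framewise displacement, outlier scan (> 0.09 mm, strict), subject-level
exclusion screen (> 3 mm or > 3° from the reference volume) → 6 mm FWHM
Gaussian smoothing → confound regression → linear detrend + band-pass.

- **Framewise displacement** uses the sum-of-absolute-differences
  convention, with rotations converted to arc length on a 50 mm sphere:
  FD(t) = Σ|Δtrans| + 50·(π/180)·Σ|Δrot°|. The source analysis tool's
  exact formula is not recoverable; this standard convention is
  threshold-compatible and fully testable.
- **aCompCor**: top 5 principal components (SVD) of the demeaned,
  variance-normalized WM/CSF voxel series; columns orthonormal.
- **Confound regression**: per-voxel least squares against intercept +
  6 motion + 6 derivatives + 5 aCompCor + one-hot spike columns.
  Collinear columns are dropped via pivoted QR with a logged warning.
  Spike regressors are used instead of volume deletion so the temporal
  grid (and the band-pass) stay valid.
- **Band-pass**: zero-phase FFT masking with raised-cosine transitions of
  half-width 25% of each cutoff; gain is exactly 1 in the interior
  passband and exactly 0 in the far stopband, so the frequency response
  is characterizable in closed form. The default band is 0.008–0.09 Hz:
  a literal reading of the upper cutoff as 0.009 Hz would leave about
  half a cycle in an 8-minute run, which cannot be intended, so 0.09 Hz
  is the default and the cutoff remains configuration.
- **Smoothing**: σ = FWHM/(2√(2 ln 2)) per axis in voxel units;
  edge-replication boundary (constant volumes pass through unchanged;
  sums are preserved away from edges).

## Connectivity and ΔFC

Seed series are unweighted means over the nucleus mask. Correlations are
plain Pearson r (the standardized GLM slope); zero-variance voxels are
missing (NaN), never 0. Group statistics operate on Fisher-z maps by
default; the value convention is recorded in every output because the
original toolchain's "beta" convention is ambiguous between r, z and
slope.

ΔFC applies the unsigned magnitude voxelwise before averaging. Seed
self-voxels are excluded from the average (their |Δ| ≈ 0 would only
dilute the statistic); this is configurable. z-scoring uses the
population convention (ddof 0) over all subject × nucleus values of one
comparison — the only choice that makes all nuclei commensurable on one
box-plot axis; mean 0 / sd 1 holds by identity.

For the between-group design, no per-patient baseline exists; each
patient's map is differenced against the voxelwise **mean control-group
map** per nucleus (median available as config). This is a package
decision — the construction is not otherwise determined — and it is
stamped into outputs.

## Inference

- **Nucleus-vs-rest**: mixed linear model z-ΔFC ~ 1 + 1{nucleus=target}
  with a per-subject random intercept, REML (statsmodels MixedLM). The
  fixed-effect t is referred to a Student t with *containment* degrees of
  freedom (n_obs − n_subjects − 1) — a documented equivalent of the
  Satterthwaite approximation at these balanced sizes, where the choice
  moves p in the third decimal. A singular or non-convergent fit falls
  back to the subject-mean-centred paired contrast (the model's
  zero-variance limit), flagged in the result.
- **Rest-of-nuclei heterogeneity**: on a balanced table, within-subject
  centring removes the random intercept exactly, so the omnibus test is
  the repeated-measures F with df (J−1, (n−1)(J−1)).
- **Pairwise and subgroup tests**: paired t of target vs each other
  nucleus (BH-corrected over 6); two-sample t of ΔFC between fMRI+ and
  fMRI− patients per nucleus (BH-corrected over 7 — the one place the
  source procedure names FDR explicitly; BH is also used wherever
  "corrected" is otherwise unspecified).
- **Voxelwise group maps**: two-sided t maps; degenerate voxels with zero
  variance and zero mean give t = 0 (no evidence), nonzero mean with zero
  variance is flagged missing.
- **Cluster-extent FWE**: random-field-theory correction is deliberately
  replaced by permutation of the maximum cluster extent — RFT needs
  smoothness-estimation machinery out of proportion to this artifact,
  whereas permutation is exact under exchangeability and directly
  testable against enumeration. Sign-flips serve paired/one-sample
  designs (exhaustive 2^n enumeration whenever 2^n ≤ the requested
  permutation count, making corrected p exact); group-label shuffles
  serve two-sample designs. Clusters are 6-connected (faces only;
  18/26 configurable). The voxel-forming threshold (p < 0.005) and
  cluster α (0.05) follow the study's convention.

## Network involvement and clustering

The default involvement score is the suprathreshold fraction
|suprathreshold ∩ ICN| / |ICN| at the map's voxel threshold; a weighted
mode (mean |t|) serves unthresholded maps, and a signed companion (mean
signed t) is always computed. Hierarchical clustering is agglomerative
with Euclidean distance and complete linkage on rows (nuclei) and columns
(networks) separately; items enter in canonical order, fixing
tie-breaks. The pipeline clusters the **signed** companion by default:
the higher-/lower-order dissociation is carried by the *direction* of FC
change (higher-order networks strengthen with the target nucleus while
lower-order coupling weakens through seed-variance inflation), and the
signed matrix is what a signed heatmap displays. Unsigned matrices remain
first-class for radar exports. No row standardization is applied by
default (the reference heatmap tool's scaling is unknown); a scale option
exists.

## Analysis scales

Desk-scale study sizes used by the test suite and acceptance script, as
the package's own choice of phantom scale:

- Generative oracle and monotonicity checks: 500 volumes, single subjects.
- Null calibration (mixed model and cluster FWE): 16³ grid, 120 volumes,
  8 subjects, 200 replicates; rejection counts are compared against the
  99% binomial band around the nominal 5% level. The mixed-model
  calibration replicates run generator → connectivity → ΔFC without the
  denoising stage: type-I error is a property of the inference stage, and
  denoising is exercised by its own efficacy check and by the recovery
  runs. The FWE calibration uses structure-free (zero-loading) noise
  cohorts passed through smoothing, since cluster-extent inference
  presupposes spatially smooth noise.
- Recovery: 20³ grid, 200 volumes, 12 subjects (within-subject) or
  12 patients + 10 controls (between-group), 50 replicates per preset.
- Acceptance script: one end-to-end run per preset at the study's group
  sizes (16; 22 vs 16) on the 20³/200-volume phantom, plus 100-replicate
  calibrations.

## Known limitations

- The phantom's subgroup contrast (fMRI+ vs fMRI−) reliably *ranks* the
  target nucleus as the greatest subgroup difference, but its two-sample
  significance at desk scale depends on the boost size and between-patient
  noise; the acceptance script reports the computed p as-is.
- Containment df slightly understates mixed-model uncertainty in
  unbalanced tables; the package only fits balanced ones.
- Exhaustive sign-flip enumeration caps the attainable corrected p at
  2/2^n for two-sided statistics (s and −s give identical |t| maps).
- Nearest-neighbour mask resampling assumes co-registered grids; no image
  registration is performed anywhere.
- Probabilistic atlases are binarized at the maximum-probability label
  before resampling; how the original analysis thresholded its
  probabilistic masks is not recoverable, so this rule is a package
  choice.
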