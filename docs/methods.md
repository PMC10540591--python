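# Methods

`cortdecode` implements a complete pipeline for decoding an ordinal,
self-reported brain state — an 8-level stress rating — from cortical fMRI,
together with a synthetic BOLD generator that makes every stage testable
without access to human data. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
experiments do and do not establish.

## The decoding problem

A subject watches alternating calming and stress-inducing video clips
during 8-minute fMRI runs (TR = 1.5 s, 320 frames per run) and reports a
stress level from 1 (calm) to 8 (maximal) every 15 s, i.e. every 10
frames; each report is taken to describe the preceding 10 frames. Two
sessions of five runs give 320 reports. The decoding task is to predict
the reported level from the concurrent cortical activity — an inherent
state of the subject, not a property of the stimulus — using a model
trained separately for each subject across both sessions.

RMSE on the 1–8 scale is the primary score because the classes are
ordered: confusing level 7 with 8 is a small error, confusing 1 with 8 a
large one. Accuracy (exact 8-class match) is reported alongside. For a
label-independent predictor on balanced labels, the best possible RMSE is
`sqrt(5.25) ≈ 2.291` (constant prediction at 4.5) and independent uniform
guessing gives `sqrt(10.5) ≈ 3.240`; these closed forms anchor the
permutation nulls.

## Surface feature extraction

Whole-brain volumes are too high-dimensional for efficient per-subject
training, and volumetric smoothing mixes gray matter with white matter
and CSF. The pipeline therefore:

1. **samples** each frame at the gray–white mesh vertices by trilinear
   interpolation (vertex world coordinates → voxel coordinates via the
   inverse NIfTI affine; a vertex outside the volume is an error);
2. **blurs along the manifold** by iterated graph diffusion
   `x ← (1−λ)x + λWx`, where `W` is the row-normalised Gaussian-weight
   adjacency (`exp(−d²/2h²)`, `h` = mean edge length) and λ = 0.5. The
   iteration count for a target FWHM is `ceil(σ²/(λh²))` with
   σ = FWHM/2.3548; FWHM = 0 is the identity. The operator is a convex
   average, so constants are preserved, outputs obey the per-frame
   maximum principle, and variance never increases;
3. **downsamples** to K patches by farthest-point sampling under
   graph-geodesic distance (ties → lowest vertex id) with
   nearest-center assignment (ties → lower patch id), averaging vertices
   within each patch. K defaults to 5100, the target dimensionality of
   the cortical feature set;
4. optionally **ranks features** by the one-way ANOVA F statistic of
   feature against the 8-class label, computed on training samples only,
   keeping the top K′ ∈ {1600, 2400, 4700}.

## Temporal preprocessing

The run-level order is fixed: sample → smooth → patch-average →
(optional nuisance regression / high-pass / Wiener deconvolution) →
percent-signal-change → block-average. Each optional step is a no-op when
disabled; disabling all gives the minimal base pipeline intended for
real-time use.

* **Nuisance regression**: OLS residual against six motion traces, an
  HRF-convolved button-press stick (one press per report cue), and an
  intercept; collinear columns are pruned at a 1e-10 relative singular
  value tolerance. Residuals are orthogonal to the regressors and the
  step is idempotent.
* **High-pass**: discrete-cosine drift regression removing components
  below 0.01 Hz (configurable), including the constant.
* **Wiener deconvolution**: `X̂ = X·H*/(|H|²+1/snr)` with the
  double-gamma HRF and snr = 100 by default; used to undo hemodynamic
  delay, not to smooth.
* **Normalisation**: per-run, per-feature percent signal change. When a
  mean-removing filter has been applied, deviations are scaled by the
  per-feature temporal mean recorded *before* the optional steps
  (identical to plain percent change in the base case). Z-scoring is
  available as an alternative.
* **Block averaging**: each 10-frame report window is reduced to
  `floor(10/BS)` non-overlapping BS-frame means using the *last*
  `floor(10/BS)·BS` frames — the earliest frames sit closest to the clip
  transition and are most contaminated by the hemodynamic lag of the
  previous clip. BS5 and BS4 yield 2 samples per report, BS3 yields 3.
  Blocks are non-overlapping (sliding windows are a possible extension,
  not implemented).

The HRF is the canonical double gamma (peak delay 6 s, undershoot delay
16 s, undershoot ratio 1/6), sampled at `ceil(length/TR)+1` points from
t = 0 and normalised to unit peak; the value at t = 0 is exactly 0.

## Decoders and evaluation protocol

Three families, all preceded by feature standardisation fitted on the
training split only:

* **SVM**: RBF-kernel multi-class SVC, C = 100, gamma = "scale";
* **SVR**: RBF support-vector regression on the numeric label, C = 100,
  ε = 0.1; predictions clipped to [1, 8], used unrounded for RMSE and
  rounded (half away from zero) for accuracy;
* **MLP**: two hidden layers (64, 32), Adam, seeded initialisation.

C = 100 is deliberately light regularisation: after smoothing, patch and
block averaging the features have high SNR, and the informative minority
of samples near clip transitions forms small, fully separable clusters
that a heavily regularised margin ignores.

Evaluation repeats a stratified **report-level** 80/20 split 25 times
(seed = base_seed + iteration). The split unit is the 15 s report: block
samples from one report are near-duplicates, so splitting at the sample
level would leak and flatter the score (a property test demonstrates
this). Per-level test counts are `round(n·0.2)`, capped so at least two
reports per level remain in training; a level with a single report stays
in training. Feature-count optimisation reruns the full experiment per
candidate K′ with the same seed schedule (paired comparisons) and picks
the lowest mean RMSE, ties to the larger K′. Conditions are compared with
a paired two-sided Wilcoxon signed-rank test on per-iteration RMSE (all
differences zero → p = 1 by convention; with tied ranks scipy's normal
approximation with tie correction applies).

## Permutation testing

Labels are permuted at the report level — all block samples of a report
keep a common, permuted label — preserving the block structure the split
respects; a sample-level shuffle would be anti-conservative on
autocorrelated data. Each of the 25 permutation replicates reruns the
full experiment and contributes its mean RMSE;
`p = (1 + #{null ≤ observed}) / (1 + n_permutations)` (add-one, never 0;
1/26 ≈ 0.038 is the smallest attainable value). For large permutation
runs the null replicates can use fewer split iterations than the
observed arm (`null_iterations`); their means are noisier but unbiased.

Two empirical properties of this test are worth knowing:

* **Temporal confounding.** True labels are temporally clustered (a clip
  spans 2–6 consecutive reports). Slow drift gives temporally close
  reports similar feature values, so even with *zero* stimulus effect a
  decoder can beat the permuted-label null, whose permutations destroy
  the clustering. The zero-effect calibration protocol therefore enables
  the high-pass step; with drift removed the test is well calibrated
  (observed mean inside the null's central 95% band, taken as
  mean ± 1.96 SD of the null means). This is a genuine property of
  permutation tests on temporally structured designs, not an artifact of
  the implementation.
* **Null location.** Null means are bounded below (up to sampling error)
  by the constant-predictor floor, but can exceed the uniform-guessing
  value: a model trained on permuted labels can be *anti*-correlated
  with the truth on held-out reports, and class imbalance widens the
  spread further.

## The synthetic generator

The generator emulates the acquisition (2 mm voxels, TR 1.5 s, 8-min
runs) and task structure (stress clips of 60/90 s at levels 2–8
alternating with calm clips of 30/60 s at level 1, packed to exactly
480 s, final clip truncated to the 15 s grid; every level appears at
least once per session). The cortex stand-in is an icosphere at a chosen
subdivision level; gray-matter voxels are those within 2 mm of a vertex.

Each level gets a smooth spatial pattern (Gaussian random field, 6 mm
FWHM, unit variance over gray matter). Patterns form a first-order
autoregression across levels with adjacent correlation exactly equal to
`ordinal_overlap` (default 0.6, decaying as 0.6^k with level distance):
the spatial form of the ordinal code, making neighbouring levels
confusable and distant levels not.

The subjective state follows the on-screen clip level through a
first-order lag (`transition_tau_s` = 3 s; 0 gives exact boxcars),
modelling the brief inertia of engaging with a new stimulus; fractional
states are expressed as triangular interpolation between the two nearest
level patterns, and the reported label is the state at the report cue
rounded to the nearest level. At the 3 s default the state settles well
within each 15 s window, so reported labels coincide with clip levels.
The voxel signal is
`baseline · (1 + Σ_l β(v,l) · (w_l ∗ HRF)(t))` with effect amplitude
5% of baseline per unit pattern — a strong, salient-state regime — plus
AR(1) noise (sd 1% of baseline, lag-1 coefficient 0.4), a per-run slow
drift (linear + half-cosine, 1% amplitude; present so the high-pass step
has a target), and optional motion/button artifacts driven by the same
regressors the nuisance step removes. All randomness flows through one
PCG64 stream (`numpy.random.default_rng`) seeded by `params.seed`;
identical seeds are bit-reproducible.

Under these defaults the full-scale subject (icosphere k=5, 10242
vertices, 5100 patches, 2×5 runs) decodes at mean RMSE ≈ 0.6–0.7 with
accuracy ≈ 92–94% for SVM/BS5/top-4700 — high accuracy coexisting with
sub-unit RMSE because residual errors lie almost entirely on
neighbouring levels, concentrated in the first report window after each
clip transition where the hemodynamic lag mixes consecutive patterns.

**What the generator does not model:** physiological (cardiac or
respiratory) noise, inter-subject anatomical variability, realistic
folded cortical geometry, non-stationary stress carry-over across clips,
or label noise in the self-reports. Passing the simulation suite
demonstrates the pipeline's correctness and its statistical behaviour
under a known ground truth; it does not by itself establish decodability
of real stress reports.

## Validation problem sizes

The validation suite balances fidelity against a single-CPU budget:

* the signal-recovery run uses the full-scale subject above
  (~3 minutes including its 25-permutation null with 5-iteration
  replicates);
* the zero-effect calibration uses 20 small subjects (icosphere k=2, one
  session of two runs, 162 features, 4 iterations, 25 permutations);
* the block-size comparison uses 5 small subjects at noise sd 5%
  (standing in for unmodelled physiological variance, where temporal
  averaging matters) with the full 2×5-run protocol. The headline
  direction — BS5 not worse than BS3 — holds in the large majority of
  seeds. BS4 is reliably the *best* of the three in this generator: the
  tail-aligned remainder rule makes BS4 drop the two most
  transition-contaminated frames of every window, an advantage the real
  data pipeline may or may not share;
* the leakage canary compares a feature encoding held-out labels
  (unit-scaled; noise on the training side) against a matched all-noise
  control column over 10 fixed splits: the encoding must not lower test
  RMSE. (For RBF kernels the canary typically *raises* RMSE at
  extreme-label test points, which is why the check is one-sided.)

## Known limitations

* The icosphere is a closed genus-0 surface; disconnected two-hemisphere
  meshes are supported (smoothing warns and stays within components) but
  not exercised by the default protocols.
* Farthest-point patching equalises geodesic radius, not vertex count;
  on highly anisotropic meshes patch sizes can vary.
* The MLP is the slowest and most variance-prone family at these sample
  sizes; it is included for completeness rather than recommended.
* `run_pipeline` handles the simulate-and-decode path; applying the
  pipeline to real data goes through the library API or the `extract`/
  `decode` CLI subcommands with user-supplied NIfTI/GIfTI/TSV inputs,
  which assume volumes and mesh are already co-registered.
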