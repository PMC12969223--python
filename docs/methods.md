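# Methods

## The analysis model

CAP analysis treats each fMRI volume as a point in voxel space and clusters
volumes, not time courses. The pipeline's units are *subject-condition
blocks*: each subject's series is cut into its RUM (rumination), WOR (worry)
and DIS (distraction) blocks, each block is masked to gray matter and
z-normalized per voxel, and the blocks are pooled as if they were different
subjects ("block aliasing"). This yields one shared CAP basis across
conditions while keeping every temporal metric condition-specific.

**Model selection.** For each candidate k (default 4–11), 50 k-means runs are
performed on random 80% frame subsamples drawn without replacement, each with
a single k-means++ initialization. Co-sampling and co-assignment counts
accumulate into a consensus matrix C, where C(i,j) is the share of co-sampled
runs in which frames i and j landed in the same cluster. PAC, the proportion
of pairs with C strictly inside (0.1, 0.9), measures ambiguity; the k with
minimal PAC wins (ties to the smaller k). Pairs never co-sampled are excluded
from the denominator and counted. The thresholds are the conventional ones in
the consensus-clustering literature and are configurable. The final solution
re-clusters all frames with 100 restarts and keeps the minimum-inertia fit;
centroids are recomputed as exact member means.

Subsampling operates at the frame level (the clustering substrate after
aliasing), and k-means uses the Euclidean metric on the normalized frames —
per-voxel z-scoring has already removed scale. Child seeds are derived per
(k, run) from the master seed, so consensus results are independent of
execution order. The scikit-learn Lloyd implementation backs every k-means
call; its empty-cluster relocation (re-seeding at the worst-fit points) keeps
k fixed.

**Labeling.** Centroid z-maps are Pearson-correlated, across in-mask voxels,
with binary indicator maps of a 7-network parcellation; +1 means the network
coincides with the CAP's coactivations, −1 with its codeactivations. The
artifact score of a CAP is the fraction of its top-decile |z| voxels lying on
the one-voxel boundary shell of the mask (6-connectivity erosion); scores
above 0.5 flag the CAP as a likely motion/susceptibility artifact. Both the
decile and the threshold are configurable; the score is invariant to sign and
affine rescaling of the centroid. Substantive CAP exclusions (e.g. dropping
sensory CAPs before statistics) are an explicit user choice, not automated.

**Temporal metrics.** Counts = volumes in a CAP per block; a visit is a
maximal run of identical labels; persistence = mean visit duration in volumes
(so counts = persistence × visits; an optional TR multiplier converts to
seconds). Persistence of a never-entered CAP is recorded as missing, not 0 —
zero would conflate "never entered" with "entered briefly" and bias
regressions toward artifactual negative associations; this choice is a
documented switch-point for sensitivity analyses. RNT = (RUM + WOR)/2
averages rather than sums, preserving the scale so RNT − DIS is meaningful.

**Robust statistics.** Associations between CAP metrics and trait scores use
an MM-estimator with Tukey's bisquare loss: a fast-S search (elemental-subset
candidates plus the LS fit, batch-refined by IRLS with the 50%-breakdown
constant c = 1.5476, keeping the smallest M-scale) followed by an IRLS M-step
at the 95%-efficiency constant c = 4.6851 with the scale fixed, iterated to a
coefficient fixed point (relative tolerance 1e-8, cap 500). Exact fits
short-circuit with unit weights. The implementation agrees with
MASS::rlm(method="MM") to ~1e-2 on contaminated test data (see the oracle
test).

Inference is case-resampling bootstrap (default 10,000 draws): percentile 95%
CIs and two-sided p = 2·min(share ≤ 0, share ≥ 0) with the add-one
correction. Percentile intervals are the default because nothing more
specific is defensible for a robust estimator at these n; BCa is not
implemented. Moderation models use the design
`1 + rnt + neu + rnt·neu + age + sex` with rnt and neu mean-centered before
the product (re-done inside every bootstrap resample); standardized betas
come from refitting on z-scored outcome and continuous predictors with the
product rebuilt from z-scored factors; sex stays a 0/1 indicator. Simple
slopes evaluate b_rnt + level·SD(neu)·b_interaction at level = ±1, with CIs
from the joint bootstrap distribution.

Polynomial model comparison contrasts the linear model with one adding the
squared mean-centered focal predictor. ΔR² uses robustness-weighted residual
sums (R² = 1 − Σw·e²/Σw·(y−ȳ_w)²; each model's own weights), reported in
percentage points with a bootstrap CI. The permutation p-value is
Freedman–Lane — permute null-model residuals, rebuild y, refit both models,
tally ΔR²* ≥ ΔR²_obs — chosen because the comparison is nested; the default
5,000 permutations are configurable. ΔBIC = [n·ln(Σw·e²/n) + p·ln n]
difference (polynomial − null). FDR control is Benjamini–Hochberg step-up;
the test family is whatever p-vector the user passes.

## The synthetic-data generator

The generator emulates the *structure* of a blocked induction study, not its
physiology. A small ellipsoidal "gray-matter" mask sits on a 3-D grid; its
interior (mask minus the one-voxel boundary shell) is partitioned into 7
contiguous parcels by k-means on voxel coordinates, which double as the
reference 7-network atlas. Each non-artifact latent state is the smoothed
(σ = 1 voxel), z-scored indicator of one parcel, lightly decorrelated until
all pairwise |r| < 0.3 (the identifiability ceiling, enforced with an error);
the optional artifact state is the z-scored boundary shell, mimicking the
edge-hugging CAP that empirical studies discard.

Each frame is `amplitude × state_map + N(0, noise_sd)` with lognormal
amplitude jitter (σ = 0.1) preventing degenerate zero within-cluster
variance. State sequences follow a sticky Markov chain,
P(j|i) = ρ·[i=j] + (1−ρ)·π_j with ρ = 0.5, whose stationary distribution is
exactly the planted occupancy π. Occupancy is planted on logits:
π = softmax(base + condition boost + b_rnt·rnt + b_neu·neu +
b_int·rnt·neu), which keeps weights on the simplex for any coefficients and
makes the planted coefficients exactly linear — hence exactly recoverable by
OLS — on the log-odds scale relative to an effect-free state. By default the
DMN-like state 0 carries (b_rnt, b_neu, b_int) = (0.35, 0, −0.45) during the
RUM and WOR blocks only, and is boosted (+0.4 logit) in those conditions,
while a control state is boosted during DIS. Trait scores are standard
bivariate normal with r = 0.5; age ~ N(23.4, 4.0) clipped to 18–45; sex is
Bernoulli with 71.8% female — the demographic profile of a young,
university-recruited sample. Noise defaults to sd 0.5 (half the map's
per-voxel scale).

What the generator does **not** emulate: hemodynamic convolution and
autocorrelated noise, physiological confounds, spatial noise correlations,
inter-subject anatomical variability, and preprocessing residue beyond the
single edge-artifact state. Passing tests therefore demonstrate the
*correctness and calibration of the estimators under the stated generative
model*, not their performance on empirical fMRI, where cluster separation is
far weaker and the true k is not a crisp object.

The spec-scale default configuration (40 subjects, 3 × 120 frames, ~2,000
voxels, k_true = 5) runs the full pipeline in minutes. Tests and the
acceptance script use reduced presets — 8 subjects × 3 × 40 frames × ~320
voxels for clustering recovery, 48 subjects for the end-to-end moderation
runs, n = 110 for pure statistical calibration — sized so the whole battery
completes in about ten minutes on one core while leaving wide recovery
margins at the default noise level.

## Numerical choices and edge cases

- Zero-variance voxels within a block normalize to 0 (logged), not NaN.
- Volume indexing is 0-based, half-open [start, end); the timing table is the
  single source of truth and instruction periods are assumed already outside
  the labeled intervals.
- Normalization convention (per voxel within block, not per volume) is a
  declared choice; per-volume spatial scaling would alter centroid units.
- k-means degeneracy: requesting more clusters than distinct frames raises an
  error rather than returning empty clusters.
- PAC with never-co-sampled pairs: excluded from the denominator, logged; at
  the default 50 runs × 80% the probability of such pairs is negligible.
- MM fits: rank-deficient designs raise immediately; rank-deficient bootstrap
  resamples are redrawn (counted); an estimate falling outside its own
  bootstrap CI (extreme skew) is logged, never silently clipped.
- Bootstrap p-values use the add-one correction, so p ≥ 2/(B+1) > 0.
- Ties in model selection go to the smaller k (parsimony), logged.

## Known limitations

- The consensus matrix is dense (O(n²) memory in frames); at the spec-scale
  default (14,400 frames) it needs ~830 MB per k. Studies beyond that need a
  chunked accumulator, which is not implemented.
- PAC can fail to separate k from k−1 when two planted states are much closer
  to each other than the rest are (the merge becomes deterministic and hence
  "stable"); the generator's near-equidistant parcels avoid this regime, and
  real data may not.
- The artifact flag is a geometric heuristic (boundary concentration); it
  cannot see ventricle- or white-matter-driven artifacts in a mask that
  excludes those tissues.
- Standard errors of MM fits are bootstrap-only; no asymptotic covariance is
  provided.
- The R² entering ΔR² is robustness-weighted; with heavy contamination its
  scale is not comparable to OLS R² (an unweighted variant is a one-line
  switch in `stats._weighted_r2` but not exposed as config).
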