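# Methods

## Polarity coding

Every gray-matter voxel's time series is z-scored on its own mean and
sample standard deviation (ddof = 1; the convention matters only at the
margin, since everything downstream is tercile-based).  Discretization into
intrinsic activation levels supports two modes, because the two natural
readings of "a voxel spends a third of its time in each band" disagree:

- `gaussian_threshold` (default): fixed cuts at ±Φ⁻¹(2/3) ≈ ±0.4307.  A
  voxel's level occupancies are then 1/3 only in expectation under
  Gaussianity; on finite scans the grand mean of h(t) is ≈ 0.333–0.334.
- `empirical_tercile`: per-voxel rank cuts at indices round(T/3) and
  round(2T/3), guaranteeing per-level counts within one sample of T/3
  (53/54/53 at T = 160).

Values exactly at a cut point go to the Neutral band — measure-zero on
real data, deterministic on synthetic integers.

The polarity metric Π(t) = −(h_z · l_z) z-scores h and l per subject over
the subject's own scan using the population SD (ddof = 0), so that
mean(Π) = −corr(h, l) holds exactly; the test suite asserts that identity.
Π is undefined (raises) when h or l is constant over the scan.

## Regimes, participation maps, CoPPs

dPRs are k-means (k = 3, Euclidean) over the pooled per-TR (h, l, n)
vectors of all subjects, with best-of-`replicates` restarts (default 50 in
the library; the pipeline and tests use 5–10 since the small-sample optima
are stable).  Clusters are relabeled canonically — state 0 has the largest
h centroid component, state 1 the largest l among the rest — so labels are
reproducible across initializations.  Empty-cluster handling is delegated
to scikit-learn's KMeans (it relocates empty clusters internally).

The participation map uses the combined-count form

    PPM(v) = (#{High TRs with IAL_v = +1} + #{Low TRs with IAL_v = −1})
             / #polarized TRs

which guarantees PPM ∈ [0, 1].  Summing the two per-state proportions
instead would range over [0, 2]; that variant is available behind
`per_state_denominator=True` but is not the default because it breaks the
unit-interval contract.  Subjects with zero polarized TRs yield an invalid
map that clustering and group tests exclude (with a log entry).

Network-level participation z-scores each network spatial map over voxels
(map scale is arbitrary), keeps voxels with z ≥ 1.25 — about the top 10.6%
of a Gaussian-valued map, commonly described as the top decile — and
averages the subject's z-scored PPM over that voxel set.  Values can be
negative (sub-mean participation).

CoPPs are k-means over the IAL volumes themselves (samples kept int8 until
clustering).  The polarization test treats all of a subject's TRs as one
dependent observation and the brain as 47 independent spatial units, so a
centroid grand mean μᵢ is referred to N(0, 1/(47·nᵢ)) with
nᵢ = n_subjects · rᵢ.  The α = 0.001 mass is placed in each tail by
default (`tail="total"` gives the two-sided split).  This null is
deliberately much wider than the independence null N(0, 1/(V·cᵢ)), whose
cut at whole-brain scale (V·cᵢ > 10⁷) would flag nearly any centroid.  A
consequence at desk scale: with fewer than ~10 subjects the conservative
cut exceeds 0.4, so only strongly pervasive polarization (high gain, low
noise) produces non-neutral CoPPs — the test suite uses such a fixture.

## Itineraries

Group transition matrices pool transition counts across the group's scans
(no transition crosses a scan boundary); `method="mean"` instead averages
per-subject row-normalized matrices, since "group-averaged" admits both
readings.  Itineraries repeatedly follow the largest off-diagonal
probability — itineraries are over successive *distinct* states, with
self-transition probabilities reported separately — until a visited state
recurs, splitting the walk into a transient and a closed orbit.  Ties break
to the lowest state index, deterministically.  By pigeonhole the walk
closes within k steps.

## Connectivity statistics

Network timecourses are band-passed to [0.05, 0.15] Hz with a 5th-order
Butterworth filter applied forward-backward (zero phase).  Sliding-window
FNC uses 22-TR windows (44 s at TR = 2 s) advanced 1 TR at a time, with a
rectangular window convolved with a Gaussian (σ = 3 TR) as correlation
weights; static FNC is the single untapered full-length window, and uses
the full available scan length.  A window covers TRs [start, start + 21]
when aligning window labels to TR labels.

Regressions are OLS with age, gender (binary-coded) and mean framewise
displacement as nuisance covariates; symptom predictors are z-scored and
corrected for the other symptom categories.  FNC responses are Fisher-z
transformed.  Multiple testing uses Benjamini–Hochberg at q = 0.05
throughout.  By default a rank-deficient design raises; the pipeline passes
`drop_collinear=True`, which drops nuisance covariates that add no rank
(in a six-subject cohort, gender can align with diagnosis by chance) while
never dropping the predictor of interest.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
scanner physics.  Each subject's voxel series is

    x_v(t) = gain · s_v · g(t) + a · Σ_n map_n(v) · tc_n(t) + ε_v(t)

- g(t) ∈ {+1, −1, 0} follows a 3-state semi-Markov chain with geometric
  dwell times (mean 8 TRs by default): Neutral polarizes High or Low with
  equal probability; a polarized regime relaxes to Neutral with
  probability 0.7, else swings to the opposite pole.
- s_v ∈ [0, 1] is a smooth participation field — Gaussian blobs on an
  ellipsoidal mask (16 × 16 × 8 grid, ~1,100 voxels) with a central
  ventricle-like zero zone — shared by the cohort and stored per subject as
  ground truth.
- Network maps are well-separated Gaussian blobs; their timecourses are
  band-limited white noise with a shared latent drive over half the
  networks and a weak coupling (0.4) to g(t), normalized to unit variance.
- ε is white Gaussian noise (SD 1.0); the network amplitude is 0.5.

Group enters through the regime gain: controls at 1.5 (with ±10% subject
jitter), patients at 0.8 further shrunk by a per-subject suppression factor
u ~ U(0, 1) (gain × (1 − 0.4u)).  Positive-symptom scores for patients are
7 + 24u plus noise on a PANSS-like scale, so the "positive symptoms
suppress polarization" regression has a recoverable sign; negative and
general scores are pure noise.  Mean framewise displacement is lognormal
and group-independent by default (a confound-free null); an optional
`confounded_motion` scenario inflates patient motion by 50% for testing
nuisance correction.  Ages are uniform on [18, 65], gender Bernoulli(0.5).

The control/patient gain pair (1.5 / 0.8) was calibrated once so that the
diagnosis effect on polarized-regime occupancy has a reliably recoverable
negative sign on cohorts of ~8 subjects; the resulting effect size
(β ≈ −0.2 occupancy units) is larger than clinical-scale reports, which is
the expected trade-off of recovering a sign at a fiftieth of the clinical
sample size.  All randomness flows from a single seed through
`numpy.random.SeedSequence`, so identical configurations reproduce cohorts
bit-for-bit.

What the generator does **not** emulate — hemodynamic convolution, spatial
autocorrelation of noise, scanner drift, multi-site effects, realistic
motion artifacts — bounds what passing tests show: they validate the
estimators and their statistical calibration on data satisfying the model's
assumptions, not robustness to real acquisition artifacts.

## Problem sizes and numerical choices

Tests and the pipeline default to 12 × 12 × 6 or 16 × 16 × 8 grids
(~450–1,100 voxels), 120–160 TRs and 6–12 subjects; k-means restarts are
5–10.  These sizes keep the full suite in the minutes range while leaving
every statistical property (type-I control, sign recovery, centroid
recovery) measurable.  Internal arithmetic is float64; volumes are written
float32 (standard neuroimaging practice, and the analysis is rank-based).
Constant voxels are excluded at load with a warning, since z-scoring is
undefined for them.

## Known limitations

- Convolutional dictionary learning is consumed, not implemented: the
  channel-coding module scores externally learned dictionaries and given
  nonnegative activations only.
- No HMM/GMM alternative to k-means state estimation.
- Anatomical interpretation (network names, region labels) is out of
  scope; networks are indices.
- The conservative CoPP null is honest about small cohorts: below ~10
  subjects it rarely declares any CoPP polarized at default gains.
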