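# Methods

## Problem and signal model

A *recording* is one user browsing one page: gaze samples `(t, x, y)` at a
nominal 120 Hz in screen coordinates, fixations (quasi-stationary
intervals, typically 100–300 ms), the 30–80 ms saccades between them, and
interaction events (scroll, pop-up open/close, click).  Fixations shorter
than 100 ms are discarded before any analysis; the boundary value 100 ms
is kept (the filter is a strict `<`).

Fixations may be imported from tracker software (preferred; flagged
`imported`) or detected by the dispersion-threshold I-DT fallback:
maximal valid-sample windows whose `(max−min x) + (max−min y)` stays
within a dispersion bound (default 50 px, a deliberately conservative
value for a 1280×1024 17″ setup) and whose span reaches the minimum
duration.  Invalid samples (blinks, track loss) never enter detection,
and gaps longer than two nominal sample intervals break every
difference-based computation.

## Layout, hit-testing and occlusion

The page is a set of axis-aligned rectangular components grouped into
disjoint AOIs.  Containment is half-open (`x0 ≤ x < x1`) so shared borders
resolve deterministically.  Scroll is a step function of the event
timeline (no interpolation).  Sticky components (the menu bar) are tested
in screen space before page-fixed components are tested in scrolled page
space; components of the same layer must not overlap (validated at load).
While the pop-up is open, only its own rectangle is active: every other
point is whitespace, i.e. the occluded AOIs are deactivated.  Fixations
are attributed by hit-testing their centroid at *onset* time, because the
pop-up state can change mid-fixation and the onset is when the visit
materialises.

## Windows, labels and fold balance

A recording of duration `T` yields `⌊T/τ⌋` windows (default τ = 5 s); the
trailing remainder is dropped.  A fixation labels every window its
`[onset, offset)` span overlaps — no minimum overlap, since fixations are
routinely interrupted by window transitions.  Majority-class baselines
report, per AOI, the modal class and its frequency (ties at 0.5 report
class 1, an arbitrary but fixed convention) and, for whole vectors, the
modal label vector's frequency.

Cross-validation folds never share users.  Users are assigned to K folds
(default 10) by an exact MILP minimising the sum of absolute deviations of
per-fold window totals from their mean, linearised with auxiliary
variables `U_k ≥ ±(x_k − x̄)` and solved with HiGHS through
`scipy.optimize.milp`.  A brute-force enumeration oracle (capped at
`K^N ≤ 3^10`) verifies optimality in the tests.

## Features

Instances are windows with `t ≥ 2`: every feature describes data strictly
before the window start `To(t)`, so the first window has no usable
history and is dropped rather than zero-filled.  Causality is part of the
contract and is asserted by ablation tests (truncating a recording at
`To(t)` changes nothing).

* **Fixation history.**  Per AOI: time since last visit in seconds (0 when
  never visited — the printed convention overloads 0, which also means "a
  visit exactly at the window start"); lag indicators `r1..r3` echoing the
  window labels at `t−1..t−3` (0 before the recording starts); a one-hot
  of the AOI holding the last fixation of the previous window, summarised
  as `End_r1 = Σ_j j·end_r1_j`.  Per component: a his-flag, time since
  last visit (s), mean fixation duration (ms) and mean gap between
  consecutive visits (ms, offset-to-next-onset; 0 with fewer than two
  visits), a one-hot of the last component fixated in the previous window
  and its integer id in a single `Component_end` column (both encodings
  are emitted since either may suit a given model).
* **Heat_AOI.**  The fraction of *training-fold* recordings whose label at
  the same window index is active; 0 when no training recording is long
  enough.  The reference formula divides by the number of training users,
  but users contribute several recordings of different lengths, so the
  per-recording mean is the only well-defined reading; test-fold users
  never contribute.
* **Visual kinematics (18).**  Over the previous window's valid samples:
  last position, mean and standard deviation per axis; velocity and
  acceleration by `np.gradient` per valid-sample chain (central
  differences inside, second-order one-sided at the edges — exact for
  quadratic trajectories), with the "last value" plus mean/std per axis.
  Degenerate windows yield zeros.
* **Oculomotor (8).**  Counts and mean/max/min of fixation durations (ms)
  and saccade amplitudes (px) over the full interaction before `To(t)`
  ("along time", not truncated to a horizon).  Only *completed* fixations
  (offset ≤ window start) count: the duration of a fixation still in
  progress is not observable at prediction time.

## Resampling and selection

MLSMOTE runs on training folds only.  Labels with `IRLbl > MeanIR` (both
computed once, on the input — a single pass, so a label with two minority
instances yields exactly two synthetic rows) seed one synthetic instance
per bearer: features interpolated uniformly toward one of its k = 5
nearest minority neighbours, binary columns rounded back to {0, 1}
(interpolating a flag is otherwise ill-defined), labels set where active
in more than half of seed + neighbours.  Bags smaller than two are
skipped with a warning.

Mutual information is empirical, in bits.  `discretized_mi` defaults to
floor discretization (the printed convention); the experiment pipeline
defaults to equal-width binning (10 bins) because flooring pixel- and
velocity-scale columns produces near-unique alphabets whose empirical MI
saturates at `H(Y)` and swamps genuinely informative features.  Multilabel
relevance is the sum of per-label MI (the aggregation used by the
selectors' reference toolbox is not published; sum-over-labels is the
simplest consistent choice).  MLMIM ranks by relevance; MLMRMR subtracts
the mean MI with already-selected features; MLJMI maximises the mean joint
MI of the candidate paired with each selected feature against the labels;
F-score sums per-label ANOVA F statistics (a perfectly separating feature
has infinite F, capped at a huge finite value so it ranks first).  Ties
break by column index.  MIFS and RFS are accepted as strategy names but
deliberately unimplemented.

## Classifiers

Features are standardized with training-fold statistics (needed by the
distance-based bases; harmless elsewhere).  Ridge regression is closed
form with an unpenalized intercept, scored by the raw linear output and
thresholded at 0.5.  The kNN base scores by the positive fraction among K
Euclidean neighbours, with distance ties broken by training index; ≥ 0.5
predicts active.  The SVM base delegates to scikit-learn's linear-kernel
SVC and uses its native sign rule, with decision values as ranking scores
(so AUC and precision are reported for SVM too).  Binary relevance fits
one base per label; classifier chains append true earlier labels at
training time and predicted ones at inference, default order = AOI order
1..n.  ML-kNN (k = 15, Laplace smoothing s = 1) combines smoothed label
priors with per-label likelihoods of observing c of k active neighbours.
Hyperparameter grids: λ ∈ 0.25:0.25:2, K ∈ 5:5:30, C ∈ 0.2:0.2:2,
feature counts 5:5:40.  The default configuration is kNN binary relevance
with K = 20 on 10 MLMIM features.

## Metrics

Macro AUC counts, per label, (positive, negative) pairs with
`score(pos) ≥ score(neg)` — ties count as successes, per the printed `≥` —
averaged over labels that have both classes (degenerate labels are
excluded with a warning, not imputed).  Example-based accuracy is the
mean Jaccard index (an instance with empty union contributes 1), subset
accuracy the exact-match rate, precision/recall the usual per-instance
ratios with empty-denominator terms defined as 0, and F the harmonic mean
of the *aggregated* precision and recall (matching the closed formula,
not a mean of per-instance F values).

## Synthetic cohorts

The generator is a semi-Markov walk over seven states (six AOIs plus an
explicit whitespace state, so all-zero label vectors occur and exercise
MLSMOTE).  Dwells are log-normal, truncated to [100, 3273] ms (the filter
floor and the longest observed fixation in the reference cohort);
saccade gaps are uniform 30–80 ms; samples are emitted at 120 Hz with
Gaussian jitter.  Self-transition probabilities are high (0.90–0.93 for
content areas) so a user stays in one semantic area for several seconds —
the realistic reading behaviour that makes window labels sparse and
autocorrelated, which is precisely the lag-1 structure the recency
features exploit.  Pop-up episodes are rare (entry probability 0.008 per
transition, ≈ 4–5 % of time) keeping AOI 6 a strongly minority label.
Scrolling keeps page-fixed targets visible and adds idle drift; recordings
default to 51 users × 3 sessions with log-normal durations of mean
78.8 s (sd 51.9 s, truncated to [16.5, 399] s).  Per-user matrices are
Dirichlet draws around the population matrix (concentration 60 at
perturbation scale 1; scale 0 copies the matrix exactly), and all users
enter at the top of the page — the shared structure that makes `Heat_AOI`
informative.

What passing tests on this generator do **not** show: behaviour under
saliency-driven content effects, reading microstructure, calibration
drift, or real inter-user variability; results on synthetic cohorts
demonstrate that the pipeline recovers planted structure, not field
accuracy.

## Problem sizes and numerical choices

The end-to-end evaluation uses 20 users × 3 sessions × 90 s (≈ 1 000
window instances) and the sensitivity harness 8 users × 2 sessions × 60 s
with two model configurations — sizes chosen so the whole pipeline runs
comfortably on a single CPU while leaving every stage (MILP folds,
MLSMOTE, MI selection, all classifiers) fully exercised.  Timing is
measured around the score/predict call only and reported per window; on
these cohorts it is orders of magnitude below every τ, the online
feasibility condition.

All fits and predictions are deterministic given data and configuration;
MLSMOTE and the simulator take explicit seeds.  Known limitations: the
fold-selection protocol evaluates configurations on test-fold means (no
inner validation loop), `Component_end` uses layout-order integer ids
(models treating it as ordinal should prefer the one-hot companions), and
the MILP, while exact, may return any one of several optimal assignments.
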