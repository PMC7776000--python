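# Methods

## Dynamic connectivity and the dFC-ALFF statistic

A subject's data is a `T × R` matrix of regional signals sampled every
`tr_seconds` (defaults: 195 retained volumes of a 200-volume acquisition at
TR = 2 s; 160 regions). A rectangular window of `width_trs` (default 20 TRs
= 40 s) slides by `step_trs` (default 1 TR); within each window the Pearson
correlation of every region pair is computed and the lower triangle
vectorized in a fixed canonical order (column-wise, pairs `(i, j)` with
`i > j`, `j` outer). Window weighting is uniform and windowed correlations
are kept as raw r (no Fisher transform — a configurable extension point,
off by default, as the modeling contract is defined on raw r). Trailing
partial windows are dropped (`W = ⌊(T − w)/step⌋ + 1`), which at the
default geometry leaves no remainder (176 windows). A region that is
constant within any window makes the correlation undefined; the code raises
an error naming the region and window rather than emitting NaN, because a
silent NaN would corrupt the spectral statistic downstream.

dFC-ALFF is computed per link from the `W`-point windowed-correlation
series: remove the series mean, take the FFT, and sum single-sided
amplitudes `2|X_k|/W` (Nyquist bin counted once) over bins with
`band_low < f_k ≤ band_high`. The band defaults to 0–1/w Hz (0.025 Hz for
the 40-s window); the sampling interval of the dFC series is one window
step (2 s), so the Nyquist frequency (0.25 Hz) comfortably covers the band.
Two deliberate conventions:

* **DC handling.** The nominal band starts at 0 Hz, but the mean is removed
  and the zero-frequency bin excluded. Including it would add the mean
  connectivity level to the statistic and turn a measure of *fluctuation*
  into a measure of *strength*. The half-open bin rule
  (`band_low < f ≤ band_high`) excludes DC exactly once and keeps the band
  edge.
* **Amplitude convention.** Any consistent scaling of the spectrum yields
  identical z-scored features (the per-subject z-score across links absorbs
  global amplitude factors — asserted by a test), so the single-sided
  `2|X_k|/W` convention is cosmetic but fixed, with the Nyquist factor
  chosen so Parseval's identity holds bin-wise.

Per subject, the `L` dFC-ALFF values (or, for the comparator, the `L`
full-scan static correlations) are standardized to z-scores using the
sample (L−1) standard deviation; with `L = 12720` the divisor choice is
negligible but one convention is fixed and tested.

## The predictive model

The association model is connectome-based predictive modeling under nested
leave-one-out cross-validation (LOOCV). For each outer fold (one held-out
subject): an inner LOOCV over the remaining subjects evaluates every
feature-selection threshold on a grid of two-sided correlation p-values
(default .001–.05, step .001; an alternative coarser grid can be
configured); at each inner fold the per-link correlations with the score
are recomputed on the inner-training subset (the leakage-safe reading; a
cheaper select-once-per-outer-fold variant is available behind
`inner_selection="outer_train"`), links with `p <` threshold enter a linear
ε-SVR (C = 1, ε = 0 — fixed, not tuned; solved by libsvm via
scikit-learn), and the threshold's score is the Pearson r between inner
predictions and true scores. The best threshold (ties to the smallest,
i.e. most stringent selection) is used to select and refit on the full
outer-training set and predict the held-out subject. The "integrated" model
keeps positively and negatively correlated links in one regression;
sign-restricted modes exist. A threshold whose selection is empty in any
inner fold is invalid for that fold's tuning; an outer fold where every
threshold is invalid, or whose tuned selection is empty, raises an error —
the pipeline never silently predicts a constant.

Two exact optimizations keep nested LOOCV tractable and are asserted (by
test) to equal the naive loop: per-fold correlation p-values are computed
once and thresholded repeatedly across the grid, sharing SVR fits between
thresholds that select the same links; and the inner fold "hold out k
within outer fold h" trains on the identical subject set as "hold out h
within outer fold k", so each unordered pair is fit once. The SVR solve
uses scikit-learn's low-level libsvm entry point (same solver and tolerance
as `sklearn.svm.SVR`, predictions verified identical to ~1e-14) with the
target centered before the solve, which is exact for ε-SVR because the
dual coefficients sum to zero.

Association quality is `evaluate_association`: Pearson r between
out-of-fold predictions and observed scores, with the two-sided p from the
t transform at n−2 degrees of freedom.

## Contributions, network models, validation

Consensus links are those selected in every outer fold; a link whose
correlation sign flips between folds is excluded (and logged), so each
consensus link carries one sign. Its contribution is the mean over outer
folds of the training-set correlation with the score. Region degree sums
`½|contribution|` over incident links. Network-level indices are computed
per sign group (negative/positive) as sums of `|contribution|` — summing
signed values within a sign group would be equivalent up to sign, but
mixing groups would cancel; a `signed_sums` flag exposes raw sums. Intra
indices take links with both ends in a network; inter indices give half of
each crossing link to either endpoint network; both are scaled by
`N_max/N` to offset unequal network sizes. Pairwise percentages divide each
network pair's `|contribution|` sum by the all-pairs inter-network total.
Reported link-share percentages round to two decimals; raw values are kept
in the output tables.

Network-restricted models rerun the identical nested LOOCV on intra-network
(6) and pairwise inter-network (15) link subsets. Benjamini–Hochberg FDR is
applied separately within the intra and pairwise families (matching their
separate reporting; a combined-family flag exists). A subset run that fails
(typically: too few links for any threshold to select reliably) is reported
as a failed row, excluded from the FDR family, and never flagged
significant.

Validation comprises: the static-FC comparator (same pipeline on whole-scan
correlations); head-motion screening (framewise displacement per volume is
the Euclidean norm of the first differences of the three translation
parameters — rotations in input files are accepted but do not enter this
formula — and the per-subject scalar is the mean FD; each consensus
feature is correlated with mean FD under BH-FDR); and a control-target run
feeding an unrelated score (an anxiety measure in the motivating design)
through the identical pipeline.

## The synthetic cohort generator

No public cohort exists for this analysis, so the generator defines the
study conditions: 200 acquired volumes at TR = 2 s with 5 discarded;
signals confined to 0.01–0.08 Hz by frequency-domain masking of white
noise (exact band control; a recursive band-pass filter family matters for
real acquisitions, not for this synthetic contract); behavioral scores
uniform over 6–29 (the observed range of the target instrument — uniform
for spread, not realism); control scores uniform over 24–57 and drawn from
an independent stream; motion as a score-independent random walk of the
three translations (step SD 0.05 mm).

A planted pair `(i, j)` shares a component `m(t)·v(t)` added to both
regions, with `v` band-limited unit-variance noise and
`m(t) = sqrt(max(0, 1 + A(y)·sin(2π·f_m·t)))`. The windowed correlation of
the pair rises and falls with `m`, so the link's dFC-ALFF increases with
the depth `A` — the construction plants a signal exactly where the
statistic looks. `f_m` defaults to 0.01 Hz, inside the 0–0.025 Hz
dFC-ALFF band. The depth is a linear map of the score across
`depth_range`; for negative-effect links it falls from 2.0 at the minimum
score to 0.1 at the maximum (positive-effect links mirror the map).

Two calibration facts, established by direct large-cohort simulation
before the test thresholds were frozen, shape these defaults:

* Windowed correlation of 0.01–0.08 Hz signals over 40 s rests on ~5–6
  effective degrees of freedom, which caps the precision of any windowed
  estimate; mild depths (A ≤ 1) shift a link's dFC-ALFF by far less than
  its between-subject spread (attainable per-link |r| ≈ 0.2). Depths above
  1 engage the `max(0, ·)` clip — the coupling is silenced for part of
  each modulation cycle — and produce unambiguous effects (per-link
  r ≈ −0.6 at the defaults).
* A region participating in several planted links accumulates shared
  components that act as noise on each other; the standard test cohort
  therefore plants ten ROI-disjoint links between two 10-region networks
  (partition 10/10/3/3/2/2 over 30 regions).

`mean_effect_links` optionally plant a score-dependent *gain* on a shared
component instead (no slow modulation): a cohort whose signal is visible to
static FC but not specifically to dFC-ALFF, used to test the comparator in
the opposite direction.

What the generator does *not* emulate: hemodynamics, scanner noise,
physiological confounds, spatial structure, or realistic score
distributions. Passing tests show the pipeline recovers the statistical
structure it assumes — they say nothing about effect sizes in real
cohorts.

All randomness flows from one seed through named substreams (scores,
control scores, motion, signals), so cohorts are byte-reproducible and the
control score and motion are independent of the planted effects by
construction.

## Problem sizes, numerics, known limitations

* Standard test/acceptance sizes: effect cohort n = 60, R = 30, L = 435,
  ten planted links (a desk-scale stand-in for n = 115, R = 160,
  L = 12720); null cohorts n = 30, R = 21, L = 210; monotonicity checks
  n = 200 at R = 6. These were chosen once as the smallest sizes at which
  each property is stably measurable.
* Tolerances: brute-force oracle comparisons at 1e−10…1e−12; spectral
  closed forms at 1e−6; z-score row statistics at 1e−10.
* Determinism: identical inputs and configuration give identical results
  throughout (no stochastic solver steps; libsvm at fixed tolerance).
* Null behavior of cross-validated association: out-of-fold predictions
  regress toward the training center, which is anti-correlated with the
  held-out value, so under the null the association r is centered near
  zero but heavy-tailed, and the parametric two-sided p rejects at roughly
  15–20% rather than 5% at these cohort sizes. Null screens based on
  parametric p should be read with that in mind; permutation-calibrated
  p-values are the rigorous alternative and can be built from
  `nested_loocv` directly (at ~100× the compute).
* The empty-selection policy (error, never a constant prediction) means
  small noise-only link subsets frequently produce "failed" network-model
  rows; this is reported, not hidden.
* The atlas partition defaults to the published six-network sizes at
  R = 160 (CON 32, FPN 21, DMN 34, SMN 33, OcN 22, CereN 18) and an even
  split otherwise; real analyses should supply their atlas's partition
  table.
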