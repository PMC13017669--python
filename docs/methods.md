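# Methods

This note defines every quantity the package computes, the model behind the
synthetic cohort generator, and the numerical choices made along the way.
Units are stated with each parameter; all defaults live in the code next to
the functions that use them and are repeated here for reference.

## 1. Hypnograms and the night window

A hypnogram is a sequence of 30-s epochs scored as one of five stages in the
canonical order `W, N1, N2, N3, R` (indices 0–4). All features are computed
on the **night window**: the span from *persistent sleep onset* — the first
epoch starting a run of 20 consecutive non-wake epochs (10 minutes) — to the
last non-wake epoch of the recording. A hypnogram without such a run has no
analyzable night and raises `NoSleepOnsetError`.

The window is partitioned into four quarters by the floor rule: with `n`
epochs starting at onset `o`, quarter `i` (0-based) covers the half-open
epoch interval `[o + floor(i*n/4), o + floor((i+1)*n/4))`. Quarters are
contiguous, exhaustive, and differ in length by at most one epoch.

## 2. The feature catalog (330 features, six sets)

| set                 | count | contents |
|---------------------|------:|----------|
| `hypnogram`         |     8 | whole-night TST, REM onset, SSI, 5 stage proportions |
| `spindle`           |    10 | whole-night spindle metrics (section 5) |
| `quarter_hypnogram` |    28 | TST, SSI, 5 stage proportions × 4 quarters |
| `transition`        |   100 | 5×5 stage-transition probabilities × 4 quarters |
| `qeeg`              |   120 | 6 bands × 5 stages × 4 quarters |
| `hypnodensity`      |    64 | (5 stage means + 10 mixtures + entropy) × 4 quarters |

Missing values (`NaN`) mark quantities that are undefined for a given night
(no REM epoch, a stage absent from a quarter, fewer than 5 minutes of N2,
no hypnodensity supplied). The schema itself is fixed.

### Hypnogram features

- **TST** (minutes): number of non-wake epochs × 0.5.
- **REM onset** (minutes): first REM epoch's offset from persistent sleep
  onset × 0.5; missing if the night has no REM.
- **SSI** (shifts/hour): count of consecutive-epoch stage changes divided by
  the window duration in hours.
- **Stage proportions**: fraction of window epochs in each stage (sums to 1,
  wake inside the window included).

Quarter metrics are the same quantities restricted to one quarter (REM onset
is whole-night only). Transition probabilities are row-normalized counts of
consecutive-epoch pairs **with both epochs inside the quarter** — pairs that
straddle a quarter boundary are not counted anywhere, so quarters remain
independent summaries. Rows with no observed departures are missing.

## 3. Quantitative EEG

Input: one EEG channel (C3 by convention) in microvolts, sampling rate
≥ 100 Hz, time-aligned with the hypnogram from recording start.

1. **Filtering** — zero-phase FIR band-pass 0.5–47 Hz (window-method design,
   ~3 s of taps so the 0.5 Hz edge is resolved; applied forward-backward).
2. **Windowing** — non-overlapping 2-s windows aligned to epoch starts
   (15 per 30-s epoch).
3. **Artifact screening** (first match wins, thresholds are implementation
   defaults): *flat* (peak-to-peak < 1 µV), *saturated* (|x| ≥ 500 µV),
   *high slew* (any sample-to-sample step > 100 µV), otherwise *clean*.
4. **Spectral estimation** — multitaper PSD per clean window: DPSS tapers
   with time-bandwidth NW = 2 and 3 tapers (2-s window → ±1 Hz smoothing),
   eigenspectra averaged.
5. **Band powers** — PSD summed over half-open frequency-bin ranges
   `[lo, hi)` for delta 0.5–4, theta 4–8, alpha 8–12, sigma 12–16, beta
   16–30, gamma 30–47 Hz, then normalized to sum to 1 per window. Half-open
   edges prevent double counting of shared boundaries.
6. **Aggregation** — mean normalized power per (band, stage, quarter) over
   clean windows; cells with no clean window are missing.

Normalization makes the features amplitude-scale invariant, which the tests
assert directly.

## 4. Spindle and slow-oscillation detection

**Spindles** are detected on N2 only (the detector refuses nights with under
5 minutes of N2, where its baseline is unstable):

1. Complex Morlet wavelet transform at 13.5 Hz with 10 cycles
   (σ_t = n_cycles / (2π f₀); the kernel is truncated at ±4σ_t and
   L2-normalized). The amplitude |coefficients| is smoothed with a 0.1-s
   moving average.
2. Thresholds multiply the **mean** of the smoothed amplitude over all N2
   samples: core = 4.5×, flank = 2×. A core-crossing is extended outward to
   the flank threshold, events separated by < 0.5 s are merged, and events
   are kept if their duration lies in [0.5, 3.0] s.
3. Per event: duration; amplitude (peak-to-peak of the 11–16 Hz filtered
   trace over the event); frequency = zero-crossings / (2 × duration);
   sigma isolation = the event's sigma-band power-to-N2-background ratio
   divided by the mean of the same ratio over the other five bands.

*Why amplitude × mean instead of power × median:* the sigma-band background
is close to narrowband Gaussian noise, whose instantaneous power is
exponentially distributed — about 3.5 % of background samples exceed
4.5 × the median power, which is an order of magnitude too many false
positives for event detection. The smoothed wavelet **amplitude** has a much
lighter tail, and the mean (rather than the median) baseline is the
convention of widely used spindle toolboxes; `threshold_stat="median"`
remains available as a configuration variant.

**Slow oscillations** (SOs) are detected on the 0.3–1.5 Hz filtered trace
within sleep intervals: a negative half-wave between a down- and the next
up-zero-crossing lasting 0.3–1.5 s, with negative peak ≤ −40 µV and
peak-to-peak (negative trough to following positive peak) ≥ 75 µV.

**Summary features** (whole-night, 10): count; density (events per N2
minute); mean frequency, amplitude, duration, sigma isolation; SO-coupling
proportion (spindles whose interval overlaps an SO); coupling angle and
phase-locking value (circular mean direction and resultant length of the
SO-band Hilbert phase at coupled spindle peaks); dispersion (Fano factor —
variance/mean — of spindle counts per 30-s N2 epoch, 0 for perfectly regular
occurrence, 1 for Poisson, > 1 for clustered).

## 5. Hypnodensity features

A hypnodensity is a per-epoch probability distribution over the five stages
(from an automated stager). Rows must be nonnegative and sum to 1 within
1e-3 (they are renormalized exactly; larger deviations are rejected). Per
quarter: the mean probability of each stage (5), the mean pairwise mixture
`min(p_a, p_b)` for each unordered stage pair (10), and the mean Shannon
entropy in nats (3 significant properties: `min` is bounded by 0.5, zero iff
either stage is excluded, and maximal at a tie — the "mixture of two stages"
reading; the product `p_a·p_b` is available as a variant).

## 6. Synthetic cohort generator

Each participant is generated from a `GroupSpec`:

- **Hypnogram**: first-order Markov chain over the five stages, one step per
  30-s epoch, starting from the group's initial distribution (wake by
  default). The default kernel is a sticky, clinically plausible routing
  (W→N1→N2→{N3, R}). Nights without a persistent sleep onset are redrawn
  from deterministic sub-seeds — a validity constraint mirroring the
  exclusion of unanalyzable recordings. Night length is drawn uniformly from
  `n_epochs_range` (default 700–1100 epochs ≈ 6–9 h).
- **EEG** (128 Hz): a sum of six band-limited unit-variance Gaussian noise
  components, each scaled per sample by `rms_uv × sqrt(profile share)` of
  the current stage, so the per-stage normalized band powers realize the
  stage's spectral profile and the overall RMS is `rms_uv` (default 15 µV).
  The default N2 profile keeps the *background* sigma share at 1 % (≈ 1.5 µV
  RMS), matching the fact that non-spindle sigma background is small —
  discrete events carry the sigma power.
- **Events**: Hann-windowed sigma bursts (13 Hz, 30 µV peak-to-peak, 1.0 s)
  are injected into N2 at `spindle_density` per minute; single-cycle 0.8 Hz,
  120 µV slow oscillations into N3 (3/min) and N2 (1.5/min, so that
  spindle–SO coupling is observable). Injections avoid overlapping each
  other and every event is recorded as ground truth.
- **Hypnodensity**: each epoch's row is Dirichlet with weight
  `concentration` (default 50) on the true stage and 1 elsewhere — larger
  concentration means sharper staging.
- **Missingness**: a configurable fraction (≤ 2 %) of feature cells is
  blanked at the feature-table level, emulating unusable segments.
- Participant seeds derive from the master seed as
  `(master*100003 + 7919*index) mod 2^31`, so cohorts are reproducible and
  participants independent.

Scope: the generator emulates staged recordings *statistically* (spectral
shape, event structure, staging uncertainty). It does not model EEG
morphology beyond that, nor arousals, body movements, or channel artifacts;
the artifact screen is exercised by dedicated synthetic windows in the
tests instead.

Two built-in scenarios support calibration experiments: `null_cohort_specs`
(two groups with identical parameters — any classifier should score at
chance) and `separated_cohort_specs` (fragmented transitions, a gamma-power
offset in N1/N2, quartered spindle density, and blunted hypnodensity in the
second group — separation should be near-perfect).

## 7. Classification framework

For one binary diagnosis task on a feature table:

1. **Outer loop**: R stratified Monte-Carlo 70/30 splits (per class,
   `round(0.7·n)` into training). R defaults to 200 (500 recommended for
   combined/exclusion models); the tests and the acceptance script use
   R = 50 with a single-point grid as a reduced but structurally identical
   protocol.
2. **Missing values**: per split, feature means computed on the training
   side are imputed into both sides (never test-side information).
3. **Tuning**: random-forest hyperparameters (max depth × max features,
   9-point grid) are selected by stratified 10-fold cross-validation on the
   training set, maximizing mean validation AUC. Within each fold the
   training portion's minority class is raised to equality by SMOTE —
   synthetic points are interpolations `x + u·(x_nn − x)` toward one of the
   k = 5 nearest minority neighbors — while validation folds contain only
   original participants.
4. **Final model**: a 500-tree random forest fit on the full, *unaltered*
   training split (no SMOTE), scored on the held-out test split: tie-aware
   rank-based AUC (Mann–Whitney), F1 of the minority class at threshold 0.5
   (ties in class size break toward the lexicographically later label), and
   mean-decrease-in-impurity importances.
5. **Aggregation**: metrics are averaged over runs; importances are
   summarized by mean rank; the mean ROC is the vertical average of
   per-run step-function ROCs on a fixed 101-point FPR grid.

**Combined model**: each set's features are ranked by mean importance rank;
the top 8 per set form a 48-feature model. **Balanced exclusion**: dropping
a set removes its 8 features and refills to 48 by taking the next-ranked
features of the retained sets round-robin (one per set per depth pass, in
canonical set order); if the retained sets run out of features the shortfall
is returned honestly rather than padded.

Group-level mean contrasts use Welch's t-test with Benjamini–Hochberg
adjustment pooled across the whole requested family.

## 8. Clustering framework

1. **Preprocessing** (whole cohort): mean imputation; features missing in
   more than 5 % of participants either raise (default) or are dropped
   (pipeline behavior — stage-conditional features such as REM-band power in
   a REM-free quarter are structurally missing); near-zero-variance features
   (< 1e-8 or < 2 distinct values) are removed; the rest are z-standardized.
2. **PCA space**: the smallest number of leading components whose cumulative
   explained variance reaches 90 %.
3. **Within each diagnosis group**: k-means (k-means++ initialization, 50
   restarts, tolerance 1e-6) for k = 2…10, with k chosen by the
   Calinski–Harabasz index `(B/(k−1))/(W/(n−k))` — higher is better
   (a `minimize` variant is exposed as a configuration switch). Clusters
   with fewer than 10 members are flagged and excluded from comparisons.
4. **Comparisons**: Welch's t-tests between the two largest retained
   clusters on the **original** feature scales (plus demographics, which are
   never clustering inputs), BH-adjusted within the group's family.

## 9. Numerical and implementation choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; every entry point records the seeds it used (the pipeline writes
  them to `manifest.yaml`). Seeds are kept below 2³¹.
- AUC uses midranks, making it exact under ties; it is property-tested
  against explicit pair counting.
- BH adjustment delegates to `statsmodels` and is property-tested against an
  independent step-up implementation; NaN p-values pass through untouched.
- The CH index is computed by definition and cross-checked against
  scikit-learn to 1e-10.
- Problem sizes in tests (2–2.5 h nights, 20 + 20 participants, 50 runs) are
  this package's own reduced defaults chosen to keep the suite fast while
  leaving every structural property intact; full-night defaults (700–1100
  epochs, 200–500 runs, 9-point grid) remain the configured protocol.
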