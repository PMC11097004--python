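# Methods

This note documents the models, numerical conventions and design choices
behind `accelbehave`, and what its synthetic experiments can and cannot say
about real collar data.

## Signal model of the synthetic generator

Each behaviour is a `BehaviourRegime`: acceleration in g on three device
axes (x sway, y heave, z surge) composed of

1. **static gravity**, a unit vector rotated by the regime's pitch and roll
   (`stX = cosP·sinR`, `stY = cosP·cosR`, `stZ = sinP`), so the attitude
   operations invert it analytically;
2. **dynamic motion**: for gaits, a fundamental sinusoid at the stride
   frequency plus one harmonic at twice the frequency and 0.4 the amplitude,
   distributed over heave/surge/sway at 1.0/0.6/0.35 of the regime amplitude
   with fixed phase offsets.  The instantaneous phase is the cumulative sum
   of a per-second frequency series, so frequency resampling never produces
   phase jumps.  For aperiodic regimes (`stride_freq_hz = 0`, i.e. rest) the
   dynamic part is amplitude-scaled white jitter;
3. **white sensor noise** per axis (`noise_sd_g`).

Amplitude is modulated at three scales: a per-individual multiplier
(CV 0.1), a per-bout "vigour" multiplier (`bout_amp_cv`), and a per-second
multiplier (`amplitude_cv`); all are log-normal with mean 1.  Grooming and
feeding additionally resample their frequency each second (`freq_cv`) and
grooming's roll wanders sinusoidally (period 4–10 s) — the "varying
frequencies and postures" character that makes such behaviours hard for
per-sample classifiers.

### Default regimes and why

| behaviour | stride (Hz) | amplitude (g) | posture | amplitude_cv | bout_amp_cv |
|---|---|---|---|---|---|
| rest  | 0    | 0.02 | level          | 0.1  | 0.1  |
| walk  | 1.8  | 0.28 | level          | 0.45 | 0.4  |
| trot  | 2.6  | 0.42 | level          | 0.45 | 0.4  |
| run   | 3.5  | 0.65 | level          | 0.45 | 0.4  |
| shake | 10   | 0.80 | level          | 0.3  | 0.35 |
| feed  | 1.0  | 0.12 | pitch −40°     | 0.6  | 0.3  |
| groom | 1.3  | 0.24 | roll 15° ± 25° wander | 0.8 | 0.3 |

The walk/trot/run amplitudes sit 1.5× apart with bout-level CV 0.4, so
neighbouring gaits genuinely overlap: a vigorous walk bout is
indistinguishable from a lazy trot bout in every derived variable (the
features carry no spectral information, deliberately — stride frequency is
invisible to them, as it is to the real feature set).  Collar shake overlaps
run in amplitude and differs mainly in its second-scale modulation.  Groom
has walk-range amplitude, a level mean pitch and an unreliable roll cue;
its identity is mostly its aperiodicity.  These overlaps are what make the
training-data factorial consequential; with cleanly separated regimes every
dataset variant would score near 1.0 and the comparisons would be vacuous.

### Calibration set

Defaults: 9 individuals; total seconds per behaviour rest 420, walk 240,
run 150, trot 60, feed 80, shake 30, groom 40 (16.3 min, ≈ 115 bouts of
4–13 s).  This is a desk-scale mirror of a realistic calibration campaign
(tens of minutes, on the order of 116 bouts, rest dominant, the confusable
trot scarce next to abundant walk and run, groom and shake under the 60 s
cap).  Totals are divided evenly across individuals to the sample, so
requested label totals are exact.

### Free-ranging deployments

The behaviour sequence is a semi-Markov bout process.  Bout durations are
`2 + Exp(mean − 2)` s — exponential, truncated at the 2 s minimum bout,
with the stated mean preserved exactly.  The embedded behaviour-to-behaviour
kernel has no self-loops and stationary law ∝ budget/mean_bout, which makes
the long-run time fraction in each behaviour equal the configured budget.
The kernel is built by Sinkhorn-balancing the outer product of the
stationary law with its diagonal removed; an exact zero-diagonal kernel
exists iff no behaviour's entry weight exceeds half the total (checked, with
a clear error otherwise).  The default budget is rest 92.1 % (22.1 h/day),
walk 55.4, groom 39.5, run 6.6, trot 5.0, shake 3.5, feed 2.7 min/day.

## Feature engineering conventions

* All running windows (static extraction, VeDBA smoothing, running SE) are
  **centred and edge-truncated**: the window shrinks at the trace ends
  rather than trailing, so features have no phase lag against labels.  A
  window of w samples spans `[i − w//2, i + w − 1 − w//2]`.
* The static window, the VeDBAs window and the SE window all default to
  2.0 s — the one smoothing constant the underlying design states.
* "Standard error" is the windowed sample standard deviation (ddof 1)
  divided by √(window count).  In interior windows the count is constant,
  so this is a monotone rescaling of the windowed SD and classifier
  behaviour is unaffected by the choice; windows with fewer than two
  samples return 0.
* Windowed statistics are computed with cumulative sums (O(n)); tests pin
  them to O(n·w) brute-force oracles at 1e-9.
* Pitch is the surge-axis elevation, roll rotates sway against heave, both
  in degrees; a zero static vector yields NaN and a logged warning.
* Calibration data are featurised **bout by bout** so windows never straddle
  a behaviour boundary (matching per-behaviour grouping before derived
  variables); free-ranging traces are featurised as one continuous stream,
  where boundary mixing is part of the measurement reality.
* 1 Hz aggregation averages non-overlapping whole seconds aligned to each
  bout's start (calibration) or t = 0 (deployments); a trailing partial
  second is dropped; labels attach by majority with ties to the earliest
  label in the block.

## Datasets and models

* Standardisation caps each behaviour at 60 s of records in the variant's
  own time base (2400 at 40 Hz, 60 at 1 Hz), by uniform record-level
  subsampling without replacement; behaviours at or under the cap are kept
  whole.  1 Hz variants are averaged before standardisation.
* The train/test split is record-level (60/40), matching the study design it
  reproduces.  With autocorrelated signals this leaks information — records
  of the same second land in both halves, so test F-measures are optimistic
  relative to new-individual generalisation.  The leakage is acknowledged,
  not fixed, because it is part of the design being studied; a stricter
  bout-level split is available (`split_train_test(..., by_bout=True)`) for
  sensitivity analysis.
* Forests are standard Breiman bagging: 500 trees, 3 candidate predictors
  per split, Gini impurity.  The two node-size knobs map to terminal nodes
  ≥ 5 (`min_node_train`) and splits only above 10 records
  (`min_node_predict`); note a 5-record leaf minimum already implies an
  effective 10-record split minimum, so the defaults coincide naturally.
  Vote ties resolve to the lowest class index (alphabetical), independent
  of the seed.
* Metrics: per-class precision/recall/F from the confusion matrix.  A class
  never predicted has undefined precision (reported N/A); printed-table
  style macro rows average the defined values (SEM = sd(ddof 1)/√k over
  classes).  For *model comparison* the package uses `macro_f_complete`,
  which scores a never-identified behaviour as 0 — excluding N/A would
  reward a model for failing to find a behaviour at all.

## Budgets and reliability

* Budgets are percentages of the labelled stream per behaviour (summing to
  100 per individual); minutes/day = percent × 14.4.  Duty-cycled
  subsampling keeps samples with `t mod 3600 < 900` (first 15 min of each
  hour).
* ICC(A,1) is implemented directly from the two-way ANOVA mean squares,
  `(MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))`, with the F-based
  95 % CI (Satterthwaite degrees of freedom).  Tests verify it against a
  from-scratch sums-of-squares oracle (1e-9) and against pingouin's
  ICC(A,1) row, estimate and CI.  Zero between-subject variance raises a
  flagged error.
* The rating unit pools behaviours across individuals (n = individuals ×
  behaviours, k = 2 methods), since one ICC is reported per model.  Rest
  exclusion removes the rest pairs without renormalising the rest; its
  dominance otherwise inflates agreement.
* Reliability categories apply the 0.9/0.75/0.5 bands to the CI bounds; a
  CI spanning bands yields a compound label ("moderate to good").
* The free-ranging reference labelling is the shipped rule tree applied to
  the first 15 min of each hour — the role a human observer with a decision
  tree plays.  The rule tree is an ordered list of single-variable
  threshold rules closed by an `else` line; the shipped thresholds were
  tuned once on the default calibration set (accuracy 0.80 there; the trot
  band is deliberately narrow because walk/trot/run overlap heavily).

## Problem sizes

Defaults are sized for a desktop core: the calibration study is 16.3 min of
behaviour (≈ 39 000 records at 40 Hz) and the default pipeline deployment is
2 h per individual (the full 2.74-day deployments remain available via
`deployment.full_scale: true` or `DeploymentConfig(duration_days=2.74)`;
label-level simulations of full deployments are cheap and used wherever the
trace itself is not needed).  The multi-seed trend checks run the complete
8-variant factorial at 500 trees over 5 seeds.

## What passing tests do and do not show

The generator reproduces the *structural* features that make training-data
processing matter: posture-coded stationary behaviours, an overlapping gait
amplitude continuum, aperiodic self-maintenance behaviours, rest-dominated
budgets, scarce confusable classes.  Under those conditions the package
recovers the expected directional effects (extended > base at 40 Hz,
40 Hz > 1 Hz for fast behaviours, standardised > inconsistent, the
extended/standardised/40 Hz model first, higher OOB under standardisation).
It does not emulate sensor drift, collar rotation, transitional samples,
individual gait idiosyncrasies beyond an amplitude factor, or truly novel
behaviours; absolute F-measures on synthetic data therefore say nothing
about absolute field accuracy, and the record-level split inflates them by
design.  At 1 Hz with inconsistent durations the extended-versus-base
ordering is seed-dependent — tiny, imbalanced 1 Hz datasets do not reliably
reward extra variables — which mirrors the source study's own model table.

## Known limitations

* No spectral features, magnetometer or gyroscope channels, GPS, or
  alternative learners — out of scope by design.
* The semi-Markov generator requires every behaviour's `budget/mean_bout`
  weight ≤ half the total (true for any realistic budget; violated only by
  a rare behaviour given an extremely short mean bout).
* ICC is undefined when budgets have no between-subject variance (e.g. a
  single behaviour); the pipeline reports such rows as `undefined`.
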