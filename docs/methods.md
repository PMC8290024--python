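# Methods

## Signal model and preprocessing

Two raw channels enter the analysis: wrist skin temperature (WT) at a
nominal 10-min cadence and an arm tilt angle at a nominal 30-s cadence.
Motor activity is derived from tilt as the absolute rate of change,
`|angle_i − angle_{i−1}| / Δt` in °/min (the first sample, having no
predecessor, is masked); body position is the tilt angle itself, the
elevation of the device X axis above the horizontal plane, clamped to
[0°, 90°]. A converter accepts raw 3-axis gravity rows and computes the
same angle as `asin(|ax| / ‖a‖)`.

All channels are averaged onto a common grid of half-open 10-min bins
`[t, t + 10 min)` anchored at local midnight; empty bins are masked, and
partial leading/trailing days are trimmed so every analyzed series spans
whole days. Timestamps are local wall-clock with no DST handling — a
documented limitation that is immaterial for single-week windows.

WT is filtered before binning with two total (never-failing) rules:
values outside 20–40 °C are masked as off-wrist/ambient, and isolated
excursions of more than 2 °C per 10-min step that return to within 2 °C
of the pre-jump value within two samples are masked as contact artifacts.
The thresholds (`wt_range`, `wt_spike_delta`) are configuration keys:
the filter is this package's own definition, deliberately simple and
stated here rather than imported from any particular device vendor's
convention.

Missing data are never imputed: masked bins are excluded from all sums,
variances and window means, consecutive-difference pairs that straddle a
masked bin are dropped, and every summary reports its masked fraction.

## TAP

Each channel is normalized per subject by clipping to its 5th–95th
percentile range and mapping linearly onto [0, 1]; WT is additionally
inverted (`1 − mapped`) because its rhythm is antiphase to activity.
TAP is the plain bin-wise mean of the three normalized channels, so 1
encodes cool-wrist/active/upright wake and 0 warm/still/horizontal
sleep. Percentile clipping (rather than raw min–max, which remains
available as `lo_pct=0, hi_pct=100`) makes the map robust to single
movement bursts or brief sensor artifacts that would otherwise compress
the informative range. By default a TAP bin is masked when any
constituent channel is masked; a renormalized mean of the available
channels can be selected instead (`missing="available"`).

## Non-parametric circadian statistics

With `p` time-of-day bins, `N` valid samples over `D` days, per-bin
across-day means `x̄_b` and grand mean `x̄`:

- `IS = [N · Σ_b (x̄_b − x̄)²] / [p · Σ_i (x_i − x̄)²]`, in [0, 1],
  exactly 1 iff all days are identical; for i.i.d. noise
  `E[IS] = (N/D − 1)/(N − 1) ≈ 1/D`.
- `IV = [N · Σ (x_i − x_{i−1})²] / [m · Σ_i (x_i − x̄)²]` where `m` is
  the number of valid consecutive pairs (`N − 1` for complete data).
- M10 and L5 are the extreme means of 10-h and 5-h windows of the mean
  daily waveform, searched exhaustively over all 144 onsets with
  circular wrap across midnight; window means are weighted by each
  bin's contributing-day count. Ties resolve to the earliest onset, and
  TM10/TL5 report the window **onset** clock time (an explicit
  convention; midpoint reporting is equally defensible but not used).
- `RA = (M10 − L5)/(M10 + L5)`, meaningful for daytime-acrophase
  variables (activity, position, TAP; raw WT has a nocturnal acrophase
  and a physiologically narrow range, so its RA is small by
  construction).
- `CFI = (IS + (2 − min(IV, 2))/2 + RA)/3`: IS, the inverted-rescaled
  IV (clipped at its white-noise ceiling of 2) and RA each contribute a
  third. This combination is linear on IV ∈ [0, 2], which is why it
  commutes with group averaging — applying it to published group-mean
  (IS, IV, RA) triples reproduces the corresponding published
  group-mean CFI values to two decimals, which the acceptance suite
  checks on four independent table rows.

IS and IV are computed on the native 10-min grid by default
(`np_bin_minutes=60` selects the classical hourly variant; both are
legitimate, and results differ modestly). Statistics that are undefined
— zero overall variance, M10 + L5 = 0 — raise `UndefinedStatistic`
rather than silently returning 0 or 1. Six whole recording days is the
default minimum for a summary, the accepted threshold for reliable
non-parametric estimates.

## Screening

The screener is a decision stump: candidate cut-offs are midpoints
between consecutive distinct sorted values of one circadian parameter,
scored by Shannon information gain (in bits, no gain-ratio correction or
pruning — both are moot for a single split); ties break toward higher
training agreement, then the lower cut-off; the predicted side is chosen
to maximize agreement. ROC points and trapezoidal AUC come from
scikit-learn; the AUC equals the two-sample U statistic with ties as ½,
and the tests verify this identity against independent pair counting.

The validation protocol draws 100 random 66 % train / 34 % test splits
(the complement of 66 % is used exactly), fits the stump on each training
part and keeps the iteration with the highest test agreement (ties:
higher test AUC, then lower index). Splits are stratified by class so
both classes appear on both sides — a deliberate tightening of plain
random sampling that avoids degenerate single-class folds at small n
(unstratified splitting is available by flag). Both the best split's
rule and a refit on the full data set are reported, since a published
cut-off may originate from either. Candidate variables are compared by a
two-sided Wilcoxon signed-rank test on per-iteration metrics paired by
split seed; all-zero difference sets short-circuit to p = 1 with a
degeneracy flag.

Sensitivity/specificity orientation is a perennial source of confusion
in screening reports, so every `ClassificationReport` carries explicit
`positive_class` / `negative_class` labels and a `swapped()` view,
letting either clinical orientation be reproduced exactly.

## Synthetic cohorts

The simulator emulates the statistical structure the analysis assumes,
not respiratory physiology. Defaults, chosen once as field-typical
values: sleep onset 23:30 + N(0, 30 min) nightly jitter, 8-h duration;
upright wake base angle 45° with i.i.d. 20° fluctuations per 30-s sample
(daytime activity of tens of °/min); sleep base 5° with 1.5°
fluctuations; an optional afternoon nap (probability 0.3/day, 30–90 min,
position-only — nap prevalence is unreported in clinic populations, so
this is a free parameter); WT 33.5 °C by day and 35.5 °C in the sleep
window with ~1-h smoothed transitions and 0.3 °C noise. Nocturnal
arousals are a homogeneous Poisson process in the sleep window at
`0.25 × AHI` bursts/hour, each burst an exponential-amplitude (mean 35°)
tilt excursion lasting 1–3 samples plus a transient 0.5 °C WT drop with
a 20-min decay; CPAP multiplies the rate by `cpap_factor ∈ [0, 1]`
(default 0.2 for the treated phenotype). Group AHI defaults are 2 / 8 /
22 / 40 events/h for healthy / mild / moderate / severe — mid-bin values
of the clinical strata. Demographics in the manifest are decorative
covariates, never used by generation.

This model reproduces the qualitative group structure of real SDB
cohorts — IS and CFI falling, IV and nocturnal L5 rising with severity,
and CPAP reversing the activity-pattern changes — and the acceptance
suite asserts exactly these sign patterns on 20-subject groups at fixed
seeds. What it does **not** emulate: absolute parameter levels of any
real cohort (no attempt is made to match published group means), SpO₂ or
respiratory channels, inter-subject lifestyle heterogeneity, device
drift, or off-wrist periods; passing tests therefore demonstrate
correctness and directional behavior of the pipeline, not clinical
performance. In particular the near-perfect synthetic screening
agreement reflects the simulator's clean group separation, not expected
field accuracy.

All randomness flows from explicit integer seeds; per-subject seeds are
derived from the cohort seed via `numpy` seed sequences, so cohorts,
pipeline runs and split protocols are bit-reproducible, and pipeline
outputs embed a hash of the analysis-relevant configuration.

## Problem sizes

The shipped tests and the acceptance script use 7-day recordings,
20 subjects per severity group, 15 pre/post CPAP pairs, 100-iteration
split protocols, 500-waveform window-search cross-checks and
300-replicate IS noise calibrations — sizes at which every Monte-Carlo
assertion is stable across seeds while the whole suite runs in well
under a minute on one core.

## Known limitations

- The WT artifact filter is a stated stand-in, not a validated clinical
  algorithm; tune `wt_range` / `wt_spike_delta` per device.
- TM10/TL5 are onset times; compare with midpoint-reporting software
  accordingly (a constant 5-h / 2.5-h offset under symmetric windows).
- No cosinor or parametric rhythm fitting, no sleep scoring from TAP,
  no covariate-adjusted inference (the tidy CSVs are designed for
  export to any statistics environment).
- Whether published group RA values are means of individual RAs or RAs
  of group means is generally ambiguous; this package always reports
  means of per-subject parameters and treats the near-agreement of the
  two conventions as a consistency observation only.
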