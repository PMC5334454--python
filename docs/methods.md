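# Methods

This note documents the models, conventions, parameters and numerical
choices behind `zfsleep`, in the order data flows through the package.

## Traces, clock, and epochs

The central observable is a rectangular matrix of nonnegative locomotor
activity, one row per well, one column per time bin.  Bins are half-open
`[start, start + bin)` and labeled by their start time; an epoch owns a
bin iff the epoch contains the bin's start.  This convention is applied
everywhere (epoch slicing, stimulus windows, opto windows), which makes
every quantification reproducible to the bin.

The acquisition software's movement-detection parameters (15-Hz capture,
detection threshold 15, burst 29, freeze 3) are carried as metadata only
(`VideotrackerSettings`); the package consumes already-integrated bins and
never rescores frames.  The interchange format is a documented CSV (long
`well,bin_start,activity` or a wide matrix); floats are written with
`%.17g` and parsed with round-trip precision, so reader∘writer is the
identity bit for bit.

The base lighting schedule is a 14/10-h cycle with lights on at 9 A.M.
and off at 11 P.M.  Day/night epochs are numbered by developmental day,
anchored by `first_day_number` (the developmental day at the start of the
span); a night carries the number of the day it follows.  Partially
recorded first/last epochs are trimmed by default and the trimming is
logged, since there is no principled way to compare a 5-h fragment of a
day with a full one.  Schedule overrides (ordered, non-overlapping
intervals) take precedence over the base cycle and become
`light-period-K` / `dark-period-K` epochs; they encode the alternation
protocol.

Wells flagged excluded in the plate map (e.g. air bubbles introduced by
plate sealing) are dropped before any computation and can never re-enter
a downstream table.  Merging independent experiments re-keys wells as
`experiment_id:well`; merged larvae are statistically indistinguishable
from same-plate larvae, which matches reporting n as animals.

## Sleep scoring

A sleep bout is a maximal run of ≥ 1 consecutive 1-min bins with activity
exactly 0.  The videotracker has already thresholded movement, so zero is
meaningful; a configurable epsilon exists for re-binned data but defaults
to 0.  Scoring choices that the definitions leave open:

* **Waking activity** is total activity divided by waking minutes (not a
  raw sum).  Per-minute normalization makes epochs of different lengths
  comparable and matches the field's convention of reporting activity per
  waking minute.  An all-sleep epoch has no waking minutes; waking
  activity is then NaN and flagged rather than divided by zero.
* **Sleep latency** with no bout in the epoch is censored at the epoch
  length, flagged, and included at that value in group means (the count
  of censored values is logged).  Dropping censored larvae would bias
  latency downward exactly in the groups that sleep least.
* **Bouts spanning an epoch boundary** are split at the boundary and each
  part assigned to its epoch.  This keeps the conservation identity
  `total_sleep + waking_minutes = epoch_minutes` exact per epoch, at the
  cost of counting a boundary-spanning bout once in each epoch.

## Synthetic data generator

The generator is a test harness that emulates the *structure* of plate
recordings; it is not an inference model, and no attempt is made to fit
it to real data.

The latent process is a two-state Markov chain (sleep/wake) at 1-min
resolution.  Transition probabilities are chosen per bin by the light
state; emissions are 0 while asleep and gamma(shape, scale) while awake,
truncated at 60 activity units/min (the bin capacity).  The gamma family
is an arbitrary choice — nonnegative and right-skewed like real
actograms — that real data cannot be said to constrain.  Defaults:

| parameter | day | night | meaning |
|---|---|---|---|
| p_ws (wake→sleep, per min) | 0.03 | 0.15 | sleep pressure |
| p_sw (sleep→wake, per min) | 0.25 | 0.10 | sleep fragility |
| gamma shape | 2.0 | 2.0 | emission shape |
| gamma scale (units/min) | 3.0 | 1.5 | waking vigor |

These give a stationary sleep fraction of ~11% by day and 60% by night
and mean bout lengths of 4 and 10 min — diurnal structure of the right
order for larvae at 5 days post fertilization.  The closed forms
`sleep fraction = p_ws/(p_ws+p_sw)` and `mean bout = 1/p_sw` are what the
scoring pipeline is validated against.

Light transitions add transients to waking emissions: a single-bin pulse
at lights-on (20 units) and an exponentially decaying burst after
lights-off (30 units, τ = 3 min, so visibly decayed within ~10 min, which
is what the alternation analysis's 10-min exclusion window is for).

Sub-minute traces (5-s bins for tap assays, 10-s for opto) are derived
from the same latent process by seeded Bernoulli thinning: each sub-bin of
a waking minute is active with probability 0.5 and the minute's activity
is split equally among active sub-bins (one is forced if none drew
active).  Sleeping minutes remain all-zero, so 1-min inactivity is
preserved across resolutions.

Tap responses are simulated directly at 5-s resolution: spontaneous
movement with probability `move_background = 0.08` per bin, and in the
bin after a tap of power P movement with probability
`min(1, move_background + top/(1 + 10^((logEC50 − log10 P)·hill)))` with
defaults top = 0.8, EC50 = 8.0 (power-setting units), hill = 1.8.  The
paper-scale protocol (14 powers spanning 1–36.31, 30 trials each, 1-min
ITI) is the default; the 14 power values themselves are not printed
anywhere, so the generator uses 14 log-spaced settings across the stated
range.  Genotype effects are multiplicative modifiers on any parameter;
heat-shock modifiers apply only to carriers of the heat-shock transgene
and only after the shock; the optogenetic multiplier (default 2.0) scales
carriers' emissions during blue-light windows.  Blue-light windows default
to onsets at 1, 4 and 7 A.M. (the stated 3-h intertrial interval read as
onset-to-onset, which keeps all three trials inside the night).

Everything is driven by one `numpy` Generator seeded from the
configuration seed, so identical (config, seed) pairs produce
byte-identical CSV outputs.

What passing tests on this generator shows — and does not.  Recovery of
generating parameters demonstrates that the scoring, correction, fitting
and ANOVA machinery is implemented correctly and is calibrated under the
generator's assumptions (geometric bout lengths, independent wells,
stationary behavior within a light phase).  Real larvae have
ultradian/circadian drifts, well-position effects, habituation and
inter-animal variability that the generator deliberately omits; passing
these tests says nothing about such structure.

## Challenge analyses

*Alternation.*  The quantitative unit is the period mean (activity per
5-s bin); aligned transition profiles are provided as a plotting aid
only.  Dark-period means use only bins starting ≥ 10 min (configurable)
after the offset; light-onset startle bins are *not* excluded from light
periods — the protocol excludes only post-offset data.  The default
period selection is the five light/dark cycles falling in the base-cycle
night, with `cycles="all"` as the alternative.

*Heat shock.*  Each larva contributes exactly one pre and one post value
per metric: the mean of the metric over the phase's two named epochs
(pre: day 5 + night 5; post: night 6 + day 7).  The published design does
not state a combination rule; averaging the day and night epoch keeps the
table balanced and gives both phases the same day/night composition.  The
phase × genotype analysis is a plain balanced two-factor ANOVA; larva is
not modeled as a repeated measure (a caveat, since each larva appears in
both phases — the type-I calibration test shows the plain model holds its
nominal level under the generator, where pre and post windows are
effectively independent given the chain's mixing).

## Startle assay

The pre-tap window is the stated 5 s.  The post-tap response window is
not stated anywhere; it defaults to 5 s by symmetry with the pre-window
and is configurable.  Background is computed per genotype (as the assay
defines it) with per-larva backgrounds emitted for diagnostics.  Dose is
log10 of the solenoid power setting; power 0 is rejected.  Corrected
responses may be negative and are left so.

The sleeping-response assay (5-min ITI, single power 3.02) defines
"sleeping at an event" as zero movement throughout the 60 s before the
tap; the sleeping-response fraction is responders among sleeping trials,
compared across genotypes by one-way ANOVA on per-larva fractions.
Genotypes with no sleeping trials are flagged and excluded with a
warning.

## 4PL fitting and curve comparison

The variable-slope log(dose) model is fitted by least squares
(`scipy.optimize.least_squares`, Levenberg–Marquardt) from a
deterministic multi-start: bottom = min(y), top = max(y), logEC50 =
median log-dose, hill ∈ {±1, ±2}; the lowest-RSS converged start wins, so
fits are reproducible without a stochastic optimizer.  The
parameterization has an exact symmetry (swapping bottom/top while
negating hill leaves the curve unchanged); fits are normalized to
top ≥ bottom, so hill > 0 iff response increases with dose.  Fits require
≥ 5 distinct doses (df ≥ 1).

Curve comparison uses the extra sum-of-squares F test with the fully
pooled model (all four parameters shared) as the null against one curve
per group.  Which parameters were shared in the published analysis is not
stated; fully-pooled vs fully-separate is the standard contrast and is
the one implemented.

## Optogenetic analysis

Analysis bins are 10 s.  Stimulation activity is the total over
`[onset + 1 min, offset)`; baseline is `[onset − 30 min, onset − 1 min)`.
The offset burst is excluded by ending analysis at light-off.  Trials are
averaged per larva before any group statistic, keeping the larva as the
experimental unit (per-trial analysis is available by not averaging, but
per-larva is the default since n is reported as animals).  Normalization
divides by the *genotype-average* baseline, not each larva's own, which
avoids exploding ratios for larvae that happened to be asleep during
baseline.  Fold changes over the control genotype propagate SEM by the
delta method for a ratio of independent means; the control's own value is
1 by construction, and fold changes are exactly invariant to rescaling
all activities.

## Statistics

* One-way ANOVA: classical between/within decomposition; p from
  `F(df_between, df_within)`.  Zero within-variance with zero
  between-variance yields an NaN F (flagged undefined) rather than 0/0.
* Two-way ANOVA: balanced orthogonal decomposition with interaction;
  unbalanced layouts are rejected outright rather than silently picking a
  sum-of-squares type.  Cells need n ≥ 2 for the interaction to be
  estimable.
* Tukey's HSD: Tukey–Kramer statistic
  `q = |mᵢ − mⱼ| / sqrt(MS_within/2 · (1/nᵢ + 1/nⱼ))`, adjusted p from
  `scipy.stats.studentized_range` with (k, df_within) — a documented
  numerical distribution validated in the tests against a Monte-Carlo
  oracle (agreement within 2% at k = 3, df = 20) and against
  `scipy.stats.tukey_hsd`.
* Student's t: pooled-variance two-sample t by default (a Welch option
  exists but is off, since the analyses specify Student's t).
* ELISA: the standard curve is a 4PL over log10 concentration fitted to
  the nonzero manufacturer standards and checked monotone over their
  range; the 0-standard's absorbance anchors clamping.  Inversion is the
  closed-form inverse of the 4PL; readings beyond the 0 standard on the
  low-concentration side return exactly 0 with a `clamped_zero` flag
  (negative estimates are rounded up to zero), and readings beyond the
  top standard are flagged `above_range`.

## Problem sizes and validation

The test suite validates: bout detection against an independent
brute-force scanner (exact agreement on 10,000 random day-long traces);
the conservation identity on a full simulated 96-well, 3-day experiment;
Markov closed forms within 3 SE at 10,000 simulated minutes for three
parameter sets (the standard error accounts for the chain's
autocorrelation); EC50 recovery within 5% from a full 96-larva × 14-power
× 30-trial simulated assay and exact (RSS < 1e-10) recovery on noiseless
curves; type-I error of the one-way ANOVA, two-way interaction, extra-SS
F and Student's t inside the binomial 99% CI of 0.05 under their nulls
(10,000 / 500 / 500 / 10,000 simulations); detection of the simulated
heat-shock effect (carrier p_ws × 0.3 post-shock) in ≥ 90% of 200 seeded
experiments; recovery of the 2× optogenetic multiplier as a fold change
of 2.0 ± 0.2 over three merged experiments; and the ELISA round trip to
1e-9.  These sizes keep the whole suite under two minutes on one core.

## Known limitations

* The generator's activity distribution, transient shapes, and effect
  sizes are the package's own choices; only their *structure* mirrors the
  assays they emulate.
* Repeated-measures structure (pre/post within larva; trials within
  larva) is handled by averaging to one value per larva, not by mixed
  models.
* The alternation analysis assumes the override schedule is known exactly;
  it does not infer light transitions from the traces.
* Latency censoring at the epoch length biases group means toward the
  epoch length in very low-sleep groups; the censored count is logged so
  users can judge.
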