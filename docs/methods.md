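# Methods

## Apparatus, tasks, and schedule

The apparatus model is a rectangular corridor of four segments indexed 0–3
clockwise from the start corner. Each segment holds two inner and two outer
side boxes (16 in total, ids `I1..I8` / `O1..O8`) and one midpoint
locomotion sensor (`M0..M3`). Three baiting tasks are defined: Task 1 baits
all 16 boxes (the only symmetric task), Task 2 the 8 inner boxes, Task 3
the 8 outer boxes. The Task 3 = outer-boxes assignment is the package's
reading of the external-side phase label; nothing downstream depends on
which asymmetric side is which, only on the rewarded/non-rewarded split.

The built-in schedule is 4 baseline trials on one day (2 × Task 1, then
2 × Task 2 three hours later) and 16 post-treatment trials over four days:
2 × Task 1 (day 11), 6 × Task 3 (days 11–12), 8 × Task 2 (days 13–14).
Every phase maps to exactly one task, so phase labels double as task keys.

Event logs are plain CSV (`animal_id, trial_id, phase, task, timestamp_ms,
kind, location`), UTF-8, integer milliseconds, one trial per contiguous
block. The format is deliberately minimal and auditable; `read_event_log`
enforces monotone timestamps, known locations, phase/task consistency, and
the reward invariants (baited box only, at most once per box). The dialect
carries no treatment-group column — group is experiment metadata, supplied
to `score --groups` as a separate mapping when needed.

## Trial scoring

All eleven parameters are pure functions of the event list and the task.
Decisions where the parameter definitions leave room:

- **Eat_T under incomplete collection** is the full 300 s window. This
  makes learning capacity degrade gracefully to
  `L_C = Eat_N / n_rewards × 100`, the fraction of rewards collected.
- **"Up to" windows are closed**: an event at exactly `Eat_T` (including
  the final reward-consuming visit) counts. Likewise a visit at exactly
  t = 300 s counts in the whole-trial tallies.
- **Skipping** counts corridor crossings with timestamps *strictly* before
  the first box visit (same-millisecond ties resolve to the visit). An
  exploration-free trial has skipping 0 by convention — the quantity is a
  pre-first-exploration count, undefined without an exploration, and zero
  keeps it summable.
- **Latency censoring**: a box class never visited gets latency 300 s.
- **Undefined is missing, not zero**: the side-discriminating parameters
  (`expl_fr_nrw`, `lat_nrw`, `w_m`, `r_m`) are reported as missing under
  the symmetric task, as is any ratio with a zero denominator; a reason
  code accompanies each.

The test suite holds an independent brute-force scorer (a literal re-pass
over the event list) and checks exact agreement on more than a thousand
simulated trials, plus a hand-computed reference trial covering every
parameter.

## Normalization

Trials are reduced to per-animal phase means before z-scoring; the mean is
the conventional reduction and makes the phase value of an animal
well-defined even when individual trials are missing. Z-scores are computed
within each (phase, parameter) cell over all animals pooled across groups,
using the sample SD (n−1); the divisor is switchable (`ddof=0`) because
"population SD" is ambiguous in common usage. Cells with SD = 0 or fewer
than two values are flagged degenerate and left missing rather than
zero-filled. The inversion registry is exactly {`lat_rw`, `lat_nrw`,
`skipping`} — the parameters where a larger raw value is an impairment.

A structural consequence worth knowing: because z-scores are centered
within phase, the within-subject "phase" main effect in the mixed ANOVA is
identically zero on z-scored data. Group and group × phase effects are
unaffected. Phase main effects are meaningful only on raw scores.

## Statistical battery

All routines are computed from explicit sums of squares (the split-plot
decomposition for the mixed design) and cross-checked in the tests against
scipy and pingouin.

- **Unpaired t** is the pooled-variance Student form by default, Welch
  behind a flag.
- **Greenhouse–Geisser epsilon** comes from the double-centered pooled
  within-group covariance of the phase measures,
  ε = tr(S̃)² / ((k−1)·tr(S̃²)), clamped to [1/(k−1), 1]. "Applied where
  appropriate" is operationalized as: apply when Mauchly's test rejects
  sphericity at p < 0.05 (`gg="auto"`), with `always`/`never` overrides.
  Note that the familiar guarantee "GG-corrected p ≥ uncorrected p" holds
  in the F ≥ 1 regime the correction exists for; for F < 1 shrinking both
  dfs can move p the other way.
- **Fisher's LSD** is reported unadjusted by construction; the result
  objects carry a note that multiplicity is uncontrolled.
- **Outlier rule**: drop x with |x − mean| > 2·SD, mean and SD from the
  full sample, single pass, never iterated. Sample SD (n−1).
- **Missing phases** trigger listwise deletion (classical RM-ANOVA); no
  imputation.

Calibration: under null simulations (500 replicates) the empirical type-I
error of both the one-way and the mixed ANOVA lies within Monte-Carlo error
of α = 0.05, p-values pass a KS uniformity check, and F = t² holds exactly
for two groups.

## Behavioral simulator

The simulator is a discrete-event model, not a kinematic one: inter-
transition times on the corridor cycle are exponential with rate
`move_rate`, each transition fires the midpoint beam, and each pass offers
at most one box visit. The trait set (exploration probability, attentional
lapse probability, baited-side bias, revisit probability, consumption
probability, mean dwell) was chosen as the minimal set that moves the
eleven scores independently: side bias is the reference-memory dial (it
only acts under asymmetric tasks; under Task 1 side choice is uniform),
revisiting the working-memory dial, lapses the skipping dial. A rat that
would re-enter an emptied baited box redirects to its unemptied same-side
neighbour when it "remembers" (probability 1 − revisit_prob), else either
revisits or skips. Each box holds one reward, consumable once, ~0.5 s into
the dwell.

Baseline defaults (move_rate 0.10 s⁻¹, explore_prob 0.6, side bias 0.5,
revisit_prob 0.25, consume_prob 0.9, lapse_prob 0.15, dwell 4 s,
between-animal CV 0.2, lognormal) give a naive animal ~25–35 corridor
crossings and ~10–15 box visits per 300 s trial with most but not all
rewards collected — mid-scale on every score so that group effects can move
scores in either direction. Group effects are multiplicative trait
modifiers with lognormal between-animal scatter; probabilities are clipped
to [0, 1]. Reproducibility uses a single root seed split per animal and per
trial via `numpy.random.SeedSequence` spawn keys, so any animal-trial can
be regenerated in isolation.

What the simulator does *not* emulate: drug pharmacokinetics (group effects
are abstract trait multipliers), spatial trajectories between sensors,
habituation or learning within a session (traits are constant over the
schedule), and circadian/session effects. Passing pipeline tests on
simulated cohorts therefore demonstrates that designed trait contrasts
propagate through scoring, normalization and the ANOVA battery with correct
calibration — not that real treated animals behave like the model.

Recovery checks: a move_rate × 1.5 contrast at 8 animals/group is detected
by the post-phase one-way ANOVA on z-scored locomotion with power > 0.8
(20 replicate cohorts); with no designed effect the rejection rate over 200
replicate cohorts is consistent with α = 0.05. The null calibration runs on
the two post-treatment asymmetric phases with 6 animals/group — the size at
which 200 full pipeline replicates stay cheap while leaving the ANOVA
well-posed.

## Saturation binding

The one-site model `B(L) = Bmax·L/(Kd+L)` is fitted to specific binding
(mean total − mean nonspecific per concentration, duplicates averaged
within assay first) by unweighted nonlinear least squares
(`scipy.optimize.curve_fit`), matching the convention of fitting the
specific-binding transform rather than a simultaneous total + nonspecific
model. The start heuristic is deterministic: Bmax₀ = 1.2 × max observed
specific binding, Kd₀ = the interpolated concentration at half Bmax₀.
Standard errors come from the estimate covariance; a Kd above 3× the top
concentration is flagged poorly constrained. Independent assay repeats are
fitted separately and serve as the units of the group t-tests, and the
comparison table reports both across-assay SEMs and per-fit SEs since
either can be the published uncertainty. Unit conversion uses 1 Ci =
2.22 × 10¹² dpm, i.e. 2.22 dpm per fmol per (Ci/mmol) of specific
activity; counting efficiency divides the raw dpm first.

The synthetic generator adds a linear nonspecific component (default
20 fmol/mg per nM, ~15% of total binding at the top of the design range)
so the total/nonspecific columns both carry signal. Noise-free generator →
fit round trips recover the generating (Bmax, Kd) to numerical precision
for all parameter sets used in the tests; recovery is also scale-
equivariant (Bmax scales, Kd invariant) and asymptotically unbiased as
noise → 0.

## Assay quantification

Densitometry: value = (target OD − local background) / (actin OD − local
background); non-positive net actin invalidates the sample with a reason;
the mean ± 2 SD screen then runs per group (skipped below n = 3). The
ratio is invariant to common rescaling of all four ODs.

Intake/dose: daily fluid is normalized to body weight first
(mL/kg/day), dose = fluid_per_kg × drinking-water concentration (mg/mL)
per drug and day, then averaged across days within animal; group summaries
are mean ± SEM (sample SD / √n) across animals. The per-day-then-average
order is the package's choice where either order is defensible; for
constant weight within a day the two differ only when fluid and weight
co-vary across days.

## Problem sizes and numerical conventions

Default test-suite problem sizes: ≥1000 simulated trials for the scoring
oracle, 500 replicates for ANOVA calibration, 20 designed-effect and 200
null cohorts for pipeline recovery — sizes at which every Monte-Carlo
band used in an assertion is at least ±3 SE wide. Tolerances: exact
(1e-12-ish) agreement for the scoring oracle and hand fixtures, 1e-8–1e-10
against the scipy/pingouin cross-checks, 0.1% for binding recovery.
Tie-breaks and degenerate inputs are enumerated above per module; every
degenerate path returns a flagged result rather than raising, except where
the input itself is malformed.
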