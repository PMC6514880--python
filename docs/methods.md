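# Methods

This note documents the analysis procedures implemented in `motorseq`, the
assumptions behind them, the choices made where the procedures were
genuinely underdetermined, and what the synthetic-data generators do and do
not emulate.

## Data model

All times are seconds as floats. The operant box records events on a 10 ms
grid; that grid is enforced only at the operant CSV boundary (values are
snapped with a warning), never internally, so electrophysiology at
sub-millisecond resolution and behaviour share one container model. Rung
indices are 1-based (37 rungs per side on the full apparatus). Ladder
touches are ordered by onset with ties broken by rung index. Licks and head
entries are instantaneous point events, matching contact-lickometer and
IR-beam acquisition.

## Operant sequence microstructure

**Segmentation.** A boundary is placed between adjacent presses when the
open interval between them contains ≥ `break_lick_count` licks (default 10;
a consumption bout) or when the inter-press interval is ≥ `break_gap`
(default 20 s self-paced, 6 s high-speed; disengagement). The lick bout is
defined purely by the count of licks between the two presses — the
acquisition stream has no bout structure of its own, and this makes the
break rule and the per-interval classification use identical event counts.

**Tie-breaking.** An entry or lick with a timestamp exactly equal to a
press is attributed to the interval *after* that press (membership
`a ≤ t < b`). On a 10 ms grid exact ties occur; this rule makes the
segmentation deterministic.

**IPI taxonomy.** Precedence: *ultrafast* (interval ≤ 0.25 s with no
intervening entry or lick — lever bounce; an eventful short interval is
classified by its events), then *consumption* (lick count at or above the
bout threshold), then *gap break* (interval ≥ `break_gap` that did not
qualify as consumption), then *check* (≥ 1 entry), else *rapid*. Two
deliberate resolutions of ambiguity:

- The printed rules "break at ≥ 10 licks", "check ≤ 10 licks" and
  "consumption > 10 licks" are mutually inconsistent at exactly 10. Here
  ≥ 10 licks is consumption and breaks the sequence; check requires < 10.
  This makes breaking and classification consistent at the boundary.
- Long disengagement pauses form their own excluded `gap_break` class
  rather than joining any analysed group, so heavy-tailed pauses cannot
  contaminate check/rapid summaries. A consumption bout that also spans
  ≥ 20 s stays consumption (the lick bout explains the pause).
- Consumption with zero entries is physically implausible (licking implies
  a magazine entry); such intervals are classified consumption but carry an
  `anomaly` flag.

The five classes partition the n−1 adjacent press pairs exactly. Ultrafast
intervals are deducted from the rapid group before any summary, so the
minimum surviving rapid IPI always exceeds 0.25 s.

**Summaries.** Each class is summarised by the median, the median absolute
deviation MAD = median(|x − median|), and MAD/median, a scale-free
dispersion suited to heavy-tailed interval data; each summary is also
recomputed restricted to IPIs ≤ 20 s as a robustness check. Sequence
features: length, duration (first to last press), inter-sequence interval,
and mean within-sequence IPI. The within-sequence mean averages *all*
adjacent intervals of the sequence (a per-class breakdown is also emitted,
so the alternative reading costs nothing). Press efficiency is
(reinforcers × ratio / presses) × 100 and is undefined (flagged NaN) for a
session without presses.

**Bimodality diagnostic.** `estimate_ultrafast_threshold` locates the
density valley of a rapid-IPI sample on a log scale with a Gaussian KDE
(Silverman bandwidth). A valley is only reported when it dips below 90 % of
the smaller of the two largest modes; KDE wiggles on unimodal samples do
not qualify. It is a diagnostic — the classification threshold stays at
0.25 s.

**Learning curves.** `aggregate_training` implements dropout imputation:
for sessions up to a configurable limit, a missing animal receives the mean
of the remaining animals of its group for that session; beyond the limit
values stay missing and the reported n drops. A session where an entire
group is missing raises an explicit no-imputation-possible error.

## Ladder locomotion

Touches lasting ≤ 30 ms (strict inequality: exactly 30 ms is dropped) are
sensor false positives. Steps are consecutive pooled touch pairs; step
length is the signed rung distance along the direction of travel (the
regular lengths 2 and 4 refer to the rung pattern, not a single limb; a
per-side computation is available). Step time is defined only between
consecutive same-side touches — the sensors report side, not paw, so each
side is treated as one front-limb stream; this is an approximation.

Taxonomy: +2/+4 between high rungs are small/large regular; anything else
is irregular with exactly one kind — *misstep* when either endpoint is a
lowered rung (misstep takes precedence within irregular: the metric is
defined by low-rung contact), *backward* only within runs of ≥ 2
consecutive negative steps (an isolated negative step is `other`, so a
hind-limb touch is not mistaken for backward walking), *leap* for lengths
> 4, else `other`. Backward-run context is computed over the whole trial
before the first/last-step omission. The first and last step of each trial
(shelter exit/entry) are excluded from all counts, including missteps.

In perturbed trials the obstacle is a lowered rung elevated 18 mm; stepping
onto it is not a misstep (elevation, not index parity, drives the misstep
test). Tone and obstacle metadata are carried through but do not enter the
misstep metric.

The session metric is 100 × (#trials with ≥ 2 misstep steps)/(#trials),
with the total misstep count per session as a secondary readout.

## In-vivo spike modulation

**Identification.** For each complex spike at time c the pause test asks
whether no simple spike falls in (c, c + w]; the cell passes when the
paused fraction reaches `min_fraction`. The pause window defaults to 10 ms
and the fraction to 0.95 — conventional climbing-fibre pause scale; both
are configurable because the acquisition literature states neither.

**Locomotion mask.** Movement is |v| above a threshold defaulting to 5 %
of the recording maximum, with sub-threshold gaps ≤ 1 s bridged; contiguous
movement spans shorter than 20 s are excluded (neither rest nor
locomotion). The threshold and hysteresis are configurable; no specific
values are dictated by the acquisition.

**Rate and smoothing.** The instantaneous rate is the reciprocal of the
inter-spike interval containing each grid sample, extended by the nearest
interval outside the spike span. Smoothing convolves with a unit-area
Gaussian whose 200 ms "window" is read as full width at half maximum
(σ ≈ 84.9 ms); a σ reading is available via a parameter. Edges use
reflect padding; the kernel is truncated at ±4σ and renormalised, so a
constant trace is a fixed point and the impulse response sums to one.

**Epoch correlation.** Rate and velocity are linearly resampled to a
common 10 ms grid (the acquisition rate of the wheel encoder is not fixed
by the hardware description; 10 ms resolves the 200 ms kernel and epoch
step exactly). Within every 2000 ms epoch advanced by 200 ms inside a
locomotion span, velocity is z-scored and Pearson-correlated with the
smoothed rate; epochs with zero variance in either signal are undefined
and excluded. The per-cell statistic is max |r| over epochs, with no
within-epoch lag scan (the statistic is a per-epoch correlation maximised
across epochs; z-scoring cannot change r — asserted by test). Rates at
rest and during locomotion are spike counts over state durations, with
spikes inheriting the state of the velocity sample containing them; rest
rates use all rest time.

## In-vitro waveform features

Spikes are voltage peaks above a configurable detection height (0 mV
default). "Threshold at the steepest slope before the spike" cannot be
taken literally — the steepest slope lies mid-upstroke — so the default
detector places threshold at the maximum of the second derivative
(upstroke onset, maximum curvature) in a 3 ms window before the peak; a
dV/dt-criterion detector (default 20 mV/ms) is the alternative mode.
Amplitude is peak − threshold; AHP is threshold minus the post-spike
minimum before the next spike; half-width is measured at
threshold + amplitude/2 with linear interpolation on both flanks. Spikes
truncated at sweep edges are excluded from features (with a warning) but
still counted. The F-I curve is the raw (current, spike count) table — no
smoothing or fitting; duplicate currents are kept per sweep and flagged.

## Synthetic-data generators

All draws come from one seeded `numpy.random.Generator` per call in a fixed
order, so outputs are byte-reproducible.

**Operant.** A semi-Markov event machine (press → optional entry → licks →
press) rather than free-running Poisson streams, so the conditional
structure the classifier assumes (licks follow entries) holds by
construction. Defaults: 30 sequences of 8 presses (a trained FR8 animal),
log-normal IPIs with medians 0.8 s (rapid), 3 s (check), 6 s (consumption)
and log-sigmas 0.5/0.5/0.4, 15 % check probability and 5 % lever-bounce
probability within sequences, 10 % disengagement gaps (22–60 s) between
sequences, consumption bouts of ≥ 12 licks. Reinforcers follow every 8th
press. Class draws are clipped away from the rule boundaries (rapid ≥
threshold + 2 grid steps, everything < break gap − 0.5 s) so that 10 ms
rounding can never flip a ledger class; clips sit in the far tails and do
not move class medians, which is what parameter recovery measures.
`median_multiplier` scales all class medians (slowing);
`dispersion_multiplier` scales rapid/check sigmas with medians untouched
(variability). Feasibility validation rejects configs whose class medians
approach the break gap.

**Ladder.** High rungs are odd indices on both sides of the generator's
profile — the real apparatus offsets parity between sides, but the misstep
metric only needs elevation, so the offset is cosmetic and dropping it
keeps pooled step lengths at the regular values. Each trial walks rung 1 to
37 in strides drawn from {+2, +4, leap +6, backward excursion}; a misstep
is a +1/+1 detour through a lowered rung, contributing exactly two
misstep-class steps while preserving the +2 net advance. The first and
last steps are always clean +2 (they are the omitted steps). For the
pure-small configuration every trial therefore has a fixed number of
misstep-eligible strides K = (n_rungs − 9)//2 + 1 (15 on the full ladder)
and P(trial has ≥ 2 misstep steps) = 1 − (1 − q)^K in closed form — the
binomial oracle for the session metric. Sub-30 ms artefact touches are
inserted (and ledger-marked) so the touch filter can be checked to remove
exactly them.

**Recordings.** Velocity is zero at rest and a rectified sum of slow
sinusoids under a raised-cosine envelope within each locomotion bout
(default two bouts of 40 s and 30 s in 120 s). Simple spikes are an
inhomogeneous gamma-interval process (shape κ = 4, a regular-ish
Purkinje-like train) with intensity max(baseline + gain·velocity, 0),
generated by time rescaling; complex spikes are Poisson at 1 Hz and each
deletes simple spikes within the 10 ms pause window. Defaults: baseline
60 spikes/s, gain 1.5 (spikes/s per velocity unit). What this does *not*
emulate: measurement noise in spike sorting, non-stationary baselines,
complex-spike-triggered rate modulation beyond the pause, and any
behavioural covariates other than wheel velocity — so passing recovery
tests demonstrate correctness of the analysis code, not robustness to
every property of real recordings.

**Excitability.** A deterministic leaky integrate-and-fire surrogate
(E_L = −65 mV, threshold −50 mV, reset −60 mV, R = 60 MΩ, τ = 10 ms,
2 ms refractory) with a stamped stereotyped spike waveform whose upstroke
kink sits exactly at threshold and whose AHP trough is 12 mV below it.
Rheobase is (V_th − E_L)/R = 250 pA and the steady ISI has the standard
closed form, giving exact oracles for the F-I curve and the waveform
detectors. The high-excitability preset raises R to 100 MΩ.

**Presets.** `control`, `slow_press` (all IPI medians × 1.5, elevated
misstep probability), `variable_press` (rapid/check dispersion × 1.5),
`high_excitability` (baseline 90 spikes/s, gain halved, higher input
resistance). Effect sizes are qualitative design choices — they encode the
*direction* of each phenotype, and are explicitly not calibrated to animal
data.

## Verification problem sizes and numerical choices

The exhaustive rule-engine checks enumerate ~25,000 tiny operant sessions
(2–3 presses, ≤ 2 events on a 0.05 s grid, with the lick-bout threshold
scaled to 2 so every branch is reachable at that event count) and all
597,870 touch sequences of length 2–6 on a 9-rung toy ladder, against
independent brute-force evaluators. Parameter recovery uses 50 sessions
per arm for the slowing ratio, 100 replicate pairs for the dispersion
direction (with the ±5 % median-stability check applied to medians pooled
across replicates, where the sampling error of a session-sized median does
not dominate), 200 72-trial sessions for the misstep metric (q = 0.04,
giving P(≥2) ≈ 0.458), and 200 uncoupled recordings against a
circular-shift permutation null (two-sample KS). Pearson correlations are
computed in double precision directly from centered sums and agree with a
textbook evaluation to 1e-12. These sizes were chosen so each check's
sampling error is several times smaller than the effect it verifies.

## Known limitations

- Side-stream step times approximate per-limb step times; paw identity is
  not observable from the rung sensors.
- The pooled step-length convention differs from a strictly per-limb
  reading of the step definitions; both are implemented, pooled is the
  default.
- The locomotion mask is threshold-based; treadmill-style intermittent
  walking with many sub-20 s bouts yields little analysable data by design.
- The curvature-based AP threshold depends on sampling rate; below ~10 kHz
  the dV/dt-criterion mode is the more stable choice.
- Generators produce idealised event streams; they validate the analysis
  rules, not the robustness of acquisition hardware.
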