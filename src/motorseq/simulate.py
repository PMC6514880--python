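"""Synthetic event-stream generators with ground-truth ledgers.

Every generator emulates one of the study's raw data kinds — operant session
event streams, ladder trials, paired spike/velocity recordings and
current-clamp sweeps — and returns, alongside the data, a ledger recording
the generating truth (per-interval classes, per-trial misstep counts, true
rates and gains) so that every analysis stage has a parameter-recovery test
surface.  Genotype-like presets encode the qualitative effect directions of
interest (slower pressing, more variable pressing, elevated misstep rate,
elevated baseline simple-spike rate with weaker velocity coupling); their
effect sizes are design choices, not calibrated to any animal data.

All draws come from a single seeded ``numpy.random.Generator`` per call, in a
fixed documented order, so outputs are reproducible and diff-stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    Direction,
    Elevation,
    LadderTrial,
    OperantSession,
    PairedRecording,
    Phase,
    RungTouch,
    Side,
    MotionState,
    CurrentClampSweep,
    ValidationError,
    VelocityTrace,
)
from .operant import IPIClass, SegmentationParams

__all__ = [
    "OperantGenConfig",
    "LadderGenConfig",
    "RecordingGenConfig",
    "ExcitabilityGenConfig",
    "OperantLedger",
    "LadderLedger",
    "RecordingLedger",
    "PresetBundle",
    "simulate_operant_session",
    "simulate_ladder_session",
    "simulate_recording",
    "simulate_current_clamp",
    "genotype_presets",
    "interior_misstep_slots",
    "expected_multi_misstep_prob",
]

_GRID = 0.01  # operant acquisition grid, seconds


# ---------------------------------------------------------------------------
# operant sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OperantGenConfig:
    """Semi-Markov lever-press session generator.

    Presses advance through sequences; within a sequence each inter-press
    interval is ultrafast (lever bounce), check (entry, few licks) or rapid
    (no events), with log-normal interval distributions per class.  Sequences
    are terminated by a consumption bout (entry plus a lick bout of >= 12
    licks) or, occasionally, a disengagement gap longer than the break
    threshold.  ``median_multiplier`` scales all class medians (slowing
    preset); ``dispersion_multiplier`` scales the rapid/check log-scale
    sigmas (variability preset) leaving medians unchanged.
    """

    n_sequences: int = 30
    sequence_lengths: tuple = (8,)
    sequence_length_probs: tuple = (1.0,)
    rapid_mu: float = math.log(0.8)
    rapid_sigma: float = 0.5
    check_mu: float = math.log(3.0)
    check_sigma: float = 0.5
    consumption_mu: float = math.log(6.0)
    consumption_sigma: float = 0.4
    p_check: float = 0.15
    ultrafast_bounce_prob: float = 0.05
    p_disengage: float = 0.10
    check_lick_mean: float = 3.0
    consumption_lick_min: int = 12
    consumption_lick_extra_mean: float = 5.0
    median_multiplier: float = 1.0
    dispersion_multiplier: float = 1.0
    ratio: int = 8
    params: SegmentationParams = field(default_factory=SegmentationParams)
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_check, self.ultrafast_bounce_prob, self.p_disengage):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")
        if min(self.median_multiplier, self.dispersion_multiplier) <= 0:
            raise ValidationError("multipliers must be positive")
        if self.consumption_lick_min < self.params.break_lick_count:
            raise ValidationError("consumption lick count must reach the bout threshold")
        if self.check_lick_mean >= self.params.break_lick_count:
            raise ValidationError("check lick mean must stay below the bout threshold")
        # feasibility: class medians must sit well below the break gap; tail
        # draws are clipped just under the gap, which leaves ledger classes
        # and medians intact only while the clip stays above the median
        for mu in (self.check_mu, self.consumption_mu):
            if math.exp(mu + math.log(self.median_multiplier)) >= 0.6 * self.params.break_gap:
                raise ValidationError(
                    "IPI distribution places its median too close to break_gap"
                )

    @property
    def true_medians(self) -> dict:
        m = self.median_multiplier
        return {
            "rapid": math.exp(self.rapid_mu) * m,
            "check": math.exp(self.check_mu) * m,
            "consumption": math.exp(self.consumption_mu) * m,
        }


@dataclass(frozen=True)
class OperantLedger:
    ipi_table: pd.DataFrame  # index, interval, true_class, boundary
    true_medians: dict
    true_sigmas: dict
    sequence_starts: np.ndarray  # press indices that begin each true sequence


def _lognormal(rng, mu, sigma, lo, hi):
    return float(np.clip(math.exp(rng.normal(mu, sigma)), lo, hi))


def simulate_operant_session(config: OperantGenConfig,
                             seed: Optional[int] = None) -> tuple[OperantSession, OperantLedger]:
    """Generate one self-paced FR session on the 10 ms grid with truth ledger."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    params = config.params
    log_m = math.log(config.median_multiplier)
    rapid_sigma = config.rapid_sigma * config.dispersion_multiplier
    check_sigma = config.check_sigma * config.dispersion_multiplier
    hi_clip = params.break_gap - 0.5
    uf_lo = int(round(0.05 / _GRID))
    uf_hi = int(round((params.ultrafast_threshold - 0.01) / _GRID))

    lengths = rng.choice(config.sequence_lengths, size=config.n_sequences,
                         p=config.sequence_length_probs)
    presses, entries, licks, reinforcers = [], [], [], []
    truth_rows = []
    sequence_starts = [0]
    t = 5.0
    press_count = 0

    def _emit_press(time):
        nonlocal press_count
        presses.append(time)
        press_count += 1
        if press_count % config.ratio == 0:
            reinforcers.append(time + 0.01)

    for s, length in enumerate(lengths):
        for i in range(int(length)):
            _emit_press(t)
            last_in_session = s == config.n_sequences - 1 and i == int(length) - 1
            if last_in_session:
                break
            if i < int(length) - 1:
                # within-sequence interval: ultrafast / check / rapid
                u = rng.random()
                if u < config.ultrafast_bounce_prob:
                    ipi = rng.integers(uf_lo, uf_hi + 1) * _GRID
                    klass = IPIClass.ULTRAFAST
                elif u < config.ultrafast_bounce_prob + config.p_check:
                    ipi = _lognormal(rng, config.check_mu + log_m, check_sigma, 0.8, hi_clip)
                    klass = IPIClass.CHECK
                    entries.append(t + 0.3 * ipi)
                    nl = int(min(rng.poisson(config.check_lick_mean),
                                 params.break_lick_count - 3))
                    if nl:
                        licks.extend(np.linspace(t + 0.3 * ipi + 0.03, t + ipi - 0.02, nl))
                else:
                    # lower clip leaves a 2-grid margin so 10 ms rounding can
                    # never push a rapid interval under the ultrafast threshold
                    ipi = _lognormal(rng, config.rapid_mu + log_m, rapid_sigma,
                                     params.ultrafast_threshold + 0.02, hi_clip)
                    klass = IPIClass.RAPID
                boundary = False
            else:
                # sequence boundary: consumption bout or disengagement gap
                if rng.random() < config.p_disengage:
                    ipi = float(rng.uniform(params.break_gap + 2.0, 60.0))
                    klass = IPIClass.GAP_BREAK
                else:
                    ipi = _lognormal(rng, config.consumption_mu + log_m,
                                     config.consumption_sigma, 3.0, hi_clip)
                    klass = IPIClass.CONSUMPTION
                    entries.append(t + 0.5)
                    nl = config.consumption_lick_min + int(
                        rng.poisson(config.consumption_lick_extra_mean))
                    licks.extend(np.linspace(t + 0.6, t + ipi - 0.02, nl))
                boundary = True
                sequence_starts.append(press_count)
            truth_rows.append({"index": press_count - 1, "interval": ipi,
                               "true_class": klass.value, "boundary": boundary})
            t += ipi

    def _grid(arr):
        return np.round(np.round(np.asarray(arr, dtype=float) / _GRID) * _GRID, 2)

    duration = float(math.ceil(t + 30.0))
    session = OperantSession(
        session_id=f"sim-{config.seed if seed is None else seed}",
        animal_id="sim",
        genotype_label="synthetic",
        phase=Phase.FR8_SELFPACED,
        session_duration=duration,
        press_times=_grid(presses),
        entry_times=_grid(sorted(entries)),
        lick_times=_grid(sorted(licks)),
        reinforcer_times=_grid(reinforcers),
    )
    ledger = OperantLedger(
        ipi_table=pd.DataFrame(truth_rows),
        true_medians=config.true_medians,
        true_sigmas={"rapid": rapid_sigma, "check": check_sigma,
                     "consumption": config.consumption_sigma},
        sequence_starts=np.asarray(sequence_starts[:config.n_sequences]),
    )
    return session, ledger


# ---------------------------------------------------------------------------
# ladder sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LadderGenConfig:
    """Ladder-crossing generator with a fixed stride structure.

    High rungs sit at odd indices (both sides) in the generator's rung
    profile.  Each trial starts and ends with a fixed +2 step (the omitted
    first/last steps), with interior strides drawn from
    {small +2, large +4, leap +6, backward excursion}.  With probability
    ``misstep_prob`` a stride is instead a detour through a lowered rung
    (+1 onto an even rung, +1 back off it) that yields exactly two
    misstep-class steps while preserving the +2 net advance — so for the
    pure-small configuration the number of misstep-eligible strides per
    trial is a fixed constant and P(n_missteps >= 2) has a closed form.
    """

    n_trials: int = 72
    n_rungs: int = 37
    p_small: float = 0.85
    p_large: float = 0.05
    p_leap: float = 0.05
    p_backward: float = 0.05
    misstep_prob: float = 0.05
    perturbed: bool = False
    perturbed_misstep_prob: float = 0.10
    artefact_fraction: float = 0.10
    session_index: int = 1
    seed: int = 0

    def __post_init__(self):
        weights = (self.p_small, self.p_large, self.p_leap, self.p_backward)
        if any(not 0.0 <= w <= 1.0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise ValidationError("stride-type weights must be in [0,1] and sum to 1")
        for p in (self.misstep_prob, self.perturbed_misstep_prob, self.artefact_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")
        if self.n_rungs < 11 or self.n_rungs % 2 == 0:
            raise ValidationError("n_rungs must be odd and at least 11")
        if self.perturbed and self.session_index < 5:
            object.__setattr__(self, "session_index", 5)

    @property
    def effective_misstep_prob(self) -> float:
        return self.perturbed_misstep_prob if self.perturbed else self.misstep_prob


def interior_misstep_slots(config: LadderGenConfig) -> int:
    """Misstep-eligible strides per trial for the pure-small configuration."""
    return (config.n_rungs - 6 - 3) // 2 + 1


def expected_multi_misstep_prob(config: LadderGenConfig) -> float:
    """Closed-form P(trial has >= 2 misstep steps) when p_small == 1.

    Each misstep event contributes exactly two misstep steps, so the trial
    qualifies iff at least one of the K independent eligible strides is a
    misstep: p = 1 - (1 - q)^K.
    """
    if config.p_small != 1.0:
        raise ValidationError("closed form requires a pure small-step configuration")
    q = config.effective_misstep_prob
    return 1.0 - (1.0 - q) ** interior_misstep_slots(config)


@dataclass(frozen=True)
class LadderLedger:
    per_trial: pd.DataFrame
    misstep_slots: int
    misstep_prob: float


def simulate_ladder_session(config: LadderGenConfig,
                            seed: Optional[int] = None) -> tuple[list[LadderTrial], LadderLedger]:
    rng = np.random.default_rng(config.seed if seed is None else seed)
    q = config.effective_misstep_prob
    stride_probs = np.array([config.p_small, config.p_large, config.p_leap,
                             config.p_backward])
    trials, rows = [], []
    for k in range(config.n_trials):
        direction = Direction.LEFT_TO_RIGHT if k % 2 == 0 else Direction.RIGHT_TO_LEFT
        # travel-space positions; actual rung = pos (L2R) or n_rungs+1-pos (R2L)
        positions = [1, 3]
        step_truth = ["small"]  # first step, excluded from analysis
        n_missteps = 0
        pos = 3
        while pos <= config.n_rungs - 6:
            if rng.random() < q:
                positions += [pos + 1, pos + 2]
                step_truth += ["misstep", "misstep"]
                n_missteps += 2
                pos += 2
            else:
                kind = rng.choice(4, p=stride_probs)
                if kind == 0:
                    positions.append(pos + 2)
                    step_truth.append("small")
                    pos += 2
                elif kind == 1:
                    positions.append(pos + 4)
                    step_truth.append("large")
                    pos += 4
                elif kind == 2:
                    positions.append(pos + 6)
                    step_truth.append("leap")
                    pos += 6
                else:
                    if pos < 7:
                        positions.append(pos + 2)
                        step_truth.append("small")
                        pos += 2
                    else:
                        positions += [pos - 2, pos - 4, pos - 2, pos]
                        step_truth += ["backward", "backward", "small", "small"]
        while pos < config.n_rungs - 2:
            positions.append(pos + 2)
            step_truth.append("small")
            pos += 2
        positions.append(config.n_rungs)
        step_truth.append("small")  # last step, excluded from analysis

        interior = step_truth[1:-1]
        sign = 1 if direction is Direction.LEFT_TO_RIGHT else -1
        touches = []
        n_artefacts = 0
        t = float(rng.uniform(0.5, 1.5))
        for j, p in enumerate(positions):
            rung = p if sign == 1 else config.n_rungs + 1 - p
            elevation = Elevation.HIGH if rung % 2 == 1 else Elevation.LOW
            side = Side.LEFT if j % 2 == 0 else Side.RIGHT
            duration = float(np.clip(math.exp(rng.normal(math.log(0.10), 0.3)),
                                     0.035, 0.6))
            touches.append(RungTouch(side=side, rung_index=rung, elevation=elevation,
                                     onset=round(t, 4), duration=round(duration, 4)))
            if rng.random() < config.artefact_fraction:
                touches.append(RungTouch(side=side, rung_index=rung,
                                         elevation=elevation, onset=round(t + 0.05, 4),
                                         duration=round(float(rng.uniform(0.005, 0.028)), 4)))
                n_artefacts += 1
            t += float(rng.uniform(0.15, 0.30))

        obstacle = None
        tone = None
        if config.perturbed:
            touched = {tt.rung_index for tt in touches}
            candidates = [r for r in range(10, config.n_rungs - 5) if r % 2 == 0
                          and r not in touched]
            obstacle = int(rng.choice(candidates)) if candidates else None
            tone = round(float(rng.uniform(1.0, t / 2)), 4)
        trials.append(LadderTrial(trial_index=k, direction=direction,
                                  session_index=config.session_index,
                                  perturbed=config.perturbed, obstacle_rung=obstacle,
                                  tone_time=tone, touches=tuple(touches)))
        rows.append({
            "trial_index": k,
            "n_missteps_true": n_missteps,
            "n_small_true": interior.count("small"),
            "n_large_true": interior.count("large"),
            "n_leap_true": interior.count("leap"),
            "n_backward_true": interior.count("backward"),
            "n_steps_true": len(interior),
            "n_artefacts": n_artefacts,
        })
    ledger = LadderLedger(per_trial=pd.DataFrame(rows),
                          misstep_slots=interior_misstep_slots(config),
                          misstep_prob=q)
    return trials, ledger


# ---------------------------------------------------------------------------
# paired spike/velocity recordings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecordingGenConfig:
    """Wheel-locomotion recording: gamma-renewal simple spikes driven by velocity.

    Velocity is zero at rest and a rectified sum of slow sinusoids under a
    raised-cosine envelope inside each locomotion bout.  The simple-spike
    intensity is ``max(baseline + gain * velocity, 0)`` and spikes are drawn
    as an inhomogeneous gamma-interval process (shape ``gamma_shape``) by
    time rescaling.  Complex spikes are Poisson at ~1 Hz and each deletes
    simple spikes within the climbing-fibre pause window after it.
    """

    duration: float = 120.0
    dt: float = 0.01
    locomotion_bouts: tuple = ((20.0, 60.0), (80.0, 110.0))
    velocity_base: float = 10.0
    velocity_mod_amp: float = 4.0
    velocity_mod_freqs: tuple = (0.10, 0.23)
    ramp: float = 2.0
    ss_baseline: float = 60.0
    coupling_gain: float = 1.5
    gamma_shape: float = 4.0
    cs_rate: float = 1.0
    pause_window: float = 0.010
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.ss_baseline < 0 or self.cs_rate < 0 or self.pause_window < 0:
            raise ValidationError("rates and pause must be non-negative")
        if self.gamma_shape <= 0 or self.dt <= 0 or self.duration <= 0:
            raise ValidationError("gamma shape, dt and duration must be positive")
        for a, b in self.locomotion_bouts:
            if not 0 <= a < b <= self.duration:
                raise ValidationError("locomotion bouts must lie within the recording")


@dataclass(frozen=True)
class RecordingLedger:
    baseline: float
    gain: float
    rate_true: np.ndarray
    state_mask_true: np.ndarray
    t_grid: np.ndarray


def _bout_envelope(t: np.ndarray, a: float, b: float, ramp: float) -> np.ndarray:
    env = np.zeros_like(t)
    inside = (t >= a) & (t <= b)
    x = t[inside]
    e = np.ones_like(x)
    up = x < a + ramp
    e[up] = 0.5 * (1 - np.cos(np.pi * (x[up] - a) / ramp))
    down = x > b - ramp
    e[down] = 0.5 * (1 - np.cos(np.pi * (b - x[down]) / ramp))
    env[inside] = e
    return env


def simulate_recording(config: RecordingGenConfig,
                       seed: Optional[int] = None) -> tuple[PairedRecording, RecordingLedger]:
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = int(round(config.duration / config.dt))
    t = config.dt * np.arange(n)
    velocity = np.zeros(n)
    mask = np.full(n, MotionState.REST, dtype=np.int8)
    for a, b in config.locomotion_bouts:
        env = _bout_envelope(t, a, b, config.ramp)
        mod = np.zeros(n)
        for w, f in zip((1.0, 0.6), config.velocity_mod_freqs):
            phase = rng.uniform(0, 2 * np.pi)
            mod += w * config.velocity_mod_amp * np.sin(2 * np.pi * f * (t - a) + phase)
        velocity += env * np.clip(config.velocity_base + mod, 0.0, None)
        mask[(t >= a) & (t <= b)] = MotionState.LOCOMOTION

    rate = config.ss_baseline + config.coupling_gain * velocity
    if config.noise_sd > 0:
        noise = rng.normal(0.0, 1.0, n)
        kernel = np.exp(-0.5 * (np.arange(-40, 41) / 10.0) ** 2)
        kernel /= kernel.sum()
        noise = np.convolve(np.pad(noise, 40, mode="reflect"), kernel, mode="valid")
        rate = rate + config.noise_sd * noise / noise.std()
    rate = np.clip(rate, 0.0, None)

    # simple spikes: time rescaling of a gamma renewal process (unit mean)
    cum = np.concatenate(([0.0], np.cumsum(rate) * config.dt))
    t_edges = np.concatenate((t, [config.duration]))
    total = cum[-1]
    n_draw = int(total + 4 * math.sqrt(total + 1) + 50)
    intervals = rng.gamma(config.gamma_shape, 1.0 / config.gamma_shape, size=n_draw)
    tau = np.cumsum(intervals)
    tau = tau[tau < total]
    ss = np.interp(tau, cum, t_edges)

    # complex spikes: homogeneous Poisson
    cs = []
    if config.cs_rate > 0:
        tt = rng.exponential(1.0 / config.cs_rate)
        while tt < config.duration:
            cs.append(tt)
            tt += rng.exponential(1.0 / config.cs_rate)
    cs = np.asarray(cs)

    # climbing-fibre pause: delete SS in (cs, cs + pause]
    if cs.size and config.pause_window > 0:
        keep = np.ones(ss.size, dtype=bool)
        lo = np.searchsorted(ss, cs, side="right")
        hi = np.searchsorted(ss, cs + config.pause_window, side="right")
        for a_i, b_i in zip(lo, hi):
            keep[a_i:b_i] = False
        ss = ss[keep]
    ss = ss[np.concatenate(([True], np.diff(ss) > 0))]

    rec = PairedRecording(
        cell_id=f"sim-cell-{config.seed if seed is None else seed}",
        ss_times=ss,
        cs_times=cs,
        velocity=VelocityTrace(values=velocity, dt=config.dt),
        state_mask=mask,
    )
    ledger = RecordingLedger(baseline=config.ss_baseline, gain=config.coupling_gain,
                             rate_true=rate, state_mask_true=mask, t_grid=t)
    return rec, ledger


# ---------------------------------------------------------------------------
# current-clamp sweeps (intrinsic excitability)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExcitabilityGenConfig:
    """Leaky integrate-and-fire surrogate for the 100-1000 pA step protocol.

    Rheobase is ``(v_thresh - e_leak) / r_m``; above it the closed-form
    steady-state firing interval is
    ``t_ref + tau * ln((v_inf - v_reset) / (v_inf - v_thresh))``.
    """

    currents: tuple = tuple(range(100, 1001, 100))
    stim_ms: float = 500.0
    pre_ms: float = 50.0
    post_ms: float = 50.0
    dt_ms: float = 0.05
    e_leak: float = -65.0
    v_thresh: float = -50.0
    v_reset: float = -60.0
    r_m: float = 0.06  # GOhm; GOhm * pA = mV
    tau_ms: float = 10.0
    refractory_ms: float = 2.0
    peak_mv: float = 25.0
    ahp_depth: float = 12.0  # trough below threshold, mV

    @property
    def rheobase_pa(self) -> float:
        return (self.v_thresh - self.e_leak) / self.r_m

    def predicted_rate(self, current_pa: float) -> float:
        """Closed-form steady firing rate in spikes/s (0 below rheobase).

        The dead time includes the 0.8 ms stamped waveform plus the
        refractory hold before integration resumes from ``v_reset``.
        """
        v_inf = self.e_leak + self.r_m * current_pa
        if v_inf <= self.v_thresh:
            return 0.0
        dead_ms = 0.8 + self.refractory_ms
        isi_ms = dead_ms + self.tau_ms * math.log(
            (v_inf - self.v_reset) / (v_inf - self.v_thresh))
        return 1000.0 / isi_ms


def simulate_current_clamp(config: ExcitabilityGenConfig = ExcitabilityGenConfig()
                           ) -> list[CurrentClampSweep]:
    """Deterministic LIF sweeps with stamped spike waveforms.

    Each threshold crossing stamps a stereotyped waveform: a 0.3 ms upstroke
    to ``peak_mv``, a 0.5 ms downstroke to the AHP trough
    (``v_thresh - ahp_depth``), then reset and a refractory hold.
    """
    dt = config.dt_ms
    n_pre = int(round(config.pre_ms / dt))
    n_stim = int(round(config.stim_ms / dt))
    n_post = int(round(config.post_ms / dt))
    n = n_pre + n_stim + n_post
    up = max(int(round(0.3 / dt)), 2)
    down = max(int(round(0.5 / dt)), 2)
    refr = int(round(config.refractory_ms / dt))
    trough = config.v_thresh - config.ahp_depth
    sweeps = []
    for current in config.currents:
        v = np.empty(n)
        v[0] = config.e_leak
        i = 0
        while i < n - 1:
            inj = current if n_pre <= i < n_pre + n_stim else 0.0
            v_inf = config.e_leak + config.r_m * inj
            v_next = v[i] + dt / config.tau_ms * (v_inf - v[i])
            if v_next >= config.v_thresh and inj > 0:
                j = i + 1
                rise = np.linspace(config.v_thresh, config.peak_mv, up)
                fall = np.linspace(config.peak_mv, trough, down + 1)[1:]
                stamp = np.concatenate((rise, fall))
                m = min(stamp.size, n - j)
                v[j:j + m] = stamp[:m]
                j += m
                hold = min(refr, n - j)
                if hold > 0:
                    v[j:j + hold] = np.linspace(trough, config.v_reset, hold)
                    j += hold
                if j >= n:
                    break
                v[j - 1] = config.v_reset if j > 0 else v[j - 1]
                i = j - 1
            else:
                v[i + 1] = v_next
                i += 1
        sweeps.append(CurrentClampSweep(injected_current=float(current), voltage=v,
                                        dt_ms=dt, sweep_id=f"I{int(current)}"))
    return sweeps


# ---------------------------------------------------------------------------
# genotype-like presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PresetBundle:
    name: str
    operant: OperantGenConfig
    ladder: LadderGenConfig
    recording: RecordingGenConfig
    excitability: ExcitabilityGenConfig


_PRESET_NAMES = ("control", "slow_press", "variable_press", "high_excitability")


def genotype_presets(name: str, seed: int = 0) -> PresetBundle:
    """Fully specified generator configs for one qualitative effect direction.

    ``slow_press`` raises all IPI medians (x1.5); ``variable_press`` raises
    rapid/check dispersion (x1.5) with medians unchanged;
    ``high_excitability`` raises the simple-spike baseline (60 -> 90
    spikes/s), halves the velocity coupling gain and raises input resistance
    so every current step fires more.  Effect sizes are qualitative design
    choices, not calibrated to animal data.
    """
    if name not in _PRESET_NAMES:
        raise ValidationError(f"unknown preset '{name}'; choose from {_PRESET_NAMES}")
    operant = OperantGenConfig(seed=seed)
    ladder = LadderGenConfig(seed=seed)
    recording = RecordingGenConfig(seed=seed)
    excitability = ExcitabilityGenConfig()
    if name == "slow_press":
        operant = replace(operant, median_multiplier=1.5)
        ladder = replace(ladder, misstep_prob=0.12)
    elif name == "variable_press":
        operant = replace(operant, dispersion_multiplier=1.5)
    elif name == "high_excitability":
        recording = replace(recording, ss_baseline=90.0, coupling_gain=0.75)
        excitability = replace(excitability, r_m=0.10)
    return PresetBundle(name=name, operant=operant, ladder=ladder,
                        recording=recording, excitability=excitability)
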