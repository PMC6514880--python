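"""Step reconstruction and classification for horizontal-ladder locomotion.

The apparatus reports rung touches (side, rung index, onset, duration) on a
ladder whose rungs alternate between high and low on each side.  Touches
shorter than 30 ms are sensor false positives and are dropped.  Steps are the
pooled consecutive touch pairs; step length is the signed rung distance along
the direction of travel.  Mice normally skip the lowered rungs, so forward
steps of length +2 (small regular) or +4 (large regular) between high rungs
dominate; everything else is irregular: missteps (a touch on a lowered rung),
leaps (length > 4), backward movements (only runs of two or more consecutive
negative steps count, so that a single hind-limb touch is not mistaken for
walking backwards) and other residual lengths.  The first and last step of a
trial (leaving and entering the shelter boxes) are excluded from analysis.

The skilled-locomotion readout is the percentage of trials in a session with
at least two missteps.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .core import Direction, Elevation, LadderTrial, RungTouch, ValidationError

__all__ = [
    "StepClass",
    "IrregularKind",
    "StepRecord",
    "TrialStepSummary",
    "LadderSessionSummary",
    "filter_touches",
    "reconstruct_steps",
    "classify_steps",
    "analyse_trial",
    "summarise_trial",
    "summarise_session",
]

#: Touches at or below this duration (seconds) are sensor artefacts.
MIN_TOUCH_DURATION = 0.030


class StepClass(str, enum.Enum):
    SMALL_REGULAR = "small_regular"
    LARGE_REGULAR = "large_regular"
    IRREGULAR = "irregular"


class IrregularKind(str, enum.Enum):
    MISSTEP = "misstep"
    LEAP = "leap"
    BACKWARD = "backward"
    OTHER = "other"


@dataclass(frozen=True)
class StepRecord:
    from_touch: RungTouch
    to_touch: RungTouch
    step_length: int  # signed rung units, positive = direction of travel
    step_time: Optional[float]  # onset-to-onset, same-side touches only
    excluded: bool = False  # first/last step of the trial
    klass: Optional[StepClass] = None
    irregular_kind: Optional[IrregularKind] = None


@dataclass(frozen=True)
class TrialStepSummary:
    n_steps: int
    n_missteps: int
    has_multiple_missteps: bool
    class_counts: dict
    mean_step_time: float


@dataclass(frozen=True)
class LadderSessionSummary:
    session_index: int
    perturbed: bool
    n_trials: int
    pct_trials_multiple_missteps: float
    total_missteps: int
    class_fractions: dict


def filter_touches(touches: Sequence[RungTouch],
                   min_duration: float = MIN_TOUCH_DURATION) -> list[RungTouch]:
    """Keep touches lasting strictly more than ``min_duration`` (default 30 ms)."""
    return [t for t in touches if t.duration > min_duration]


def reconstruct_steps(trial: LadderTrial, prefiltered: bool = False) -> list[StepRecord]:
    """Build step records from a trial's (filtered) touches.

    Step length pools consecutive touches across sides; step time is defined
    only between consecutive touches of the same side (the sensors report
    side, not paw, so each side is treated as one front-limb stream).  With
    fewer than three touches every step is a first/last step and the
    analysable list is empty.
    """
    touches = list(trial.touches) if prefiltered else filter_touches(trial.touches)
    sign = 1 if trial.direction is Direction.LEFT_TO_RIGHT else -1
    steps = []
    for i in range(len(touches) - 1):
        a, b = touches[i], touches[i + 1]
        step_time = b.onset - a.onset if a.side is b.side else None
        steps.append(
            StepRecord(
                from_touch=a,
                to_touch=b,
                step_length=sign * (b.rung_index - a.rung_index),
                step_time=step_time,
                excluded=(i == 0 or i == len(touches) - 2),
            )
        )
    return steps


def classify_steps(steps: Sequence[StepRecord]) -> list[StepRecord]:
    """Assign the regular/irregular taxonomy to reconstructed steps.

    Backward labelling needs run context, so it is computed over the whole
    step list (including the excluded first/last steps) before any omission.
    Within irregular steps, misstep (low-rung contact) takes precedence over
    backward and leap.
    """
    negative = [s.step_length < 0 for s in steps]
    in_backward_run = [False] * len(steps)
    i = 0
    while i < len(steps):
        if negative[i]:
            j = i
            while j < len(steps) and negative[j]:
                j += 1
            if j - i >= 2:
                for k in range(i, j):
                    in_backward_run[k] = True
            i = j
        else:
            i += 1

    out = []
    for s, backward in zip(steps, in_backward_run):
        low = (s.from_touch.elevation is Elevation.LOW) or (s.to_touch.elevation is Elevation.LOW)
        both_high = not low
        if s.step_length == 2 and both_high:
            klass, kind = StepClass.SMALL_REGULAR, None
        elif s.step_length == 4 and both_high:
            klass, kind = StepClass.LARGE_REGULAR, None
        else:
            klass = StepClass.IRREGULAR
            if low:
                kind = IrregularKind.MISSTEP
            elif backward:
                kind = IrregularKind.BACKWARD
            elif s.step_length > 4:
                kind = IrregularKind.LEAP
            else:
                kind = IrregularKind.OTHER
        out.append(replace(s, klass=klass, irregular_kind=kind))
    return out


def analyse_trial(trial: LadderTrial,
                  min_duration: float = MIN_TOUCH_DURATION) -> list[StepRecord]:
    """Filter, reconstruct and classify one trial in a single call."""
    touches = filter_touches(trial.touches, min_duration)
    filtered = replace(trial, touches=tuple(touches))
    return classify_steps(reconstruct_steps(filtered, prefiltered=True))


def summarise_trial(steps: Sequence[StepRecord]) -> TrialStepSummary:
    """Summarise the analysable (non-excluded) classified steps of a trial."""
    kept = [s for s in steps if not s.excluded]
    if any(s.klass is None for s in kept):
        raise ValidationError("steps must be classified before summarising")
    counts = {k.value: 0 for k in StepClass}
    for s in kept:
        counts[s.klass.value] += 1
    n_missteps = sum(1 for s in kept if s.irregular_kind is IrregularKind.MISSTEP)
    times = [s.step_time for s in kept if s.step_time is not None]
    return TrialStepSummary(
        n_steps=len(kept),
        n_missteps=n_missteps,
        has_multiple_missteps=n_missteps >= 2,
        class_counts=counts,
        mean_step_time=float(np.mean(times)) if times else float("nan"),
    )


def summarise_session(trial_summaries: Sequence[TrialStepSummary],
                      session_index: int = 1,
                      perturbed: bool = False) -> LadderSessionSummary:
    """Session metric: % of trials with two or more missteps, plus totals."""
    if not trial_summaries:
        raise ValidationError("cannot summarise a session with zero trials")
    n_trials = len(trial_summaries)
    n_multi = sum(1 for t in trial_summaries if t.has_multiple_missteps)
    total_steps = sum(t.n_steps for t in trial_summaries)
    fractions = {}
    for klass in StepClass:
        count = sum(t.class_counts[klass.value] for t in trial_summaries)
        fractions[klass.value] = count / total_steps if total_steps else float("nan")
    return LadderSessionSummary(
        session_index=session_index,
        perturbed=perturbed,
        n_trials=n_trials,
        pct_trials_multiple_missteps=100.0 * n_multi / n_trials,
        total_missteps=sum(t.n_missteps for t in trial_summaries),
        class_fractions=fractions,
    )
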