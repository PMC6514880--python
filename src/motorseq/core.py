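"""Domain containers and validation shared by all analysis modules.

Times are seconds as floats throughout.  The 10 ms acquisition grid of the
operant box is enforced only at the operant I/O boundary (see :mod:`motorseq.io`),
never internally, so that sub-millisecond electrophysiology and behavioural
event streams share one data model.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ValidationError",
    "UndefinedStatisticError",
    "TIME_GRID",
    "Phase",
    "Side",
    "Elevation",
    "Direction",
    "MotionState",
    "OperantSession",
    "RungTouch",
    "LadderTrial",
    "VelocityTrace",
    "PairedRecording",
    "CurrentClampSweep",
]

#: Acquisition resolution of the operant box, seconds.
TIME_GRID = 0.01


class ValidationError(ValueError):
    """A container's invariants are violated or an input file is malformed."""


class UndefinedStatisticError(ValueError):
    """A statistic is requested on an input for which it is undefined."""


class Phase(str, enum.Enum):
    CRF = "CRF"
    FR8_SELFPACED = "FR8_selfpaced"
    FR8_HIGHSPEED = "FR8_highspeed"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class Elevation(str, enum.Enum):
    HIGH = "high"
    LOW = "low"


class Direction(str, enum.Enum):
    LEFT_TO_RIGHT = "left_to_right"
    RIGHT_TO_LEFT = "right_to_left"


class MotionState(enum.IntEnum):
    """Per-sample behavioural state of a wheel recording."""

    REST = 0
    LOCOMOTION = 1
    EXCLUDED = 2


def _event_array(values, name: str, *, strict: bool = False) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be a 1-D sequence of times")
    if arr.size:
        d = np.diff(arr)
        if strict and np.any(d <= 0):
            raise ValidationError(f"{name} must be strictly increasing")
        if not strict and np.any(d < 0):
            raise ValidationError(f"{name} must be non-decreasing")
    arr.setflags(write=False)
    return arr


@dataclass(frozen=True)
class OperantSession:
    """One operant-chamber training session as four timestamp streams.

    Lever presses, magazine head entries (IR beam), licks (contact lickometer)
    and reinforcer deliveries are point events in seconds from session start.
    """

    session_id: str
    animal_id: str
    genotype_label: str
    phase: Phase
    session_duration: float
    press_times: np.ndarray = field(default_factory=lambda: np.array([]))
    entry_times: np.ndarray = field(default_factory=lambda: np.array([]))
    lick_times: np.ndarray = field(default_factory=lambda: np.array([]))
    reinforcer_times: np.ndarray = field(default_factory=lambda: np.array([]))
    speed_limit_s: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "phase", Phase(self.phase))
        if not self.session_duration > 0:
            raise ValidationError("session_duration must be positive")
        for name in ("press_times", "entry_times", "lick_times", "reinforcer_times"):
            arr = _event_array(getattr(self, name), name)
            if arr.size and (arr[0] < 0 or arr[-1] > self.session_duration):
                raise ValidationError(
                    f"{name} contains timestamps outside [0, {self.session_duration}]"
                )
            object.__setattr__(self, name, arr)
        if self.phase is Phase.FR8_HIGHSPEED:
            if self.speed_limit_s is None or not self.speed_limit_s > 0:
                raise ValidationError("high-speed sessions require a positive speed_limit_s")
        elif self.speed_limit_s is not None:
            raise ValidationError("speed_limit_s is only meaningful for high-speed sessions")

    @property
    def n_presses(self) -> int:
        return int(self.press_times.size)

    @property
    def n_reinforcers(self) -> int:
        return int(self.reinforcer_times.size)


@dataclass(frozen=True)
class RungTouch:
    """A single filtered rung contact on the horizontal ladder."""

    side: Side
    rung_index: int
    elevation: Elevation
    onset: float
    duration: float

    def __post_init__(self):
        object.__setattr__(self, "side", Side(self.side))
        object.__setattr__(self, "elevation", Elevation(self.elevation))
        if not self.duration > 0:
            raise ValidationError("touch duration must be positive")
        if self.rung_index < 1:
            raise ValidationError("rung indices are 1-based")


@dataclass(frozen=True)
class LadderTrial:
    """One back-or-forth crossing of the ladder with its ordered rung touches."""

    trial_index: int
    direction: Direction
    session_index: int
    touches: tuple[RungTouch, ...] = ()
    perturbed: bool = False
    obstacle_rung: Optional[int] = None
    tone_time: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "direction", Direction(self.direction))
        object.__setattr__(self, "touches", tuple(self.touches))
        if not 1 <= self.session_index <= 8:
            raise ValidationError("session_index must be in 1..8")
        if self.perturbed and self.session_index < 5:
            raise ValidationError(
                "perturbed trials occur in sessions 5-8 of the training design"
            )
        # touches ordered by onset, ties broken by rung index
        key = [(t.onset, t.rung_index) for t in self.touches]
        if key != sorted(key):
            raise ValidationError("touches must be ordered by onset (ties by rung index)")


@dataclass(frozen=True)
class VelocityTrace:
    """Uniformly sampled wheel velocity."""

    values: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self):
        if not self.dt > 0:
            raise ValidationError("velocity sample interval must be positive")
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValidationError("velocity values must be 1-D")
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def span(self) -> float:
        return self.dt * self.n


@dataclass(frozen=True)
class PairedRecording:
    """Simple/complex Purkinje-cell spike trains paired with wheel velocity."""

    cell_id: str
    ss_times: np.ndarray
    cs_times: np.ndarray
    velocity: VelocityTrace
    state_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        object.__setattr__(self, "ss_times", _event_array(self.ss_times, "ss_times", strict=True))
        object.__setattr__(self, "cs_times", _event_array(self.cs_times, "cs_times", strict=True))
        if self.state_mask is not None:
            mask = np.asarray(self.state_mask)
            if mask.shape != (self.velocity.n,):
                raise ValidationError(
                    "state_mask must carry one label per velocity sample "
                    f"({mask.size} vs {self.velocity.n})"
                )
            mask = mask.astype(np.int8)
            mask.setflags(write=False)
            object.__setattr__(self, "state_mask", mask)


@dataclass(frozen=True)
class CurrentClampSweep:
    """A whole-cell current-clamp sweep: voltage (mV) under a square current step."""

    injected_current: float  # pA
    voltage: np.ndarray  # mV
    dt_ms: float
    sweep_id: str = ""

    def __post_init__(self):
        if not self.dt_ms > 0:
            raise ValidationError("sample interval must be positive")
        arr = np.asarray(self.voltage, dtype=float)
        if arr.ndim != 1 or arr.size < 3:
            raise ValidationError("voltage trace must be 1-D with at least 3 samples")
        arr.setflags(write=False)
        object.__setattr__(self, "voltage", arr)

    @property
    def times_ms(self) -> np.ndarray:
        return self.dt_ms * np.arange(self.voltage.size)
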