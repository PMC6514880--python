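"""CSV reading and writing for event-stream inputs.

All tables are long-format, comma-separated with a header.  Session-level
metadata travels in ``# key: value`` comment lines before the header so that a
single file round-trips a full session.  Operant timestamps are snapped to the
10 ms acquisition grid at this boundary (with a warning when rounding was
needed); other modalities keep full float precision.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import (
    TIME_GRID,
    CurrentClampSweep,
    LadderTrial,
    OperantSession,
    PairedRecording,
    RungTouch,
    ValidationError,
    VelocityTrace,
)

__all__ = [
    "read_operant_session",
    "write_operant_session",
    "read_ladder_session",
    "write_ladder_session",
    "read_recording",
    "write_recording",
    "read_sweeps",
    "write_sweeps",
]

_OPERANT_EVENTS = ("press", "entry", "lick", "reinforcer")


def _read_metadata(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, value = line[1:].split(":", 1)
                meta[key.strip()] = value.strip()
    return meta


def _snap_to_grid(times: np.ndarray, label: str) -> np.ndarray:
    snapped = np.round(times / TIME_GRID) * TIME_GRID
    if not np.allclose(snapped, times, atol=1e-9):
        warnings.warn(
            f"{label}: timestamps at sub-10 ms precision rounded to the 10 ms grid",
            stacklevel=3,
        )
    return np.round(snapped, 9)


def read_operant_session(path, dialect: str = "csv") -> OperantSession:
    """Read a long-format operant event table into a validated session.

    Out-of-range rows are rejected with an error naming the offending rows.
    """
    meta = _read_metadata(path)
    sep = "\t" if dialect == "tsv" else ","
    table = pd.read_csv(path, comment="#", sep=sep)
    for col in ("event_type", "timestamp"):
        if col not in table.columns:
            raise ValidationError(f"missing required column '{col}' in {path}")
    try:
        duration = float(meta["session_duration"])
    except KeyError:
        raise ValidationError(f"missing '# session_duration:' metadata in {path}") from None
    unknown = set(table["event_type"]) - set(_OPERANT_EVENTS)
    if unknown:
        raise ValidationError(f"unknown event types {sorted(unknown)} in {path}")
    bad = table.index[(table["timestamp"] < 0) | (table["timestamp"] > duration)]
    if len(bad):
        raise ValidationError(
            f"rows {list(bad)} of {path} have timestamps outside [0, {duration}]"
        )
    streams = {}
    for ev in _OPERANT_EVENTS:
        t = table.loc[table["event_type"] == ev, "timestamp"].to_numpy(dtype=float)
        streams[ev] = _snap_to_grid(np.sort(t), f"{path} ({ev})")
    speed = meta.get("speed_limit_s", "")
    return OperantSession(
        session_id=meta.get("session_id", ""),
        animal_id=meta.get("animal_id", ""),
        genotype_label=meta.get("genotype_label", ""),
        phase=meta.get("phase", "FR8_selfpaced"),
        session_duration=duration,
        press_times=streams["press"],
        entry_times=streams["entry"],
        lick_times=streams["lick"],
        reinforcer_times=streams["reinforcer"],
        speed_limit_s=float(speed) if speed else None,
    )


def write_operant_session(session: OperantSession, path) -> None:
    rows = []
    for ev, stream in (
        ("press", session.press_times),
        ("entry", session.entry_times),
        ("lick", session.lick_times),
        ("reinforcer", session.reinforcer_times),
    ):
        snapped = _snap_to_grid(stream, f"{path} ({ev})")
        rows.extend((ev, t) for t in snapped)
    rows.sort(key=lambda r: (r[1], _OPERANT_EVENTS.index(r[0])))
    with open(path, "w") as fh:
        fh.write(f"# session_id: {session.session_id}\n")
        fh.write(f"# animal_id: {session.animal_id}\n")
        fh.write(f"# genotype_label: {session.genotype_label}\n")
        fh.write(f"# phase: {session.phase.value}\n")
        fh.write(f"# session_duration: {session.session_duration:.2f}\n")
        if session.speed_limit_s is not None:
            fh.write(f"# speed_limit_s: {session.speed_limit_s:.2f}\n")
        fh.write("event_type,timestamp\n")
        for ev, t in rows:
            fh.write(f"{ev},{t:.2f}\n")


_LADDER_COLUMNS = [
    "trial_index",
    "session_index",
    "direction",
    "perturbed",
    "obstacle_rung",
    "tone_time",
    "side",
    "rung_index",
    "elevation",
    "onset",
    "duration",
]


def read_ladder_session(path) -> list[LadderTrial]:
    """Read a per-touch ladder table (one row per rung touch) into trials."""
    table = pd.read_csv(path, comment="#")
    missing = [c for c in _LADDER_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"missing required columns {missing} in {path}")
    trials = []
    for trial_index, group in table.groupby("trial_index", sort=True):
        head = group.iloc[0]
        touches = tuple(
            RungTouch(
                side=row.side,
                rung_index=int(row.rung_index),
                elevation=row.elevation,
                onset=float(row.onset),
                duration=float(row.duration),
            )
            for row in group.itertuples()
        )
        obstacle = head["obstacle_rung"]
        tone = head["tone_time"]
        trials.append(
            LadderTrial(
                trial_index=int(trial_index),
                direction=head["direction"],
                session_index=int(head["session_index"]),
                perturbed=bool(head["perturbed"]),
                obstacle_rung=None if pd.isna(obstacle) else int(obstacle),
                tone_time=None if pd.isna(tone) else float(tone),
                touches=touches,
            )
        )
    return trials


def write_ladder_session(trials: list[LadderTrial], path) -> None:
    rows = []
    for trial in trials:
        for touch in trial.touches:
            rows.append(
                {
                    "trial_index": trial.trial_index,
                    "session_index": trial.session_index,
                    "direction": trial.direction.value,
                    "perturbed": trial.perturbed,
                    "obstacle_rung": trial.obstacle_rung,
                    "tone_time": trial.tone_time,
                    "side": touch.side.value,
                    "rung_index": touch.rung_index,
                    "elevation": touch.elevation.value,
                    "onset": touch.onset,
                    "duration": touch.duration,
                }
            )
    pd.DataFrame(rows, columns=_LADDER_COLUMNS).to_csv(path, index=False, float_format="%.6f")


def read_recording(spikes_path, velocity_path, cell_id: str = "") -> PairedRecording:
    """Assemble a paired recording from a spike table and a velocity table.

    Spike table columns: ``spike_type`` in {SS, CS} and ``time_s``.  Velocity
    table columns: ``time_s``, ``velocity`` and optionally ``state`` (integer
    :class:`~motorseq.core.MotionState` labels).
    """
    spikes = pd.read_csv(spikes_path, comment="#")
    for col in ("spike_type", "time_s"):
        if col not in spikes.columns:
            raise ValidationError(f"missing required column '{col}' in {spikes_path}")
    vel = pd.read_csv(velocity_path, comment="#")
    for col in ("time_s", "velocity"):
        if col not in vel.columns:
            raise ValidationError(f"missing required column '{col}' in {velocity_path}")
    t = vel["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValidationError("velocity trace needs at least two samples")
    dts = np.diff(t)
    dt = float(np.median(dts))
    if dt <= 0 or not np.allclose(dts, dt, rtol=1e-6, atol=1e-9):
        raise ValidationError("velocity trace must be uniformly sampled with dt > 0")
    trace = VelocityTrace(values=vel["velocity"].to_numpy(dtype=float), dt=dt, t0=float(t[0]))
    mask = None
    if "state" in vel.columns:
        mask = vel["state"].to_numpy(dtype=np.int8)
    ss = np.sort(spikes.loc[spikes["spike_type"] == "SS", "time_s"].to_numpy(dtype=float))
    cs = np.sort(spikes.loc[spikes["spike_type"] == "CS", "time_s"].to_numpy(dtype=float))
    return PairedRecording(cell_id=cell_id, ss_times=ss, cs_times=cs, velocity=trace, state_mask=mask)


def write_recording(rec: PairedRecording, spikes_path, velocity_path) -> None:
    spikes = pd.DataFrame(
        {
            "spike_type": ["SS"] * rec.ss_times.size + ["CS"] * rec.cs_times.size,
            "time_s": np.concatenate([rec.ss_times, rec.cs_times]),
        }
    ).sort_values("time_s", kind="stable")
    spikes.to_csv(spikes_path, index=False, float_format="%.6f")
    vel = pd.DataFrame({"time_s": rec.velocity.times, "velocity": rec.velocity.values})
    if rec.state_mask is not None:
        vel["state"] = rec.state_mask
    vel.to_csv(velocity_path, index=False, float_format="%.6f")


def read_sweeps(path) -> list[CurrentClampSweep]:
    """Read current-clamp sweeps (columns sweep_id, current_pA, time_ms, voltage_mV)."""
    table = pd.read_csv(path, comment="#")
    for col in ("sweep_id", "current_pA", "time_ms", "voltage_mV"):
        if col not in table.columns:
            raise ValidationError(f"missing required column '{col}' in {path}")
    sweeps = []
    for sweep_id, group in table.groupby("sweep_id", sort=True):
        t = group["time_ms"].to_numpy(dtype=float)
        if t.size < 3:
            raise ValidationError(f"sweep {sweep_id} has fewer than 3 samples")
        dt = float(np.median(np.diff(t)))
        sweeps.append(
            CurrentClampSweep(
                injected_current=float(group["current_pA"].iloc[0]),
                voltage=group["voltage_mV"].to_numpy(dtype=float),
                dt_ms=dt,
                sweep_id=str(sweep_id),
            )
        )
    return sweeps


def write_sweeps(sweeps: list[CurrentClampSweep], path) -> None:
    frames = []
    for sweep in sweeps:
        frames.append(
            pd.DataFrame(
                {
                    "sweep_id": sweep.sweep_id,
                    "current_pA": sweep.injected_current,
                    "time_ms": sweep.times_ms,
                    "voltage_mV": sweep.voltage,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")
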