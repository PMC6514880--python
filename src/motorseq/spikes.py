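"""Purkinje-cell spike-train analysis and intrinsic-excitability features.

In vivo: Purkinje cells are identified by the pause in simple-spike (SS)
firing that follows each complex spike (CS).  During head-fixed locomotion on
a wheel, the SS instantaneous firing rate (reciprocal inter-spike interval,
smoothed with a 200 ms Gaussian kernel) is correlated with wheel velocity in
sliding 2000 ms epochs advanced in 200 ms increments; velocity is z-scored
within each epoch and the per-cell statistic is the maximum absolute Pearson
coefficient over epochs.  Only locomotion periods of at least 20 s enter the
analysis.

In vitro: action-potential threshold is taken at the onset of the upstroke
(maximum curvature of the membrane potential before the peak; a dV/dt
criterion detector is available as an alternative), AHP amplitude is the
post-spike minimum relative to that threshold, and the spike count across
100-1000 pA current steps gives the F-I excitability curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import (
    CurrentClampSweep,
    MotionState,
    PairedRecording,
    UndefinedStatisticError,
    ValidationError,
    VelocityTrace,
)

__all__ = [
    "PCValidation",
    "RateTrace",
    "EpochCorrelation",
    "ModulationResult",
    "WaveformFeatures",
    "SweepFeatures",
    "CannotIdentifyError",
    "validate_purkinje",
    "segment_locomotion",
    "instantaneous_rate",
    "gaussian_smooth",
    "epoch_correlations",
    "firing_rates",
    "analyse_recording",
    "ap_features",
    "fi_curve",
]

#: 200 ms Gaussian window interpreted as full width at half maximum.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class CannotIdentifyError(ValueError):
    """Raised when a recording has no complex spikes to validate against."""


@dataclass(frozen=True)
class PCValidation:
    n_cs: int
    pause_window: float
    fraction_paused: float
    is_single_unit: bool


@dataclass(frozen=True)
class RateTrace:
    """Firing rate (spikes/s) on a uniform time grid."""

    values: np.ndarray
    dt: float
    t0: float = 0.0
    smoothing_window: Optional[float] = None

    def __post_init__(self):
        if not self.dt > 0:
            raise ValidationError("rate sample interval must be positive")
        arr = np.asarray(self.values, dtype=float)
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)


@dataclass(frozen=True)
class EpochCorrelation:
    epoch_start: float
    r: float  # NaN when either signal has zero variance in the epoch
    n_samples: int


@dataclass(frozen=True)
class ModulationResult:
    epoch_correlations: list
    max_abs_r: float
    ss_rate_rest: float = float("nan")
    ss_rate_locomotion: float = float("nan")
    cs_rate_rest: float = float("nan")
    cs_rate_locomotion: float = float("nan")


@dataclass(frozen=True)
class WaveformFeatures:
    """Per-spike action-potential features (mV / ms)."""

    ap_threshold: float
    ap_amplitude: float
    ahp_amplitude: float  # threshold minus post-spike minimum
    half_width: float
    peak_time_ms: float


@dataclass(frozen=True)
class SweepFeatures:
    spike_count: int
    features: list  # WaveformFeatures for non-truncated spikes


def validate_purkinje(rec: PairedRecording, pause_window: float = 0.010,
                      min_fraction: float = 0.95) -> PCValidation:
    """Fraction of complex spikes followed by an SS-free pause of >= pause_window.

    Tests, for each CS at time c, that no simple spike falls in
    (c, c + pause_window].
    """
    if rec.cs_times.size == 0:
        raise CannotIdentifyError("recording has no complex spikes")
    lo = np.searchsorted(rec.ss_times, rec.cs_times, side="right")
    hi = np.searchsorted(rec.ss_times, rec.cs_times + pause_window, side="right")
    paused = hi == lo
    fraction = float(np.mean(paused))
    return PCValidation(
        n_cs=int(rec.cs_times.size),
        pause_window=pause_window,
        fraction_paused=fraction,
        is_single_unit=fraction >= min_fraction,
    )


def segment_locomotion(velocity: VelocityTrace, speed_threshold: Optional[float] = None,
                       min_duration: float = 20.0, bridge_gap: float = 1.0) -> np.ndarray:
    """Label each velocity sample as rest, locomotion or excluded.

    Samples with |v| above ``speed_threshold`` (default 5% of the recording
    maximum) form candidate movement spans; sub-threshold gaps up to
    ``bridge_gap`` seconds inside movement are bridged.  Spans shorter than
    ``min_duration`` are labelled EXCLUDED rather than locomotion.
    """
    v = np.abs(velocity.values)
    if speed_threshold is None:
        vmax = v.max(initial=0.0)
        speed_threshold = 0.05 * vmax
    moving = v > speed_threshold
    if not moving.any():
        return np.full(velocity.n, MotionState.REST, dtype=np.int8)

    # bridge short sub-threshold gaps between movement samples
    idx = np.flatnonzero(moving)
    gaps = np.diff(idx)
    max_gap = int(round(bridge_gap / velocity.dt))
    bridged = moving.copy()
    for k in np.flatnonzero((gaps > 1) & (gaps <= max_gap + 1)):
        bridged[idx[k]:idx[k + 1]] = True

    mask = np.full(velocity.n, MotionState.REST, dtype=np.int8)
    min_len = int(round(min_duration / velocity.dt))
    edges = np.flatnonzero(np.diff(np.concatenate(([0], bridged.view(np.int8), [0]))))
    for a, b in zip(edges[::2], edges[1::2]):
        mask[a:b] = MotionState.LOCOMOTION if (b - a) >= min_len else MotionState.EXCLUDED
    return mask


def instantaneous_rate(ss_times: np.ndarray, grid_dt: float,
                       t0: float = 0.0, t_end: Optional[float] = None) -> RateTrace:
    """Instantaneous firing frequency: 1/ISI of the interval containing each sample.

    Before the first and after the last spike the nearest interval's rate is
    extended.  Requires at least two spikes.
    """
    ss = np.asarray(ss_times, dtype=float)
    if ss.size < 2:
        raise UndefinedStatisticError("instantaneous rate needs at least two spikes")
    if t_end is None:
        t_end = float(ss[-1])
    n = int(np.floor((t_end - t0) / grid_dt)) + 1
    grid = t0 + grid_dt * np.arange(n)
    idx = np.clip(np.searchsorted(ss, grid, side="right") - 1, 0, ss.size - 2)
    isi = np.diff(ss)
    return RateTrace(values=1.0 / isi[idx], dt=grid_dt, t0=t0)


def gaussian_smooth(trace: RateTrace, window: float = 0.200,
                    interpretation: str = "fwhm") -> RateTrace:
    """Convolve with a unit-area Gaussian kernel (reflect padding at edges).

    ``window`` is interpreted as the kernel's full width at half maximum by
    default ("Gaussian window of 200 ms" -> sigma ~ 85 ms); pass
    ``interpretation='sigma'`` to treat it as sigma directly.
    """
    if window < 2 * trace.dt:
        raise ValidationError("smoothing window must cover at least two samples")
    if interpretation == "fwhm":
        sigma = window * FWHM_TO_SIGMA
    elif interpretation == "sigma":
        sigma = window
    else:
        raise ValidationError("interpretation must be 'fwhm' or 'sigma'")
    sigma_samples = sigma / trace.dt
    radius = int(np.ceil(4 * sigma_samples))
    k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma_samples) ** 2)
    k /= k.sum()
    padded = np.pad(trace.values, radius, mode="reflect")
    smoothed = np.convolve(padded, k, mode="valid")
    return RateTrace(values=smoothed, dt=trace.dt, t0=trace.t0, smoothing_window=window)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.dot(xc, xc))
    sy = np.sqrt(np.dot(yc, yc))
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.dot(xc, yc) / (sx * sy))


def _resample(values: np.ndarray, dt: float, t0: float, grid: np.ndarray) -> np.ndarray:
    return np.interp(grid, t0 + dt * np.arange(values.size), values)


def epoch_correlations(rate: RateTrace, velocity: VelocityTrace,
                       state_mask: Optional[np.ndarray] = None,
                       epoch: float = 2.000, step: float = 0.200,
                       grid_dt: float = 0.010) -> ModulationResult:
    """Sliding-epoch Pearson correlation between firing rate and wheel velocity.

    Both signals are resampled to a common grid (linear interpolation,
    default 10 ms).  Within every epoch fully inside a locomotion span the
    velocity is z-scored and correlated with the rate; epochs where either
    signal has zero variance are undefined and excluded from the maximum.
    """
    n = int(np.floor(velocity.span / grid_dt))
    grid = velocity.t0 + grid_dt * np.arange(n)
    r_common = _resample(rate.values, rate.dt, rate.t0, grid)
    v_common = _resample(velocity.values, velocity.dt, velocity.t0, grid)
    if state_mask is None:
        mask_common = np.full(n, MotionState.LOCOMOTION, dtype=np.int8)
    else:
        src_idx = np.clip(((grid - velocity.t0) / velocity.dt).round().astype(int),
                          0, velocity.n - 1)
        mask_common = np.asarray(state_mask, dtype=np.int8)[src_idx]

    epoch_len = int(round(epoch / grid_dt))
    step_len = int(round(step / grid_dt))
    moving = mask_common == MotionState.LOCOMOTION
    edges = np.flatnonzero(np.diff(np.concatenate(([0], moving.view(np.int8), [0]))))
    epochs = []
    for a, b in zip(edges[::2], edges[1::2]):
        if b - a < epoch_len:
            continue
        for s in range(a, b - epoch_len + 1, step_len):
            v_e = v_common[s:s + epoch_len]
            sd = v_e.std()
            if sd == 0.0:
                r = float("nan")
            else:
                v_z = (v_e - v_e.mean()) / sd
                r = _pearson(v_z, r_common[s:s + epoch_len])
            epochs.append(EpochCorrelation(epoch_start=float(grid[s]), r=r,
                                           n_samples=epoch_len))
    defined = [abs(e.r) for e in epochs if np.isfinite(e.r)]
    max_abs_r = max(defined) if defined else float("nan")
    return ModulationResult(epoch_correlations=epochs, max_abs_r=max_abs_r)


def firing_rates(rec: PairedRecording, state_mask: np.ndarray) -> dict:
    """SS and CS rates (spikes/s) at rest and during locomotion.

    The mask is per velocity sample; a spike inherits the state of the sample
    containing it.  Zero-duration states yield NaN.
    """
    mask = np.asarray(state_mask, dtype=np.int8)
    if mask.shape != (rec.velocity.n,):
        raise ValidationError("state mask must match the velocity grid")
    dt, t0 = rec.velocity.dt, rec.velocity.t0
    out = {}
    for state, label in ((MotionState.REST, "rest"), (MotionState.LOCOMOTION, "locomotion")):
        duration = float(np.sum(mask == state)) * dt
        for spikes, kind in ((rec.ss_times, "ss"), (rec.cs_times, "cs")):
            if duration == 0.0:
                out[f"{kind}_rate_{label}"] = float("nan")
                continue
            idx = np.clip(np.floor((spikes - t0) / dt).astype(int), 0, mask.size - 1)
            count = int(np.sum(mask[idx] == state))
            out[f"{kind}_rate_{label}"] = count / duration
    return out


def analyse_recording(rec: PairedRecording, epoch: float = 2.000, step: float = 0.200,
                      smoothing_window: float = 0.200, grid_dt: float = 0.010,
                      speed_threshold: Optional[float] = None,
                      min_locomotion: float = 20.0) -> ModulationResult:
    """Full in-vivo pipeline: mask, smoothed rate, epoch correlations, rates."""
    mask = rec.state_mask
    if mask is None:
        mask = segment_locomotion(rec.velocity, speed_threshold=speed_threshold,
                                  min_duration=min_locomotion)
    rate = instantaneous_rate(rec.ss_times, grid_dt, t0=rec.velocity.t0,
                              t_end=rec.velocity.t0 + rec.velocity.span)
    rate = gaussian_smooth(rate, smoothing_window)
    result = epoch_correlations(rate, rec.velocity, mask, epoch=epoch, step=step,
                                grid_dt=grid_dt)
    rates = firing_rates(rec, mask)
    return ModulationResult(epoch_correlations=result.epoch_correlations,
                            max_abs_r=result.max_abs_r, **rates)


def ap_features(sweep: CurrentClampSweep, detection_height: float = 0.0,
                method: str = "curvature", dvdt_criterion: float = 20.0,
                search_window_ms: float = 3.0) -> SweepFeatures:
    """Per-spike AP threshold, amplitude, AHP and half-width for one sweep.

    Spikes are voltage peaks above ``detection_height`` (mV).  The default
    threshold detector takes the maximum of the second derivative of the
    membrane potential in a window before the peak (the onset of the
    upstroke); ``method='dvdt'`` instead takes the first crossing of
    ``dvdt_criterion`` (mV/ms).  Spikes truncated at the sweep edges are
    excluded from the feature list (with a warning) but still counted.
    """
    v = sweep.voltage
    dt = sweep.dt_ms
    peaks, _ = find_peaks(v, height=detection_height)
    features = []
    n_truncated = 0
    win = int(round(search_window_ms / dt))
    for j, p in enumerate(peaks):
        w0 = max(p - win, 0) if j == 0 else max(p - win, peaks[j - 1])
        post_end = peaks[j + 1] if j + 1 < len(peaks) else v.size
        if p - w0 < 3 or post_end - p < 3:
            n_truncated += 1
            continue
        if method == "curvature":
            d2 = np.gradient(np.gradient(v[w0:p + 1], dt), dt)
            thr_idx = w0 + int(np.argmax(d2[:-1]))
        elif method == "dvdt":
            dv = np.gradient(v[w0:p + 1], dt)
            crossing = np.flatnonzero(dv >= dvdt_criterion)
            if crossing.size == 0:
                n_truncated += 1
                continue
            thr_idx = w0 + int(crossing[0])
        else:
            raise ValidationError("method must be 'curvature' or 'dvdt'")
        threshold = float(v[thr_idx])
        amplitude = float(v[p]) - threshold
        trough = float(np.min(v[p:post_end]))
        half_level = threshold + amplitude / 2.0
        left = np.flatnonzero(v[w0:p] <= half_level)
        right = np.flatnonzero(v[p + 1:post_end] <= half_level)
        if left.size == 0 or right.size == 0:
            half_width = float("nan")
        else:
            i0 = w0 + left[-1]  # last sample at/below the level before the peak
            t_left = i0 + ((half_level - v[i0]) / (v[i0 + 1] - v[i0])
                           if v[i0 + 1] != v[i0] else 0.0)
            i1 = p + 1 + right[0]  # first sample at/below the level after the peak
            t_right = (i1 - 1) + ((half_level - v[i1 - 1]) / (v[i1] - v[i1 - 1])
                                  if v[i1] != v[i1 - 1] else 0.0)
            half_width = (t_right - t_left) * dt
        features.append(
            WaveformFeatures(
                ap_threshold=threshold,
                ap_amplitude=amplitude,
                ahp_amplitude=threshold - trough,
                half_width=float(half_width),
                peak_time_ms=float(p * dt),
            )
        )
    if n_truncated:
        warnings.warn(f"{n_truncated} spike(s) truncated at sweep edges; "
                      "excluded from waveform features", stacklevel=2)
    return SweepFeatures(spike_count=int(len(peaks)), features=features)


def fi_curve(sweeps: Sequence[CurrentClampSweep], **detect_kwargs) -> pd.DataFrame:
    """Spike count versus injected current, one row per sweep, no fitting.

    Duplicate currents are kept as separate rows and flagged.
    """
    if len(sweeps) < 2 or len({s.injected_current for s in sweeps}) < 2:
        raise ValidationError("F-I curve needs at least two sweeps with distinct currents")
    rows = []
    for sweep in sweeps:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            count = ap_features(sweep, **detect_kwargs).spike_count
        rows.append({"sweep_id": sweep.sweep_id, "current_pA": sweep.injected_current,
                     "spike_count": count})
    table = pd.DataFrame(rows).sort_values("current_pA", kind="stable").reset_index(drop=True)
    table["duplicate_current"] = table["current_pA"].duplicated(keep=False)
    return table
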