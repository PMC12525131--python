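"""Electrographic seizure and status-epilepticus detection.

Single-channel EEG is screened with operational criteria: an
electrographic seizure is a run of spike-wave discharges repeating faster
than 2 Hz, at least 3 times the baseline amplitude, and lasting longer
than 10 s.  Status epilepticus (SE) offset is a sustained slowing of the
discharge rate below 1 Hz.

The pipeline is: robust baseline scale (MAD of a quiet epoch) →
running-median-subtracted spike extraction → sliding-window spike rate →
interval segmentation with gap merging → per-event rate/amplitude/duration
screening.  All thresholds live in :class:`DetectorParams`; the defaults
encode the criteria above.  Event intervals are half-open ``[start, end)``
in seconds from the trace's ``t0``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .exceptions import DegenerateBaselineError, InputError, InvalidParameterError

__all__ = [
    "EEGTrace",
    "BaselineStats",
    "SpikeTrain",
    "SeizureEvent",
    "SEBounds",
    "DetectorParams",
    "BehavioralScore",
    "PowerSpectrogram",
    "baseline_stats",
    "detect_spikes",
    "spike_rate",
    "detect_seizure_events",
    "detect_se",
    "power_spectrogram",
]

#: Gaussian-consistency factor turning a median absolute deviation into a
#: standard-deviation-equivalent scale
MAD_TO_SIGMA = 1.4826

#: refractory separation between detected spikes, seconds
SPIKE_REFRACTORY_S = 0.05

#: running-median window for slow-drift removal, seconds
RUNNING_MEDIAN_S = 0.5


class BehavioralScore(enum.IntEnum):
    """Modified Racine behavioral seizure severity scale (BSS1–BSS6)."""

    BSS1 = 1  # normal behavior
    BSS2 = 2  # behavioral arrest, facial twitching, or head bobbing
    BSS3 = 3  # unilateral forelimb clonus
    BSS4 = 4  # bilateral forelimb clonus
    BSS5 = 5  # rearing and loss of motor control
    BSS6 = 6  # running seizures and involuntary jumping

    @property
    def label(self) -> str:
        return _BSS_LABELS[self.value]


_BSS_LABELS = {
    1: "normal behavior",
    2: "behavioral arrest, facial twitching, or head bobbing",
    3: "unilateral forelimb clonus",
    4: "bilateral forelimb clonus",
    5: "rearing and loss of motor control",
    6: "running seizures and involuntary jumping",
}


@dataclass(frozen=True)
class EEGTrace:
    """Sampled single-channel EEG (µV)."""

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise InputError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise InputError("samples must be finite")
        if not (self.sampling_rate > 0 and math.isfinite(self.sampling_rate)):
            raise InvalidParameterError(
                f"sampling_rate must be positive, got {self.sampling_rate}"
            )
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.sampling_rate


@dataclass(frozen=True)
class BaselineStats:
    """Robust amplitude scale of a baseline (pre-injection) epoch."""

    amplitude_scale: float
    epoch: tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.amplitude_scale > 0):
            raise InvalidParameterError("amplitude_scale must be positive")


@dataclass(frozen=True)
class SpikeTrain:
    """Detected spike times (s) with absolute deviation amplitudes (µV)."""

    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        amps = np.asarray(self.amplitudes, dtype=float)
        if times.shape != amps.shape or times.ndim != 1:
            raise InputError("times and amplitudes must be equal-length 1-D arrays")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise InputError("spike times must be strictly increasing")
        if np.any(amps <= 0):
            raise InputError("spike amplitudes must be positive")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "amplitudes", amps)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class SeizureEvent:
    """One detected electrographic seizure, ``[start, end)`` seconds."""

    start: float
    end: float
    mean_spike_rate: float
    median_amplitude_ratio: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class SEBounds:
    """Status epilepticus onset/offset; ``offset`` is ``None`` while the
    animal is still in SE at the end of the trace (right-censored)."""

    onset: float
    offset: Optional[float]

    def __post_init__(self) -> None:
        if self.offset is not None and self.offset <= self.onset:
            raise InputError("SE offset must follow onset")


@dataclass(frozen=True)
class DetectorParams:
    """All detector thresholds.

    min_rate (Hz), amp_ratio (× baseline) and min_duration (s) are the
    seizure criteria; se_min_duration promotes an event to SE onset;
    se_offset_rate/se_offset_sustain define the sustained slowing that
    marks SE offset.
    """

    min_rate: float = 2.0
    amp_ratio: float = 3.0
    min_duration: float = 10.0
    merge_gap: float = 5.0
    rate_window: float = 2.0
    se_min_duration: float = 300.0
    se_offset_rate: float = 1.0
    se_offset_sustain: float = 120.0

    def __post_init__(self) -> None:
        for name in (
            "min_rate", "amp_ratio", "min_duration", "merge_gap",
            "rate_window", "se_min_duration", "se_offset_rate",
            "se_offset_sustain",
        ):
            if not (getattr(self, name) > 0):
                raise InvalidParameterError(f"{name} must be positive")


def baseline_stats(trace: EEGTrace, epoch: tuple[float, float] = (0.0, 60.0)) -> BaselineStats:
    """Robust baseline amplitude: 1.4826 × MAD of the epoch samples.

    The epoch (seconds, relative to ``t0``-anchored time) must lie within
    the trace and span at least 10 s.  A flat epoch (zero MAD) raises
    :class:`DegenerateBaselineError`.
    """
    start, end = float(epoch[0]), float(epoch[1])
    if end - start < 10.0:
        raise InputError(f"baseline epoch must span >= 10 s, got {end - start} s")
    if start < trace.t0 - 1e-9 or end > trace.t_end + 1e-9:
        raise InputError(
            f"epoch [{start}, {end}] outside trace [{trace.t0}, {trace.t_end}]"
        )
    fs = trace.sampling_rate
    i0 = int(round((start - trace.t0) * fs))
    i1 = int(round((end - trace.t0) * fs))
    seg = trace.samples[i0:i1]
    med = np.median(seg)
    mad = np.median(np.abs(seg - med))
    if mad == 0:
        raise DegenerateBaselineError(
            "baseline epoch has zero amplitude spread (flat signal)"
        )
    scale = MAD_TO_SIGMA * float(mad)
    floor = np.finfo(float).eps * float(np.max(np.abs(trace.samples)))
    return BaselineStats(amplitude_scale=max(scale, floor), epoch=(start, end))


def _deviation(trace: EEGTrace) -> np.ndarray:
    """Samples minus a running median (slow drift / DC removal)."""
    win = int(round(RUNNING_MEDIAN_S * trace.sampling_rate))
    win = max(3, win | 1)  # odd, >= 3
    if win >= len(trace.samples):
        return trace.samples - np.median(trace.samples)
    return trace.samples - median_filter(trace.samples, size=win, mode="nearest")


def detect_spikes(
    trace: EEGTrace, baseline: BaselineStats, params: DetectorParams = DetectorParams()
) -> SpikeTrain:
    """Local extrema of the running-median-subtracted signal exceeding
    ``amp_ratio × amplitude_scale``, separated by a 50 ms refractory."""
    dev = np.abs(_deviation(trace))
    threshold = params.amp_ratio * baseline.amplitude_scale
    distance = max(1, int(round(SPIKE_REFRACTORY_S * trace.sampling_rate)))
    idx, props = find_peaks(dev, height=threshold, distance=distance)
    return SpikeTrain(
        times=trace.t0 + idx / trace.sampling_rate,
        amplitudes=props["peak_heights"],
    )


def spike_rate(train: SpikeTrain, rate_window: float, t_grid: Sequence[float]) -> np.ndarray:
    """Centered sliding-window spike rate (Hz) at each grid time.

    The window is half-open, ``[t - w/2, t + w/2)``, matching the event
    interval convention.
    """
    if rate_window <= 0:
        raise InputError("rate_window must be positive")
    grid = np.asarray(t_grid, dtype=float)
    half = rate_window / 2.0
    lo = np.searchsorted(train.times, grid - half, side="left")
    hi = np.searchsorted(train.times, grid + half, side="left")
    return (hi - lo) / rate_window


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Index ranges [i, j) of True runs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_seizure_events(
    trace: EEGTrace, baseline: BaselineStats, params: DetectorParams = DetectorParams()
) -> list[SeizureEvent]:
    """Segment the trace into electrographic seizures.

    Maximal intervals where the sliding spike rate exceeds ``min_rate`` are
    merged across gaps shorter than ``merge_gap``, trimmed to their first
    and last spike, and kept iff duration > ``min_duration`` and the median
    spike amplitude ratio >= ``amp_ratio``.  Returned events are disjoint
    and time-ordered.
    """
    if trace.duration <= params.min_duration:
        raise InputError("trace shorter than the minimum event duration")
    train = detect_spikes(trace, baseline, params)
    if len(train) == 0:
        return []
    step = min(0.5, params.rate_window / 4.0)
    grid = np.arange(trace.t0, trace.t_end + step / 2, step)
    rate = spike_rate(train, params.rate_window, grid)
    intervals = [(grid[i], grid[j - 1]) for i, j in _runs(rate > params.min_rate)]
    # merge across short rate dips
    merged: list[list[float]] = []
    for s, e in intervals:
        if merged and s - merged[-1][1] < params.merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    events: list[SeizureEvent] = []
    for s, e in merged:
        in_ev = (train.times >= s - step) & (train.times <= e + step)
        n = int(np.count_nonzero(in_ev))
        if n < 2:
            continue
        t_ev = train.times[in_ev]
        start, end = float(t_ev[0]), float(t_ev[-1])
        duration = end - start
        if duration <= params.min_duration:
            continue
        if n / duration <= params.min_rate:
            continue
        ratio = float(np.median(train.amplitudes[in_ev]) / baseline.amplitude_scale)
        if ratio < params.amp_ratio:
            continue
        events.append(
            SeizureEvent(
                start=start,
                end=end,
                mean_spike_rate=n / duration,
                median_amplitude_ratio=ratio,
            )
        )
    return events


def detect_se(
    events: Sequence[SeizureEvent],
    trace: EEGTrace,
    baseline: BaselineStats,
    params: DetectorParams = DetectorParams(),
) -> Optional[SEBounds]:
    """Locate status epilepticus within detected events.

    Onset is the start of the first event lasting >= ``se_min_duration``.
    Offset is the earliest time after onset at which the discharge rate
    has slowed below ``se_offset_rate`` and stays below it on average for
    the next ``se_offset_sustain`` seconds (windowed rate below threshold
    at the candidate time *and* mean spike rate over the sustain interval
    below threshold — the averaged form tolerates isolated spurious
    peaks).  If no such sustained quiet interval completes before the
    trace ends, the offset is open (``None``) — the animal is still in SE
    at the end of the recording.
    """
    onset = None
    for ev in events:
        if ev.duration >= params.se_min_duration:
            onset = ev.start
            break
    if onset is None:
        return None
    train = detect_spikes(trace, baseline, params)
    step = 0.5
    t_last = trace.t_end - params.se_offset_sustain
    if t_last > onset:
        grid = np.arange(onset + step, t_last + step / 2, step)
        rate_now = spike_rate(train, params.rate_window, grid)
        n_sustain = np.searchsorted(
            train.times, grid + params.se_offset_sustain, side="left"
        ) - np.searchsorted(train.times, grid, side="left")
        rate_sustain = n_sustain / params.se_offset_sustain
        ok = (rate_now < params.se_offset_rate) & (
            rate_sustain < params.se_offset_rate
        )
        if ok.any():
            return SEBounds(onset=onset, offset=float(grid[int(np.argmax(ok))]))
    return SEBounds(onset=onset, offset=None)


@dataclass(frozen=True)
class PowerSpectrogram:
    """Short-time power representation: ``power[i, k]`` is the power of
    segment ``i`` in frequency bin ``k``; per-segment total power equals
    the segment's time-domain mean square (Parseval)."""

    times: np.ndarray
    frequencies: np.ndarray
    power: np.ndarray

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        with np.errstate(divide="ignore"):
            db = 10 * np.log10(np.maximum(self.power.T, 1e-300))
        ax.pcolormesh(self.times, self.frequencies, db, shading="nearest")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("frequency (Hz)")
        return ax


def power_spectrogram(trace: EEGTrace, segment: float, step: float) -> PowerSpectrogram:
    """Non-overlapping-capable short-time periodogram.

    Power is normalised so that ``power[i].sum()`` equals the mean square
    of segment ``i`` (one-sided bins, boxcar window).
    """
    fs = trace.sampling_rate
    nseg = int(round(segment * fs))
    nstep = max(1, int(round(step * fs)))
    if nseg > len(trace.samples):
        raise InputError("segment longer than trace")
    if nseg < 1:
        raise InputError("segment must contain at least one sample")
    starts = np.arange(0, len(trace.samples) - nseg + 1, nstep)
    freqs = np.fft.rfftfreq(nseg, d=1.0 / fs)
    power = np.empty((len(starts), len(freqs)))
    for i, s in enumerate(starts):
        x = trace.samples[s : s + nseg]
        spec = np.abs(np.fft.rfft(x)) ** 2 / nseg**2
        # fold two-sided power into one-sided bins
        if nseg % 2 == 0:
            spec[1:-1] *= 2.0
        else:
            spec[1:] *= 2.0
        power[i] = spec
    times = trace.t0 + (starts + nseg / 2.0) / fs
    return PowerSpectrogram(times=times, frequencies=freqs, power=power)
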