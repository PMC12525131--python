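"""Synthetic inputs with ground truth for every downstream analysis.

Three generators emulate the data the toolkit consumes:

* :func:`gen_pk_samples` — noisy brain-concentration samples from the
  Bateman model under a known schedule (lognormal multiplicative noise so
  concentrations stay positive, parameterised by coefficient of variation);
* :func:`gen_eeg` — Gaussian background EEG plus embedded rhythmic
  spike-wave events of specified rate, amplitude (× baseline) and
  duration, with exact event intervals as truth;
* :func:`gen_diary` / :func:`gen_weekly` — daily seizure counts drawn
  negative-binomially around a pattern-specific rate trajectory (regular,
  clustered, progressive, remitting), and Poisson weekly totals around a
  given mean trajectory.

Every generator is a pure function of its spec plus seed
(bit-reproducible), and generated objects satisfy the invariants of the
types they instantiate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .diary import SeizureDiary, SeizurePattern
from .eeg import EEGTrace
from .exceptions import InputError
from .pk import ConcentrationSeries, DoseSchedule, PKParams, concentration

__all__ = [
    "DiarySpec",
    "EEGSpec",
    "EEGEventSpec",
    "PKGroundTruth",
    "EEGGroundTruth",
    "DiaryGroundTruth",
    "gen_pk_samples",
    "gen_eeg",
    "gen_diary",
    "gen_weekly",
    "SPIKE_TEMPLATE_WIDTH_S",
]

#: total width of the biphasic spike-wave template, seconds
SPIKE_TEMPLATE_WIDTH_S = 0.07


# ---------------------------------------------------------------------------
# PK samples


@dataclass(frozen=True)
class PKGroundTruth:
    params: PKParams
    schedule: DoseSchedule
    noise_free: np.ndarray


def gen_pk_samples(
    params: PKParams,
    schedule: DoseSchedule,
    cv: float = 0.05,
    n: int = 24,
    horizon: float = 180.0,
    seed: int = 0,
) -> tuple[ConcentrationSeries, PKGroundTruth]:
    """Noisy concentration–time samples from the Bateman model.

    ``n`` sample times are spread evenly over ``(0, horizon]``; values are
    the model concentration times lognormal multiplicative noise with
    coefficient of variation ``cv`` (mean 1), so ``cv = 0`` reproduces the
    model exactly.
    """
    if cv < 0:
        raise InputError("cv must be >= 0")
    if n < 1:
        raise InputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    times = np.linspace(horizon / n, horizon, n)
    clean = concentration(schedule, times, params)
    clean = np.atleast_1d(np.asarray(clean, dtype=float))
    if cv > 0:
        sigma2 = np.log1p(cv**2)
        noise = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)
    else:
        noise = np.ones(n)
    return (
        ConcentrationSeries(times=times, values=clean * noise),
        PKGroundTruth(params=params, schedule=schedule, noise_free=clean),
    )


# ---------------------------------------------------------------------------
# EEG


@dataclass(frozen=True)
class EEGEventSpec:
    """One embedded spike-wave event."""

    start: float
    duration: float
    spike_rate: float
    amplitude_ratio: float


@dataclass(frozen=True)
class EEGSpec:
    """Recipe for a synthetic EEG trace."""

    duration: float = 3600.0
    sampling_rate: float = 200.0
    noise_scale: float = 20.0
    events: tuple[EEGEventSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate < 100:
            raise InputError("sampling_rate must be >= 100 Hz")
        events = tuple(
            e if isinstance(e, EEGEventSpec) else EEGEventSpec(*e) for e in self.events
        )
        ordered = sorted(events, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.start + a.duration > b.start:
                raise InputError(
                    f"events overlap: [{a.start}, {a.start + a.duration}) and "
                    f"[{b.start}, ...)"
                )
        for e in ordered:
            if e.start < 0 or e.start + e.duration > self.duration:
                raise InputError("event outside trace duration")
        object.__setattr__(self, "events", ordered and tuple(ordered) or ())


@dataclass(frozen=True)
class EEGGroundTruth:
    events: tuple[EEGEventSpec, ...]
    spike_times: np.ndarray
    noise_scale: float


def _spike_template(fs: float) -> np.ndarray:
    """Biphasic spike-wave complex, unit positive peak.

    Sharp positive spike (10 ms triangular) followed by a slower negative
    wave (half-sine over the remaining 60 ms, 0.3 × peak).  Only the rate,
    amplitude and duration of the complexes matter to the detector.
    """
    n_pos = max(3, int(round(0.010 * fs)) | 1)
    n_neg = max(2, int(round((SPIKE_TEMPLATE_WIDTH_S - 0.010) * fs)))
    pos = 1.0 - np.abs(np.linspace(-1, 1, n_pos))
    neg = -0.3 * np.sin(np.linspace(0, np.pi, n_neg))
    return np.concatenate([pos, neg])


def gen_eeg(spec: EEGSpec) -> tuple[EEGTrace, EEGGroundTruth]:
    """Gaussian background plus embedded periodic spike-wave events.

    Each event contributes complexes at ``spike_rate`` whose positive peak
    is ``amplitude_ratio × noise_scale`` — i.e. ``amplitude_ratio`` times
    the MAD-based baseline scale the detector estimates on Gaussian
    background of standard deviation ``noise_scale``.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    n = int(round(spec.duration * fs))
    x = rng.normal(0.0, spec.noise_scale, n)
    template = _spike_template(fs)
    peak_offset = int(np.argmax(template))
    all_spike_times: list[float] = []
    for ev in spec.events:
        n_spikes = int(np.floor(ev.duration * ev.spike_rate))
        times = ev.start + np.arange(n_spikes) / ev.spike_rate
        amp = ev.amplitude_ratio * spec.noise_scale
        for t in times:
            i0 = int(round(t * fs)) - peak_offset
            j0, j1 = max(i0, 0), min(i0 + len(template), n)
            if j0 >= j1:
                continue
            x[j0:j1] += amp * template[j0 - i0 : j1 - i0]
            all_spike_times.append(t)
    trace = EEGTrace(samples=x, sampling_rate=fs, t0=0.0)
    truth = EEGGroundTruth(
        events=spec.events,
        spike_times=np.array(all_spike_times),
        noise_scale=spec.noise_scale,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# Diaries


@dataclass(frozen=True)
class DiarySpec:
    """Recipe for a synthetic seizure diary.

    ``dispersion`` is negative-binomial overdispersion ``a >= 0`` with
    ``var = mu + a mu^2``; ``a = 0`` degenerates to Poisson.  Pattern
    parameters: regular uses ``base_rate`` throughout; clustered
    alternates ``cluster_dwell`` days at ``cluster_rate`` with
    ``quiescent_dwell`` seizure-free days; progressive ramps linearly from
    ``base_rate`` to ``ramp_end_rate``; remitting decays as
    ``base_rate * exp(-decay_k * day)``.
    """

    pattern: SeizurePattern = SeizurePattern.REGULAR
    n_days: int = 42
    base_rate: float = 2.0
    dispersion: float = 0.3
    cluster_rate: float = 12.0
    cluster_dwell: int = 2
    quiescent_dwell: int = 6
    ramp_end_rate: float = 4.0
    decay_k: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        pattern = self.pattern
        if isinstance(pattern, str) and pattern == "clustered":
            pattern = SeizurePattern.CLUSTERING
        object.__setattr__(self, "pattern", SeizurePattern(pattern))
        if self.n_days < 7:
            raise InputError("n_days must be >= 7")
        for name in ("base_rate", "cluster_rate", "ramp_end_rate"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if self.dispersion < 0 or self.decay_k < 0:
            raise InputError("dispersion and decay_k must be >= 0")


@dataclass(frozen=True)
class DiaryGroundTruth:
    pattern: SeizurePattern
    daily_rates: np.ndarray


def _rate_trajectory(spec: DiarySpec) -> np.ndarray:
    days = np.arange(spec.n_days)
    if spec.pattern is SeizurePattern.REGULAR:
        return np.full(spec.n_days, spec.base_rate)
    if spec.pattern is SeizurePattern.CLUSTERING:
        period = spec.cluster_dwell + spec.quiescent_dwell
        in_burst = (days % period) < spec.cluster_dwell
        return np.where(in_burst, spec.cluster_rate, 0.0)
    if spec.pattern is SeizurePattern.PROGRESSIVE:
        return np.linspace(spec.base_rate, spec.ramp_end_rate, spec.n_days)
    if spec.pattern is SeizurePattern.REMITTING:
        return spec.base_rate * np.exp(-spec.decay_k * days)
    raise InputError(f"cannot generate pattern {spec.pattern}")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, a: float) -> np.ndarray:
    """Negative binomial via gamma–Poisson mixture; ``a = 0`` is Poisson."""
    mu = np.asarray(mu, dtype=float)
    if a == 0:
        return rng.poisson(mu)
    lam = np.where(mu > 0, rng.gamma(1.0 / a, a * np.maximum(mu, 1e-300)), 0.0)
    return rng.poisson(lam)


def gen_diary(spec: DiarySpec) -> tuple[SeizureDiary, DiaryGroundTruth]:
    """Daily seizure counts around the pattern's rate trajectory."""
    rng = np.random.default_rng(spec.seed)
    rates = _rate_trajectory(spec)
    counts = _nb_draw(rng, rates, spec.dispersion)
    diary = SeizureDiary(
        animal_id=f"sim-{spec.pattern.value}-{spec.seed}",
        counts=counts,
        recording_start=0,
        se_day=None,
    )
    return diary, DiaryGroundTruth(pattern=spec.pattern, daily_rates=rates)


def gen_weekly(
    trajectory: Sequence[float], noise: str = "poisson", seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson weekly totals around a weekly mean trajectory.

    Returns ``(totals, means)`` where ``means`` is the truth.
    """
    means = np.asarray(trajectory, dtype=float)
    if np.any(means < 0):
        raise InputError("weekly means must be >= 0")
    if noise != "poisson":
        raise InputError(f"unknown noise model {noise!r}")
    rng = np.random.default_rng(seed)
    return rng.poisson(means), means
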