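"""Chronic-epilepsy statistics from daily seizure diaries.

A diary is the per-animal sequence of daily seizure counts over a
video/EEG recording span.  The statistics implemented here follow the
operational definitions used for the pilocarpine TLE model:

* seizure frequency = total seizures / days from the first seizure to the
  end of the recording (inclusive span);
* % seizure-free days = days without seizures within that same span;
* a *high day* has strictly more than 7 seizures;
* a *cluster* is a (run of) high day(s) followed by 5 or more consecutive
  seizure-free days, fully inside the record;
* an animal is epileptic iff it had at least two spontaneous seizures;
* remission is assessed on weekly seizure totals by comparing one-phase
  decay / straight line / horizontal line (and optionally Gaussian) fits
  (see :mod:`pilotle.remission`);
* the dose required to trigger SE is summarised by a Kaplan–Meier
  product-limit curve over cumulative pilocarpine dose, right-censoring
  animals that never reached SE.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import norm

from .exceptions import InputError, NoSeizuresError

__all__ = [
    "SeizureDiary",
    "ClusterEvent",
    "SeizurePattern",
    "DiaryStats",
    "DoseToSERecord",
    "MannKendallResult",
    "KaplanMeierDoseCurve",
    "seizure_frequency",
    "pct_seizure_free_days",
    "flag_high_days",
    "detect_clusters",
    "mann_kendall_trend",
    "classify_pattern",
    "weekly_counts",
    "epilepsy_status",
    "diary_stats",
    "km_dose_to_se",
    "HIGH_DAY_THRESHOLD",
    "MIN_FREE_RUN",
    "EPILEPSY_MIN_SEIZURES",
]

#: a "high day" has strictly more than this many seizures
HIGH_DAY_THRESHOLD = 7
#: minimum number of consecutive seizure-free days after a high day to
#: count as a cluster
MIN_FREE_RUN = 5
#: minimum number of spontaneous seizures that defines epilepsy
EPILEPSY_MIN_SEIZURES = 2


class SeizurePattern(str, enum.Enum):
    REGULAR = "regular"
    CLUSTERING = "clustering"
    PROGRESSIVE = "progressive"
    REMITTING = "remitting"
    NON_EPILEPTIC = "non_epileptic"


@dataclass(frozen=True)
class SeizureDiary:
    """Daily seizure counts for one animal.

    ``counts[i]`` is the number of seizures on day ``recording_start + i``;
    every day in ``[recording_start, recording_end]`` has an explicit count.
    """

    animal_id: str
    counts: np.ndarray
    recording_start: int = 0
    se_day: Optional[int] = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 1 or counts.size < 1:
            raise InputError("counts must be a non-empty 1-D sequence")
        if np.any(counts < 0):
            raise InputError("seizure counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_mapping(
        cls,
        animal_id: str,
        day_counts: Mapping[int, int],
        se_day: Optional[int] = None,
    ) -> "SeizureDiary":
        days = sorted(day_counts)
        if days != list(range(days[0], days[-1] + 1)):
            missing = sorted(set(range(days[0], days[-1] + 1)) - set(days))
            raise InputError(f"day gaps in diary for {animal_id}: missing {missing}")
        return cls(
            animal_id=animal_id,
            counts=np.array([day_counts[d] for d in days], dtype=int),
            recording_start=days[0],
            se_day=se_day,
        )

    @property
    def recording_end(self) -> int:
        return self.recording_start + len(self.counts) - 1

    @property
    def days(self) -> np.ndarray:
        return self.recording_start + np.arange(len(self.counts))

    @property
    def day_counts(self) -> dict[int, int]:
        return dict(zip(self.days.tolist(), self.counts.tolist()))

    @property
    def n_seizures(self) -> int:
        return int(self.counts.sum())

    @property
    def first_seizure_day(self) -> Optional[int]:
        nz = np.flatnonzero(self.counts)
        return None if nz.size == 0 else int(self.recording_start + nz[0])

    @property
    def latency_days(self) -> Optional[int]:
        """Days from SE to the first spontaneous seizure."""
        if self.se_day is None or self.first_seizure_day is None:
            return None
        return self.first_seizure_day - self.se_day


@dataclass(frozen=True)
class ClusterEvent:
    """A high day (last of a consecutive high-day run) followed by at
    least ``MIN_FREE_RUN`` seizure-free days."""

    high_day: int
    count: int
    free_run: int


@dataclass(frozen=True)
class DoseToSERecord:
    """Cumulative pilocarpine dose at SE onset, or at the last dose for
    animals that never reached SE (right-censored)."""

    animal_id: str
    cumulative_dose: float
    reached_se: bool

    def __post_init__(self) -> None:
        if not (self.cumulative_dose > 0):
            raise InputError("cumulative_dose must be positive")


@dataclass(frozen=True)
class MannKendallResult:
    s: int
    z: float
    p: float


def epilepsy_status(diary: SeizureDiary) -> bool:
    """True iff the diary records at least two spontaneous seizures."""
    return diary.n_seizures >= EPILEPSY_MIN_SEIZURES


def _first_seizure_span(diary: SeizureDiary) -> tuple[int, int]:
    first = diary.first_seizure_day
    if first is None:
        raise NoSeizuresError(
            f"diary {diary.animal_id} has no seizures; frequency undefined"
        )
    span = diary.recording_end - first + 1  # inclusive of both endpoints
    return first, span


def seizure_frequency(diary: SeizureDiary) -> float:
    """Seizures per day: total count / inclusive days from first seizure
    to the end of the recording."""
    _, span = _first_seizure_span(diary)
    return diary.n_seizures / span


def pct_seizure_free_days(diary: SeizureDiary) -> float:
    """Percent of days without seizures between the first seizure and the
    end of the recording (inclusive span)."""
    first, span = _first_seizure_span(diary)
    i0 = first - diary.recording_start
    free = int(np.count_nonzero(diary.counts[i0:] == 0))
    return 100.0 * free / span


def flag_high_days(diary: SeizureDiary, high_threshold: int = HIGH_DAY_THRESHOLD) -> list[int]:
    """Days with strictly more than ``high_threshold`` seizures."""
    return diary.days[diary.counts > high_threshold].tolist()


def detect_clusters(
    diary: SeizureDiary,
    high_threshold: int = HIGH_DAY_THRESHOLD,
    min_free_run: int = MIN_FREE_RUN,
) -> list[ClusterEvent]:
    """Cluster events: high day(s) followed by >= ``min_free_run``
    seizure-free days.

    Consecutive high days collapse into one event anchored at the run's
    last day; the following free days must all lie within the record.
    ``free_run`` is the full length of the following zero run.
    """
    counts = diary.counts
    n = len(counts)
    high = counts > high_threshold
    events: list[ClusterEvent] = []
    i = 0
    while i < n:
        if not high[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and high[j + 1]:
            j += 1
        # anchor at the run's last day; count the zero run that follows
        k = j + 1
        while k < n and counts[k] == 0:
            k += 1
        free = k - (j + 1)
        if j + 1 + min_free_run <= n and free >= min_free_run:
            events.append(
                ClusterEvent(
                    high_day=int(diary.recording_start + j),
                    count=int(counts[j]),
                    free_run=int(free),
                )
            )
        i = j + 1
    return events


def mann_kendall_trend(series: Sequence[float]) -> MannKendallResult:
    """Mann–Kendall trend test with tie correction.

    ``S = sum_{i<j} sign(x_j - x_i)``; the normal approximation uses the
    tie-corrected variance and a continuity correction.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise InputError("Mann–Kendall needs at least 4 points")
    n = len(x)
    s = int(np.sign(x[None, :] - x[:, None])[np.triu_indices(n, k=1)].sum())
    _, tie_counts = np.unique(x, return_counts=True)
    var = (
        n * (n - 1) * (2 * n + 5)
        - sum(t * (t - 1) * (2 * t + 5) for t in tie_counts if t > 1)
    ) / 18.0
    if var <= 0:
        return MannKendallResult(s=s, z=0.0, p=1.0)
    if s > 0:
        z = (s - 1) / math.sqrt(var)
    elif s < 0:
        z = (s + 1) / math.sqrt(var)
    else:
        z = 0.0
    p = 2.0 * float(norm.sf(abs(z)))
    return MannKendallResult(s=s, z=z, p=min(p, 1.0))


def weekly_counts(diary: SeizureDiary, anchor: Optional[int] = None) -> np.ndarray:
    """Total seizures per consecutive 7-day bin starting at ``anchor``
    (default: the first seizure day).  A final partial week is dropped."""
    if anchor is None:
        anchor = diary.first_seizure_day
        if anchor is None:
            raise NoSeizuresError(
                f"diary {diary.animal_id} has no seizures; no default anchor"
            )
    if not (diary.recording_start <= anchor <= diary.recording_end):
        raise InputError(f"anchor day {anchor} outside record")
    i0 = anchor - diary.recording_start
    tail = diary.counts[i0:]
    n_weeks = len(tail) // 7
    return tail[: 7 * n_weeks].reshape(n_weeks, 7).sum(axis=1)


def classify_pattern(
    diary: SeizureDiary,
    high_threshold: int = HIGH_DAY_THRESHOLD,
    min_free_run: int = MIN_FREE_RUN,
    alpha: float = 0.05,
    remit_final_fraction: float = 0.25,
) -> SeizurePattern:
    """Classify the diary's seizure dynamics.

    Precedence: non-epileptic (< 2 seizures) → remitting (a declining
    weekly trajectory model — one-phase decay with Y0 > plateau, or a line
    with negative slope — beats the horizontal line at ``alpha`` by the
    extra-sum-of-squares F-test, and the final week falls below
    ``remit_final_fraction`` of the peak week) → progressive (Mann–Kendall
    upward trend in daily counts at ``alpha``) → clustering (>= 1 cluster
    event) → regular.
    """
    from .remission import RemissionModelName, fit_remission_models

    if not epilepsy_status(diary):
        return SeizurePattern.NON_EPILEPTIC
    try:
        weekly = weekly_counts(diary)
    except NoSeizuresError:  # pragma: no cover - excluded by status check
        weekly = np.array([])
    if len(weekly) >= 4:
        res = {f.model: f for f in fit_remission_models(weekly)[0]}
        decay = res[RemissionModelName.ONE_PHASE_DECAY]
        line = res[RemissionModelName.STRAIGHT_LINE]
        declining = []
        if decay.params["y0"] > decay.params["plateau"] and decay.params["k"] > 0:
            declining.append(decay)
        if line.params["slope"] < 0:
            declining.append(line)
        peak = weekly.max()
        if (
            any(f.p_vs_horizontal < alpha for f in declining)
            and peak > 0
            and weekly[-1] < remit_final_fraction * peak
        ):
            return SeizurePattern.REMITTING
    if len(diary.counts) >= 4:
        mk = mann_kendall_trend(diary.counts)
        if mk.z > 0 and mk.p < alpha:
            return SeizurePattern.PROGRESSIVE
    if detect_clusters(diary, high_threshold, min_free_run):
        return SeizurePattern.CLUSTERING
    return SeizurePattern.REGULAR


@dataclass(frozen=True)
class DiaryStats:
    """Bundle of all per-diary statistics."""

    animal_id: str
    n_seizures: int
    span_days: int
    frequency: Optional[float]
    pct_seizure_free: Optional[float]
    first_seizure_day: Optional[int]
    latency_days: Optional[int]
    high_days: list[int]
    clusters: list[ClusterEvent]
    pattern: SeizurePattern

    def to_dict(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "n_seizures": self.n_seizures,
            "span_days": self.span_days,
            "frequency_sz_per_day": self.frequency,
            "pct_seizure_free_days": self.pct_seizure_free,
            "first_seizure_day": self.first_seizure_day,
            "latency_days": self.latency_days,
            "high_days": self.high_days,
            "n_clusters": len(self.clusters),
            "pattern": self.pattern.value,
        }


def diary_stats(
    diary: SeizureDiary,
    high_threshold: int = HIGH_DAY_THRESHOLD,
    min_free_run: int = MIN_FREE_RUN,
) -> DiaryStats:
    """Compute the full statistics bundle for one diary."""
    epileptic = epilepsy_status(diary)
    has_seizure = diary.first_seizure_day is not None
    return DiaryStats(
        animal_id=diary.animal_id,
        n_seizures=diary.n_seizures,
        span_days=len(diary.counts),
        frequency=seizure_frequency(diary) if has_seizure else None,
        pct_seizure_free=pct_seizure_free_days(diary) if has_seizure else None,
        first_seizure_day=diary.first_seizure_day,
        latency_days=diary.latency_days,
        high_days=flag_high_days(diary, high_threshold),
        clusters=detect_clusters(diary, high_threshold, min_free_run),
        pattern=classify_pattern(diary, high_threshold, min_free_run),
    )


class KaplanMeierDoseCurve:
    """Product-limit estimate of the fraction of animals not yet in SE as
    cumulative pilocarpine dose increases.

    Thin wrapper over :class:`lifelines.KaplanMeierFitter` with dose in
    place of time; ties between SE events and censorings at the same dose
    follow the standard convention (events first).
    """

    def __init__(self, records: Sequence[DoseToSERecord]):
        from lifelines import KaplanMeierFitter

        records = list(records)
        if not records:
            raise InputError("need at least one dose-to-SE record")
        self.records = records
        doses = [r.cumulative_dose for r in records]
        observed = [r.reached_se for r in records]
        self._kmf = KaplanMeierFitter()
        self._kmf.fit(doses, event_observed=observed, label="fraction not in SE")
        sf = self._kmf.survival_function_
        self.doses = sf.index.to_numpy(dtype=float)
        self.survival = sf.iloc[:, 0].to_numpy(dtype=float)

    def survival_at(self, dose: float) -> float:
        """Step-function value just after ``dose``."""
        idx = np.searchsorted(self.doses, dose, side="right") - 1
        return float(self.survival[max(idx, 0)])

    def plot(self, ax=None):
        ax = self._kmf.plot_survival_function(ax=ax)
        ax.set_xlabel("cumulative pilocarpine dose (mg/kg)")
        ax.set_ylabel("fraction not in SE")
        return ax


def km_dose_to_se(records: Sequence[DoseToSERecord]) -> KaplanMeierDoseCurve:
    """Kaplan–Meier curve of pilocarpine dose required to trigger SE."""
    return KaplanMeierDoseCurve(records)
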