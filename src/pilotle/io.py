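"""File readers/writers and run configuration.

Formats (all plain text):

* **Diary CSV** — columns ``animal_id, day, n_seizures``, one row per
  animal-day.  Day gaps are an error unless ``fill_zeros`` is set.  An
  optional metadata CSV (``animal_id, se_day, recording_start,
  recording_end``) attaches the SE day and recording bounds.
* **EEG CSV** — a comment header ``# sampling_rate_hz=<float>`` followed
  by columns ``time_s, amplitude_uv``.  EDF files are read through
  :mod:`mne` when available (single channel selected by index or label).
* **Dose-record CSV** — columns ``animal_id, cumulative_dose_mg_per_kg,
  reached_se``.
* **Config YAML** — PK parameters, protocol, detector and diary
  thresholds, seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .diary import DoseToSERecord, SeizureDiary
from .eeg import DetectorParams, EEGTrace
from .exceptions import FormatError, InputError
from .pk import PKParams, TargetWindow

__all__ = [
    "RunConfig",
    "read_diary_csv",
    "write_diary_csv",
    "read_dose_records_csv",
    "write_dose_records_csv",
    "read_eeg",
    "write_eeg_csv",
    "load_config",
]

PathLike = Union[str, os.PathLike]


def read_diary_csv(
    path: PathLike,
    fill_zeros: bool = False,
    meta_path: Optional[PathLike] = None,
) -> list[SeizureDiary]:
    """Load per-animal seizure diaries from CSV.

    Raises :class:`FormatError` naming the offending row for missing
    columns, negative counts, duplicate animal-days, or (without
    ``fill_zeros``) day gaps.
    """
    df = pd.read_csv(path)
    required = {"animal_id", "day", "n_seizures"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    meta = {}
    if meta_path is not None:
        mdf = pd.read_csv(meta_path)
        if "animal_id" not in mdf.columns:
            raise FormatError(f"{meta_path}: missing column animal_id")
        for _, row in mdf.iterrows():
            meta[str(row["animal_id"])] = row
    diaries = []
    for animal_id, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy(dtype=int)
        counts = grp["n_seizures"].to_numpy()
        dup = pd.Series(days).duplicated()
        if dup.any():
            raise FormatError(
                f"{path}: duplicate rows for animal {animal_id} day "
                f"{days[dup.to_numpy()][0]}"
            )
        if np.any(counts < 0):
            bad_day = days[counts < 0][0]
            raise FormatError(
                f"{path}: negative count for animal {animal_id} day {bad_day}"
            )
        row = meta.get(str(animal_id))
        start = int(row["recording_start"]) if row is not None and "recording_start" in row and pd.notna(row.get("recording_start")) else int(days[0])
        end = int(row["recording_end"]) if row is not None and "recording_end" in row and pd.notna(row.get("recording_end")) else int(days[-1])
        full = np.arange(start, end + 1)
        gaps = sorted(set(full.tolist()) - set(days.tolist()))
        if gaps and not fill_zeros:
            raise FormatError(
                f"{path}: day gaps for animal {animal_id}: missing day {gaps[0]}"
                + (f" (+{len(gaps) - 1} more)" if len(gaps) > 1 else "")
            )
        series = np.zeros(len(full), dtype=int)
        series[np.searchsorted(full, days)] = counts.astype(int)
        se_day = None
        if row is not None and "se_day" in row and pd.notna(row.get("se_day")):
            se_day = int(row["se_day"])
        diaries.append(
            SeizureDiary(
                animal_id=str(animal_id),
                counts=series,
                recording_start=start,
                se_day=se_day,
            )
        )
    return diaries


def write_diary_csv(diaries: Sequence[SeizureDiary], path: PathLike) -> None:
    rows = [
        {"animal_id": d.animal_id, "day": int(day), "n_seizures": int(c)}
        for d in diaries
        for day, c in zip(d.days, d.counts)
    ]
    pd.DataFrame(rows, columns=["animal_id", "day", "n_seizures"]).to_csv(
        path, index=False
    )


def read_dose_records_csv(path: PathLike) -> list[DoseToSERecord]:
    df = pd.read_csv(path)
    required = {"animal_id", "cumulative_dose_mg_per_kg", "reached_se"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        DoseToSERecord(
            animal_id=str(r["animal_id"]),
            cumulative_dose=float(r["cumulative_dose_mg_per_kg"]),
            reached_se=bool(r["reached_se"]),
        )
        for _, r in df.iterrows()
    ]


def write_dose_records_csv(records: Sequence[DoseToSERecord], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "cumulative_dose_mg_per_kg": r.cumulative_dose,
                "reached_se": r.reached_se,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


_EEG_HEADER_PREFIX = "# sampling_rate_hz="


def write_eeg_csv(trace: EEGTrace, path: PathLike) -> None:
    """Two-column EEG CSV with a sampling-rate comment header."""
    with open(path, "w") as fh:
        fh.write(f"{_EEG_HEADER_PREFIX}{trace.sampling_rate!r}\n")
        fh.write("time_s,amplitude_uv\n")
        np.savetxt(
            fh,
            np.column_stack([trace.times(), trace.samples]),
            fmt="%.9g",
            delimiter=",",
        )


def _read_eeg_csv(path: PathLike) -> EEGTrace:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith(_EEG_HEADER_PREFIX):
            raise FormatError(
                f"{path}: line 1 must declare '{_EEG_HEADER_PREFIX}<Hz>', got {first!r}"
            )
        try:
            fs = float(first[len(_EEG_HEADER_PREFIX):])
        except ValueError as exc:
            raise FormatError(f"{path}: unparseable sampling rate in {first!r}") from exc
        df = pd.read_csv(fh)
    for col in ("time_s", "amplitude_uv"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    t = df["time_s"].to_numpy(dtype=float)
    return EEGTrace(
        samples=df["amplitude_uv"].to_numpy(dtype=float),
        sampling_rate=fs,
        t0=float(t[0]) if len(t) else 0.0,
    )


def _read_eeg_edf(path: PathLike, channel: Union[int, str]) -> EEGTrace:
    try:
        from mne.io import read_raw_edf
    except ImportError as exc:  # pragma: no cover
        raise InputError(
            "EDF support requires the optional 'mne' dependency; "
            "install pilotle[edf] or supply CSV input"
        ) from exc
    raw = read_raw_edf(path, preload=True, verbose="error")
    names = raw.ch_names
    if isinstance(channel, int):
        if not (0 <= channel < len(names)):
            raise InputError(
                f"{path}: channel index {channel} out of range; available: {names}"
            )
        name = names[channel]
    else:
        if channel not in names:
            raise InputError(
                f"{path}: unknown channel {channel!r}; available: {names}"
            )
        name = channel
    data = raw.get_data(picks=[name])[0] * 1e6  # volts -> microvolts
    return EEGTrace(samples=data, sampling_rate=float(raw.info["sfreq"]), t0=0.0)


def read_eeg(path: PathLike, channel: Union[int, str] = 0) -> EEGTrace:
    """Read a single-channel EEG trace from CSV or EDF."""
    suffix = Path(path).suffix.lower()
    if suffix == ".edf":
        return _read_eeg_edf(path, channel)
    return _read_eeg_csv(path)


@dataclass
class RunConfig:
    """Configuration for the end-to-end pipeline."""

    pk_params: PKParams = field(default_factory=PKParams)
    detector_params: DetectorParams = field(default_factory=DetectorParams)
    target_window: TargetWindow = field(default_factory=TargetWindow)
    initial_dose: float = 166.0
    n_boosters: int = 1
    booster_interval: float = 45.0
    scopolamine_lead: float = 20.0
    high_threshold: int = 7
    min_free_run: int = 5
    epilepsy_min: int = 2
    seed: int = 0
    out_dir: str = "pilotle-out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("high_threshold", "min_free_run", "epilepsy_min"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")


def load_config(path: PathLike) -> RunConfig:
    """Load a YAML config; unknown keys are an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a mapping")
    kwargs = dict(raw)
    if "pk_params" in kwargs:
        kwargs["pk_params"] = PKParams(**kwargs["pk_params"])
    if "detector_params" in kwargs:
        kwargs["detector_params"] = DetectorParams(**kwargs["detector_params"])
    if "target_window" in kwargs:
        kwargs["target_window"] = TargetWindow(**kwargs["target_window"])
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(kwargs) - valid
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**kwargs)
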