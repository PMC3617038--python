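"""File formats and clock alignment.

CSV is the interchange format throughout: comma-delimited, UTF-8, header row
mandatory in the package's native files. Timestamps are wall-clock local at
minute resolution; epochs are left-closed ([t, t+60 s)). Two epoch-file
dialects are read:

* the native dialect — ``timestamp,counts`` rows with ISO minute timestamps;
* a device-export dialect — a dashed ``Key: value`` header block (start
  time/date, epoch period, subject) followed by one count per line, in the
  spirit of ActiLife exports. The layout is versioned here, not claimed
  bit-faithful to any ActiLife release.

Readers raise :class:`~relcal.exceptions.ParseError` naming the offending
line. All writers round-trip losslessly through their readers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ParseError
from .types import (
    CalibrationSession,
    CalibrationStage,
    CutpointPair,
    EpochSeries,
    SubjectProfile,
)

_TS_FMT = "%Y-%m-%d %H:%M:%S"
_DEVICE_BANNER = "------------ relcal epoch export v1 ------------"
_DEVICE_END = "-----------------------------------------------"


def _parse_timestamp(text: str, line: int) -> datetime:
    try:
        return datetime.strptime(text.strip(), _TS_FMT)
    except ValueError as err:
        raise ParseError(f"bad timestamp {text.strip()!r}", line) from err


def _parse_count(text: str, line: int) -> float:
    try:
        value = float(text)
    except ValueError as err:
        raise ParseError(f"non-numeric counts {text.strip()!r}", line) from err
    if not math.isfinite(value) or value < 0:
        raise ParseError(f"negative or non-finite counts {text.strip()!r}", line)
    return value


def _read_native_epochs(lines: list[str], subject_id: str) -> EpochSeries:
    header = [h.strip().lower() for h in lines[0].split(",")]
    if header[:2] != ["timestamp", "counts"]:
        raise ParseError(f"expected header 'timestamp,counts', got {lines[0]!r}", 1)
    times: list[datetime] = []
    counts: list[float] = []
    for i, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split(",")
        if len(parts) < 2:
            raise ParseError("expected 'timestamp,counts'", i)
        times.append(_parse_timestamp(parts[0], i))
        counts.append(_parse_count(parts[1], i))
    if not times:
        raise ParseError("no epoch rows", len(lines))
    deltas = {
        (b - a).total_seconds() for a, b in zip(times, times[1:])
    }
    if len(times) > 1:
        if len(deltas) != 1:
            bad = next(
                i + 2
                for i, (a, b) in enumerate(zip(times, times[1:]))
                if (b - a).total_seconds() != (times[1] - times[0]).total_seconds()
            )
            raise ParseError("irregular epoch spacing", bad)
        epoch_s = int(deltas.pop())
    else:
        epoch_s = 60
    return EpochSeries(subject_id, times[0], np.array(counts), epoch_s)


def _read_device_epochs(lines: list[str], subject_id: str) -> EpochSeries:
    meta: dict[str, str] = {}
    data_start = None
    for i, raw in enumerate(lines[1:], start=2):
        stripped = raw.strip()
        if stripped.startswith("---"):
            data_start = i + 1
            break
        if ": " not in stripped:
            raise ParseError(f"malformed header line {stripped!r}", i)
        # keys may themselves contain colons, e.g. 'Epoch Period (hh:mm:ss)'
        key, _, value = stripped.partition(": ")
        meta[key.strip().lower()] = value.strip()
    if data_start is None:
        raise ParseError("header block never closed by a dashed line", len(lines))
    for key in ("start time", "start date", "epoch period (hh:mm:ss)"):
        if key not in meta:
            raise ParseError(f"missing header field {key!r}", data_start - 1)
    try:
        start = datetime.strptime(
            meta["start date"] + " " + meta["start time"], "%m/%d/%Y %H:%M:%S"
        )
    except ValueError as err:
        raise ParseError(f"bad start date/time in header: {err}", data_start - 1) from err
    h, m, s = (int(x) for x in meta["epoch period (hh:mm:ss)"].split(":"))
    epoch_s = 3600 * h + 60 * m + s
    counts = [
        _parse_count(raw, i)
        for i, raw in enumerate(lines[data_start - 1:], start=data_start)
        if raw.strip()
    ]
    if not counts:
        raise ParseError("no epoch rows after header block", len(lines))
    return EpochSeries(
        meta.get("subject", subject_id), start, np.array(counts), epoch_s
    )


def read_epoch_csv(path: str | Path, subject_id: str | None = None) -> EpochSeries:
    """Read an epoch-count file, auto-detecting the dialect."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError("empty file", 1)
    sid = subject_id or path.stem
    if lines[0].startswith("---"):
        return _read_device_epochs(lines, sid)
    return _read_native_epochs(lines, sid)


def write_epoch_csv(
    series: EpochSeries, path: str | Path, dialect: str = "native"
) -> None:
    """Write an epoch series in the native or device-export dialect."""
    path = Path(path)
    step = timedelta(seconds=series.epoch_length_s)
    if dialect == "native":
        rows = ["timestamp,counts"]
        t = series.start_time
        for c in series.counts:
            rows.append(f"{t.strftime(_TS_FMT)},{c:g}")
            t += step
    elif dialect == "device":
        period = (
            f"{series.epoch_length_s // 3600:02d}:"
            f"{series.epoch_length_s % 3600 // 60:02d}:"
            f"{series.epoch_length_s % 60:02d}"
        )
        rows = [
            _DEVICE_BANNER,
            f"Subject: {series.subject_id}",
            f"Start Time: {series.start_time.strftime('%H:%M:%S')}",
            f"Start Date: {series.start_time.strftime('%m/%d/%Y')}",
            f"Epoch Period (hh:mm:ss): {period}",
            _DEVICE_END,
        ] + [f"{c:g}" for c in series.counts]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


@dataclass
class HeartRateLog:
    """A minute-level HR series plus any gaps in its minute grid."""

    times: list[datetime]
    hr: np.ndarray
    gaps: list[datetime]

    def to_series(self) -> pd.Series:
        return pd.Series(self.hr, index=pd.DatetimeIndex(self.times), name="hr")


def read_hr_log(path: str | Path) -> HeartRateLog:
    """Read a ``timestamp,hr`` CSV; one value per minute, gaps reported."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError("empty file", 1)
    header = [h.strip().lower() for h in lines[0].split(",")]
    if header[:2] != ["timestamp", "hr"]:
        raise ParseError(f"expected header 'timestamp,hr', got {lines[0]!r}", 1)
    times: list[datetime] = []
    hr: list[float] = []
    seen: set[datetime] = set()
    for i, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split(",")
        if len(parts) < 2:
            raise ParseError("expected 'timestamp,hr'", i)
        t = _parse_timestamp(parts[0], i)
        if t in seen:
            raise ParseError(f"duplicate timestamp {parts[0].strip()!r}", i)
        seen.add(t)
        try:
            v = float(parts[1])
        except ValueError as err:
            raise ParseError(f"non-numeric heart rate {parts[1].strip()!r}", i) from err
        times.append(t)
        hr.append(v)
    if not times:
        raise ParseError("no heart-rate rows", len(lines))
    order = np.argsort([t.timestamp() for t in times])
    times = [times[i] for i in order]
    hr_arr = np.array(hr)[order]
    gaps = []
    t = times[0]
    present = set(times)
    while t <= times[-1]:
        if t not in present:
            gaps.append(t)
        t += timedelta(minutes=1)
    return HeartRateLog(times, hr_arr, gaps)


def write_hr_log(times: Sequence[datetime], hr: Sequence[float], path: str | Path) -> None:
    rows = ["timestamp,hr"] + [
        f"{t.strftime(_TS_FMT)},{v:g}" for t, v in zip(times, hr)
    ]
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


@dataclass
class AlignedSeries:
    """HR and count series trimmed to a common minute grid."""

    times: list[datetime]
    hr: np.ndarray
    counts: np.ndarray
    offset_applied_s: float


def align_to_test_clock(
    hr_log: HeartRateLog, counts: EpochSeries, offset_s: float = 0.0
) -> AlignedSeries:
    """Shift the accelerometer clock by ``offset_s`` seconds onto the test
    clock and trim both series to their overlapping minutes.

    A positive offset means the accelerometer clock lags the test clock.
    """
    if counts.epoch_length_s != 60:
        raise AlignmentError("alignment requires 60 s epochs")
    step = timedelta(seconds=counts.epoch_length_s)
    shifted_start = counts.start_time + timedelta(seconds=offset_s)
    count_times = [shifted_start + i * step for i in range(len(counts.counts))]
    count_map = dict(zip(count_times, counts.counts))
    hr_map = dict(zip(hr_log.times, hr_log.hr))
    common = sorted(set(count_map) & set(hr_map))
    if not common:
        raise AlignmentError("no overlapping minutes after applying the offset")
    return AlignedSeries(
        times=common,
        hr=np.array([hr_map[t] for t in common]),
        counts=np.array([count_map[t] for t in common]),
        offset_applied_s=offset_s,
    )


def session_from_aligned(
    profile: SubjectProfile,
    aligned: AlignedSeries,
    speeds_kph: Sequence[float] = (3.2, 4.8, 6.4, 8.0, 9.6),
    stage_minutes: int = 5,
) -> CalibrationSession:
    """Chunk an aligned minute series into protocol stages in order.

    Minutes are assigned to stages sequentially from the start of the
    aligned record; a trailing partial stage is kept (calibration drops it
    if it has fewer than two minutes).
    """
    n = len(aligned.times)
    stages: list[CalibrationStage] = []
    for k, speed in enumerate(speeds_kph):
        lo, hi = k * stage_minutes, min((k + 1) * stage_minutes, n)
        if lo >= n:
            break
        stages.append(
            CalibrationStage(
                speed,
                list(aligned.hr[lo:hi]),
                list(aligned.counts[lo:hi]),
                stage_minutes,
            )
        )
    truncated = n < stage_minutes * len(speeds_kph)
    return CalibrationSession(
        profile, stages, truncated, "record shorter than protocol" if truncated else ""
    )


# ---------------------------------------------------------------------------
# tabular formats

PROFILE_COLUMNS = [
    "subject_id", "age", "sex", "height_cm", "weight_kg",
    "resting_hr", "max_hr", "vo2max",
]


def read_profiles_csv(path: str | Path) -> list[SubjectProfile]:
    df = pd.read_csv(path)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"profile table missing columns {missing}", 1)
    return [
        SubjectProfile(
            subject_id=str(r.subject_id), age=float(r.age), sex=str(r.sex),
            height_cm=float(r.height_cm), weight_kg=float(r.weight_kg),
            resting_hr=float(r.resting_hr), max_hr=float(r.max_hr),
            vo2max=float(r.vo2max),
        )
        for r in df.itertuples()
    ]


def write_profiles_csv(profiles: Sequence[SubjectProfile], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": p.subject_id, "age": p.age, "sex": p.sex,
                "height_cm": p.height_cm, "weight_kg": p.weight_kg,
                "resting_hr": p.resting_hr, "max_hr": p.max_hr, "vo2max": p.vo2max,
            }
            for p in profiles
        ]
    ).to_csv(path, index=False)


CUTPOINT_COLUMNS = [
    "subject_id", "slope", "intercept", "orientation", "r_squared",
    "moderate_cut", "vigorous_cut",
]


def write_cutpoints_csv(rows: Sequence[dict], path: str | Path) -> None:
    """Write a cutpoint table (one row per subject; see CUTPOINT_COLUMNS)."""
    pd.DataFrame(rows, columns=CUTPOINT_COLUMNS).to_csv(path, index=False)


def read_cutpoints_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", "moderate_cut", "vigorous_cut") if c not in df.columns]
    if missing:
        raise ParseError(f"cutpoint table missing columns {missing}", 1)
    return df
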