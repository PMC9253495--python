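"""Data model, CSV readers/writers and preprocessing for telemonitored cohorts.

The study design monitors each subject for about a week with a chest-worn
sensor recording per-minute physical activity (PA, arbitrary non-negative
acceleration units) and chest surface temperature (degC).  A self-reported
diary gives work and sleep intervals; a questionnaire gives shift type,
age, chronotype score, years of past night work and sleep times.

Time is handled as naive local clock time; daylight-saving transitions are
out of scope for one-week monitoring windows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

ShiftType = Literal["DS", "NS"]

__all__ = [
    "MinuteSeries",
    "Diary",
    "SubjectMeta",
    "DayPartition",
    "Subject",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "resample",
    "sqrt_pa",
    "partition_days",
    "eligibility",
    "sleep_debt",
]


class CohortDataError(ValueError):
    """Malformed or inconsistent cohort input."""


class EligibilityError(ValueError):
    """Monitoring span cannot satisfy the >=1 workday + >=1 free day rule."""


@dataclass
class MinuteSeries:
    """Per-minute PA and temperature on a strict 1-minute grid.

    Missing values are encoded as NaN, never as 0.  ``temp`` may be None
    when the cohort file carries no temperature column; temperature-based
    stages must refuse such series.
    """

    subject_id: str
    timestamps: pd.DatetimeIndex
    pa: np.ndarray
    temp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.pa = np.asarray(self.pa, dtype=float)
        if self.temp is not None:
            self.temp = np.asarray(self.temp, dtype=float)
        n = len(self.timestamps)
        if len(self.pa) != n or (self.temp is not None and len(self.temp) != n):
            raise CohortDataError(f"{self.subject_id}: channel lengths differ from grid")
        if n > 1:
            deltas = np.diff(self.timestamps.asi8)
            if not np.all(deltas == 60 * 10**9):
                bad = int(np.flatnonzero(deltas != 60 * 10**9)[0])
                raise CohortDataError(
                    f"{self.subject_id}: grid spacing is not 1 minute at row {bad + 1}"
                )
        with np.errstate(invalid="ignore"):
            if np.any(self.pa[~np.isnan(self.pa)] < 0):
                raise CohortDataError(f"{self.subject_id}: negative PA values")

    @property
    def n_minutes(self) -> int:
        return len(self.timestamps)

    @property
    def has_temp(self) -> bool:
        return self.temp is not None

    def to_frame(self) -> pd.DataFrame:
        data = {"pa": self.pa}
        if self.temp is not None:
            data["temp"] = self.temp
        return pd.DataFrame(data, index=self.timestamps)


@dataclass
class Diary:
    """Self-reported work and sleep intervals, each a (start, end) pair."""

    work_intervals: list[tuple[datetime, datetime]] = field(default_factory=list)
    sleep_intervals: list[tuple[datetime, datetime]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("work_intervals", "sleep_intervals"):
            ivs = sorted(getattr(self, name))
            for s, e in ivs:
                if e <= s:
                    raise CohortDataError(f"{name}: interval end {e} not after start {s}")
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise CohortDataError(f"{name}: overlapping intervals at {s2}")
            setattr(self, name, ivs)


@dataclass
class SubjectMeta:
    subject_id: str
    shift_type: ShiftType
    age: float
    chronotype_score: float
    years_night_work: float
    sex: str = "F"
    ideal_tst_h: float | None = None
    reported_tst_h: float | None = None

    def __post_init__(self) -> None:
        if self.shift_type not in ("DS", "NS"):
            raise CohortDataError(f"unknown shift type {self.shift_type!r}")
        if not 16 <= self.chronotype_score <= 86:
            raise CohortDataError(
                f"{self.subject_id}: chronotype score {self.chronotype_score} outside [16, 86]"
            )
        if self.years_night_work < 0:
            raise CohortDataError(f"{self.subject_id}: negative years of night work")


@dataclass
class DayPartition:
    """Work/free labelling of consecutive 24-h spans covering the monitoring period.

    ``anchor`` is the clock time at which each 24-h day starts: midnight for
    day shifters, the night-shift start (20:00 or 21:00) for night shifters.
    """

    day_starts: list[datetime]
    labels: list[str]  # "workday" | "freeday"
    anchor: time

    def __post_init__(self) -> None:
        if len(self.day_starts) != len(self.labels):
            raise CohortDataError("day_starts and labels length mismatch")
        for s1, s2 in zip(self.day_starts, self.day_starts[1:]):
            if s2 - s1 != timedelta(days=1):
                raise CohortDataError("day partition has gaps or overlaps")
        for lab in self.labels:
            if lab not in ("workday", "freeday"):
                raise CohortDataError(f"unknown day label {lab!r}")

    @property
    def n_work(self) -> int:
        return sum(l == "workday" for l in self.labels)

    @property
    def n_free(self) -> int:
        return sum(l == "freeday" for l in self.labels)

    def day_type_of(self, timestamps: pd.DatetimeIndex) -> np.ndarray:
        """Label each timestamp 'workday'/'freeday' ('' outside the partition)."""
        out = np.full(len(timestamps), "", dtype=object)
        for start, lab in zip(self.day_starts, self.labels):
            end = start + timedelta(days=1)
            mask = (timestamps >= start) & (timestamps < end)
            out[np.asarray(mask)] = lab
        return out


@dataclass
class Subject:
    series: MinuteSeries
    diary: Diary
    meta: SubjectMeta

    @property
    def subject_id(self) -> str:
        return self.series.subject_id


@dataclass
class Cohort:
    subjects: dict[str, Subject]

    def __iter__(self):
        return iter(self.subjects.values())

    def __len__(self) -> int:
        return len(self.subjects)

    def __getitem__(self, sid: str) -> Subject:
        return self.subjects[sid]

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects)


# ---------------------------------------------------------------------------
# CSV dialect
#
# series CSV : subject_id,timestamp,pa,temp     (empty cell = missing)
# diary CSV  : subject_id,kind{work|sleep},start,end
# meta CSV   : one row per subject
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, series_path, diary_path, meta_path) -> None:
    srows = []
    for subj in cohort:
        frame = subj.series.to_frame().reset_index(names="timestamp")
        frame.insert(0, "subject_id", subj.subject_id)
        if "temp" not in frame:
            frame["temp"] = np.nan
        srows.append(frame)
    pd.concat(srows, ignore_index=True).to_csv(series_path, index=False)

    drows = []
    for subj in cohort:
        for kind, ivs in (("work", subj.diary.work_intervals), ("sleep", subj.diary.sleep_intervals)):
            for s, e in ivs:
                drows.append({"subject_id": subj.subject_id, "kind": kind, "start": s, "end": e})
    pd.DataFrame(drows, columns=["subject_id", "kind", "start", "end"]).to_csv(diary_path, index=False)

    mrows = [dataclasses.asdict(subj.meta) for subj in cohort]
    pd.DataFrame(mrows).to_csv(meta_path, index=False)


def read_cohort(series_path, diary_path, meta_path) -> Cohort:
    """Load and validate a cohort from the three CSV files.

    Duplicate (subject, timestamp) rows and non-monotone timestamps are hard
    errors reported with the offending row number.
    """
    sdf = pd.read_csv(series_path, parse_dates=["timestamp"])
    ddf = pd.read_csv(diary_path, parse_dates=["start", "end"])
    mdf = pd.read_csv(meta_path)
    has_temp = "temp" in sdf.columns and sdf["temp"].notna().any()

    subjects: dict[str, Subject] = {}
    for sid, grp in sdf.groupby("subject_id", sort=True):
        sid = str(sid)
        dup = grp["timestamp"].duplicated()
        if dup.any():
            row = int(grp.index[dup][0]) + 2  # header + 0-based
            raise CohortDataError(f"{sid}: duplicated minute at series row {row}")
        if not grp["timestamp"].is_monotonic_increasing:
            row = int(grp.index[grp["timestamp"].diff() < pd.Timedelta(0)][0]) + 2
            raise CohortDataError(f"{sid}: non-monotone timestamp at series row {row}")
        series = MinuteSeries(
            subject_id=sid,
            timestamps=pd.DatetimeIndex(grp["timestamp"]),
            pa=grp["pa"].to_numpy(dtype=float),
            temp=grp["temp"].to_numpy(dtype=float) if has_temp else None,
        )
        dsub = ddf[ddf["subject_id"].astype(str) == sid]
        diary = Diary(
            work_intervals=[
                (s.to_pydatetime(), e.to_pydatetime())
                for s, e in zip(dsub[dsub["kind"] == "work"]["start"], dsub[dsub["kind"] == "work"]["end"])
            ],
            sleep_intervals=[
                (s.to_pydatetime(), e.to_pydatetime())
                for s, e in zip(dsub[dsub["kind"] == "sleep"]["start"], dsub[dsub["kind"] == "sleep"]["end"])
            ],
        )
        mrow = mdf[mdf["subject_id"].astype(str) == sid]
        if len(mrow) != 1:
            raise CohortDataError(f"{sid}: expected exactly one metadata row, got {len(mrow)}")
        m = mrow.iloc[0]
        meta = SubjectMeta(
            subject_id=sid,
            shift_type=str(m["shift_type"]),
            age=float(m["age"]),
            chronotype_score=float(m["chronotype_score"]),
            years_night_work=float(m["years_night_work"]),
            sex=str(m.get("sex", "F")),
            ideal_tst_h=float(m["ideal_tst_h"]) if pd.notna(m.get("ideal_tst_h")) else None,
            reported_tst_h=float(m["reported_tst_h"]) if pd.notna(m.get("reported_tst_h")) else None,
        )
        subjects[sid] = Subject(series=series, diary=diary, meta=meta)
    return Cohort(subjects=subjects)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

_BIN_MINUTES = {"5min": 5, "hourly": 60}


def resample(series: MinuteSeries, bin: str = "5min") -> pd.DataFrame:
    """Clock-aligned binned means (5-min for PA modelling, hourly for spectra).

    A bin is the mean of its observed minutes and missing only when every
    constituent minute is missing.  Bin boundaries align to the clock
    (…:00, :05, …), so the first/last bins may be partial.
    """
    if bin not in _BIN_MINUTES:
        raise ValueError(f"bin must be one of {sorted(_BIN_MINUTES)}")
    frame = series.to_frame()
    # mean() skips NaN; all-NaN bins yield NaN
    return frame.resample(f"{_BIN_MINUTES[bin]}min").mean()


def sqrt_pa(values: pd.Series | np.ndarray) -> np.ndarray:
    """Square-root transform of activity, the scale on which the Gaussian
    emission model is fitted.  Missing values propagate."""
    arr = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(arr[~np.isnan(arr)] < 0):
            raise ValueError("negative activity values cannot be sqrt-transformed")
    return np.sqrt(arr)


def partition_days(
    diary: Diary,
    meta: SubjectMeta,
    span: tuple[datetime, datetime],
    default_ns_anchor: time = time(21, 0),
) -> DayPartition:
    """Label every 24-h window of the monitoring span workday or free day.

    Day shifters' days are anchored at midnight; night shifters' days start
    when the night shift begins (diary-derived, 21:00 by default when the
    diary is ambiguous).  A day is a workday iff a diary work interval
    starts within it.
    """
    start, end = span
    if meta.shift_type == "DS":
        anchor = time(0, 0)
    else:
        anchor = default_ns_anchor
        starts = [s.time() for s, _ in diary.work_intervals]
        if starts:
            # night shifts begin 20:00 or 21:00; trust the diary's mode
            cands = [t for t in starts if t in (time(20, 0), time(21, 0))]
            if cands:
                anchor = max(set(cands), key=cands.count)

    first = datetime.combine(start.date(), anchor)
    if first > start:
        first -= timedelta(days=1)
    day_starts: list[datetime] = []
    cur = first
    while cur < end:
        day_starts.append(cur)
        cur += timedelta(days=1)

    labels = []
    for ds in day_starts:
        de = ds + timedelta(days=1)
        is_work = any(ds <= s < de for s, _ in diary.work_intervals)
        labels.append("workday" if is_work else "freeday")

    if meta.shift_type == "NS" and not diary.work_intervals:
        import warnings

        warnings.warn(f"{meta.subject_id}: NS diary has no work intervals; labelling all days free")
    return DayPartition(day_starts=day_starts, labels=labels, anchor=anchor)


def eligibility(partition: DayPartition) -> tuple[bool, str]:
    """At least one workday and one free day are required so that recovery
    from work-schedule disruption can be assessed."""
    if partition.n_work == 0:
        return False, "no workday in monitoring span"
    if partition.n_free == 0:
        return False, "no free day in monitoring span"
    return True, "eligible"


def sleep_debt(meta: SubjectMeta) -> float | None:
    """Self-reported ideal total sleep time minus reported total sleep time
    (hours; may be negative)."""
    if meta.ideal_tst_h is None or meta.reported_tst_h is None:
        return None
    return meta.ideal_tst_h - meta.reported_tst_h
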