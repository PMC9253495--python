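"""Synthetic shift-worker cohorts with the statistical structure the
analysis assumes.

The study's telemonitored data are available only on request, so every
downstream stage is exercised on simulated cohorts: day shifters (DS,
alternating 07:00-14:00 morning and 14:00-21:00 afternoon shifts) and
night shifters (NS, 21:00-07:00), monitored for about a week with at
least one work day and one free day each.

Activity is generated from the same model class the analysis fits: a
3-state latent Markov chain on the 5-minute grid whose transition logits
carry a 24-h sinusoid (phase per day type), with Gaussian emissions on the
square-root scale that are squared into activity units.  Temperature is a
sum of 24/12/8-h harmonics around ~35 degC plus an ultradian sinusoid
active only during rest, and white noise.  Missingness is block-structured
(geometric gap lengths) because telemetry dropouts are bursty.

Activity units are arbitrary non-negative accelerometry counts; the sensor
scale is not part of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, time, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import (
    Cohort,
    Diary,
    EligibilityError,
    MinuteSeries,
    Subject,
    SubjectMeta,
    partition_days,
)

__all__ = [
    "ScheduleSpec",
    "GenParams",
    "SimulatedActivity",
    "default_params",
    "make_schedule",
    "simulate_activity",
    "simulate_temperature",
    "inject_missingness",
    "generate_cohort",
]

_EPOCH = datetime(2021, 3, 1)  # nominal local-time origin of monitoring
_DAY_MIN = 1440


@dataclass
class ScheduleSpec:
    """Shift schedule over the monitoring period.

    ``shift_intervals[d]`` is the (start, end) clock time of day ``d``'s
    shift (None on free days); NS shifts end past midnight of the next day.
    """

    shift_type: str  # "DS" | "NS"
    n_days: int
    work_day_flags: list[bool]
    shift_intervals: list[tuple[time, time] | None]
    start: datetime = _EPOCH

    def __post_init__(self) -> None:
        if self.n_days < 2:
            raise EligibilityError(
                "n_days < 2 cannot satisfy >=1 workday and >=1 free day"
            )
        if len(self.work_day_flags) != self.n_days or len(self.shift_intervals) != self.n_days:
            raise ValueError("per-day fields must have length n_days")
        if not any(self.work_day_flags) or all(self.work_day_flags):
            raise EligibilityError("schedule needs at least 1 work day and 1 free day")

    @property
    def n_minutes(self) -> int:
        return self.n_days * _DAY_MIN

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n_minutes, freq="min")

    def work_intervals(self) -> list[tuple[datetime, datetime]]:
        out = []
        for d, (flag, iv) in enumerate(zip(self.work_day_flags, self.shift_intervals)):
            if not flag or iv is None:
                continue
            s, e = iv
            start = datetime.combine((self.start + timedelta(days=d)).date(), s)
            end = datetime.combine((self.start + timedelta(days=d)).date(), e)
            if end <= start:  # night shift spans midnight
                end += timedelta(days=1)
            out.append((start, end))
        return out


def make_schedule(
    shift_type: str,
    n_days: int = 7,
    work_day_flags: Sequence[bool] | None = None,
    start: datetime = _EPOCH,
) -> ScheduleSpec:
    """Default schedule: work days first, the last two days free (one free
    day when n_days == 2).  DS alternate morning and afternoon shifts."""
    if n_days < 2:
        raise EligibilityError("n_days < 2 cannot satisfy >=1 workday and >=1 free day")
    if work_day_flags is None:
        n_free = 1 if n_days == 2 else 2
        work_day_flags = [True] * (n_days - n_free) + [False] * n_free
    flags = list(work_day_flags)
    intervals: list[tuple[time, time] | None] = []
    w = 0
    for flag in flags:
        if not flag:
            intervals.append(None)
        elif shift_type == "NS":
            intervals.append((time(21, 0), time(7, 0)))
        else:
            intervals.append((time(7, 0), time(14, 0)) if w % 2 == 0 else (time(14, 0), time(21, 0)))
            w += 1 if flag else 0
    return ScheduleSpec(shift_type=shift_type, n_days=n_days,
                        work_day_flags=flags, shift_intervals=intervals, start=start)


@dataclass
class GenParams:
    """Generator parameters; the transition structure mirrors the fitted
    model (per-row multinomial logits, self-transition as reference, one
    24-h harmonic whose phase is the acrophase of rest propensity).

    ``harmonic_amp[j]`` modulates row ``j``: it is added to the logit of
    entering rest and subtracted from the logits of leaving rest, so rest
    propensity peaks at the acrophase.  ``harmonic_amp_work`` (if set)
    replaces it on work days — small work-day amplitudes yield the
    fragmented, weakly rhythmic work-day rest typical of night shifters.
    """

    state_means: tuple[float, float, float] = (1.3, 4.0, 6.5)  # sqrt-PA scale
    state_sds: tuple[float, float, float] = (0.45, 0.9, 0.9)
    baseline_logits: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.0, -2.8, -4.6],
             [-3.9, 0.0, -1.5],
             [-4.6, -1.0, 0.0]]
        )
    )
    harmonic_amp: tuple[float, float, float] = (1.7, 2.6, 2.6)
    harmonic_amp_work: tuple[float, float, float] | None = None
    acrophase_work: float = 3.0  # clock hour of maximal rest propensity
    acrophase_free: float = 3.5
    temp_harmonics: tuple[tuple[float, float, float], ...] = (
        (24.0, 1.2, 4.0),  # (period h, amplitude degC, phase h)
        (12.0, 0.45, 2.0),
        (8.0, 0.15, 1.0),
    )
    ultradian_period_h: float = 2.2
    ultradian_amp: float = 0.35
    temp_offset: float = 35.0
    temp_noise_sd: float = 0.25
    missing_frac: float = 0.03
    mean_gap_min: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        m = self.state_means
        if not (m[0] < m[1] < m[2]):
            raise ValueError("state means must be strictly increasing")
        if any(s <= 0 for s in self.state_sds):
            raise ValueError("state sds must be positive")
        if not 0 <= self.missing_frac < 0.5:
            raise ValueError("missing_frac must be in [0, 0.5)")
        if not 0.5 <= self.ultradian_period_h <= 6:
            raise ValueError("ultradian_period_h must be in [0.5, 6] h")
        self.baseline_logits = np.asarray(self.baseline_logits, dtype=float)

    # -- transition structure -------------------------------------------------

    def _amp_matrix(self, day_type: str) -> np.ndarray:
        amp = self.harmonic_amp
        if day_type == "workday" and self.harmonic_amp_work is not None:
            amp = self.harmonic_amp_work
        A = np.zeros((3, 3))
        A[1, 0] = amp[1]   # entering rest from MA
        A[2, 0] = amp[2]   # entering rest from HA
        A[0, 1] = -amp[0]  # leaving rest suppressed at acrophase
        A[0, 2] = -amp[0]
        return A

    def transition_matrix(self, t_hours: float, day_type: str = "workday") -> np.ndarray:
        """Realized 5-min-step transition matrix at clock time ``t_hours``."""
        phase = self.acrophase_work if day_type == "workday" else self.acrophase_free
        mod = np.cos(2 * np.pi * (t_hours - phase) / 24.0)
        Z = self.baseline_logits + self._amp_matrix(day_type) * mod
        np.fill_diagonal(Z, 0.0)
        E = np.exp(Z - Z.max(axis=1, keepdims=True))
        return E / E.sum(axis=1, keepdims=True)

    def average_transition_matrix(self, day_type: str = "workday", n_grid: int = 288) -> np.ndarray:
        """Transition matrix averaged over the 24-h clock."""
        ts = np.arange(n_grid) * 24.0 / n_grid
        return np.mean([self.transition_matrix(t, day_type) for t in ts], axis=0)

    def stationary_occupancy(self, day_type: str = "workday") -> np.ndarray:
        """Stationary distribution of the clock-averaged chain — a coarse
        oracle for the long-run state occupancy."""
        P = self.average_transition_matrix(day_type)
        vals, vecs = np.linalg.eig(P.T)
        v = np.real(vecs[:, np.argmax(np.real(vals))])
        return v / v.sum()

    def periodic_occupancy(self, day_type: str = "workday",
                           n_cycles: int = 50) -> np.ndarray:
        """Time-averaged state occupancy of the periodically inhomogeneous
        chain: the marginal distribution is propagated through the 288-slot
        daily transition cycle until it locks onto the periodic fixed
        point, then averaged over the clock.  This is the exact numeric
        oracle for long-run empirical state fractions (the stationary
        distribution of the clock-averaged matrix is only approximate)."""
        Ps = np.stack([self.transition_matrix(s / 12.0, day_type) for s in range(288)])
        mu = np.full(3, 1.0 / 3.0)
        for _ in range(n_cycles):
            prev = mu.copy()
            for s in range(288):
                mu = mu @ Ps[s]
            if np.abs(mu - prev).max() < 1e-12:
                break
        # one more cycle, accumulating the per-slot marginals
        acc = np.zeros(3)
        for s in range(288):
            acc += mu
            mu = mu @ Ps[s]
        return acc / 288.0


def default_params(shift_type: str, seed: int = 0) -> GenParams:
    """Study-condition defaults per shift group.

    NS rest their work days after the night shift (acrophase ~11:00) with a
    weak, fragmented work-day rhythm; their free-day sleep is late-ish
    (~05:30).  NS ultradian sleep cycles are shorter than DS (1.8 vs 2.2 h,
    the group medians the analysis should reproduce in ordering)."""
    if shift_type == "NS":
        return GenParams(
            acrophase_work=11.0,
            acrophase_free=5.5,
            harmonic_amp_work=(0.7, 1.1, 1.1),
            ultradian_period_h=1.8,
            seed=seed,
        )
    return GenParams(acrophase_work=3.0, acrophase_free=3.5,
                     ultradian_period_h=2.2, seed=seed)


@dataclass
class SimulatedActivity:
    """Per-minute activity with its latent 5-min states and rest mask."""

    timestamps: pd.DatetimeIndex
    pa: np.ndarray  # per-minute activity (squared sqrt-scale emissions)
    states_5min: np.ndarray
    rest_mask: np.ndarray  # per-minute, True where latent state is rest
    day_labels_5min: np.ndarray


def _bin_day_labels(schedule: ScheduleSpec) -> tuple[np.ndarray, np.ndarray, Diary]:
    """Work/free label and clock hour per 5-min bin, via the same day
    partition the analysis applies."""
    diary = Diary(work_intervals=schedule.work_intervals())
    meta = SubjectMeta(subject_id="_sim", shift_type=schedule.shift_type,
                       age=40, chronotype_score=50, years_night_work=0)
    span = (schedule.start, schedule.start + timedelta(days=schedule.n_days))
    part = partition_days(diary, meta, span)
    bins = pd.date_range(schedule.start, periods=schedule.n_minutes // 5, freq="5min")
    labels = part.day_type_of(bins)
    hours = np.asarray(bins.hour + bins.minute / 60.0, dtype=float)
    return labels, hours, diary


def simulate_activity(schedule: ScheduleSpec, params: GenParams, seed: int) -> SimulatedActivity:
    """Sample the latent circadian-modulated 3-state chain on the 5-minute
    grid and emit per-minute activity (sqrt-scale Gaussian, squared)."""
    rng = np.random.default_rng(seed)
    labels, hours, _ = _bin_day_labels(schedule)
    n_bins = len(hours)
    means = np.asarray(params.state_means)
    sds = np.asarray(params.state_sds)

    # precompute the two diurnal transition-matrix profiles (288 clock slots)
    slot = (hours * 12).astype(int) % 288
    ts = np.arange(288) / 12.0
    P_by = {
        dt: np.stack([params.transition_matrix(t, dt) for t in ts])
        for dt in ("workday", "freeday")
    }

    states = np.empty(n_bins, dtype=int)
    pi0 = params.stationary_occupancy("freeday")
    states[0] = rng.choice(3, p=pi0)
    for t in range(1, n_bins):
        dt = labels[t - 1] if labels[t - 1] else "freeday"
        P = P_by[dt][slot[t - 1]]
        states[t] = rng.choice(3, p=P[states[t - 1]])

    v = rng.normal(means[states], sds[states])
    pa_bin = v**2
    pa = np.repeat(pa_bin, 5)
    rest_mask = np.repeat(states == 0, 5)
    return SimulatedActivity(
        timestamps=schedule.timestamps(), pa=pa, states_5min=states,
        rest_mask=rest_mask, day_labels_5min=np.asarray(labels, dtype=object),
    )


def simulate_temperature(
    schedule: ScheduleSpec, params: GenParams, rest_mask: np.ndarray, seed: int
) -> np.ndarray:
    """Per-minute chest temperature: configured harmonics on the clock, an
    ultradian sinusoid running only within rest episodes, white noise."""
    n = schedule.n_minutes
    if len(rest_mask) != n:
        raise ValueError("rest_mask must have one entry per minute")
    rng = np.random.default_rng(seed)
    t_h = np.arange(n) / 60.0
    clock_h = t_h % 24.0
    temp = np.full(n, params.temp_offset)
    for period, amp, phase in params.temp_harmonics:
        temp += amp * np.cos(2 * np.pi * (clock_h - phase) / period)
    # ultradian cycle restarts at each rest episode onset
    rm = np.asarray(rest_mask, dtype=bool)
    starts = np.flatnonzero(rm & ~np.r_[False, rm[:-1]])
    ends = np.flatnonzero(rm & ~np.r_[rm[1:], False]) + 1
    for s, e in zip(starts, ends):
        tt = (np.arange(e - s)) / 60.0
        temp[s:e] += params.ultradian_amp * np.cos(2 * np.pi * tt / params.ultradian_period_h)
    temp += rng.normal(0, params.temp_noise_sd, n)
    return temp


def inject_missingness(series: MinuteSeries, fraction: float, seed: int) -> MinuteSeries:
    """Mark contiguous gaps (geometric lengths, mean ~30 min) as missing in
    both channels until about ``fraction`` of minutes are removed."""
    if fraction >= 0.5:
        raise ValueError("refusing to remove >= 50% of the data")
    if fraction <= 0:
        return series
    rng = np.random.default_rng(seed)
    n = series.n_minutes
    target = int(round(fraction * n))
    missing = np.zeros(n, dtype=bool)
    p_geom = 1.0 / 30.0
    while missing.sum() < target:
        start = int(rng.integers(0, n))
        length = int(rng.geometric(p_geom))
        length = min(length, target - int(missing.sum()) + length // 2, n - start)
        missing[start: start + max(length, 1)] = True
    pa = series.pa.copy()
    pa[missing] = np.nan
    temp = None
    if series.temp is not None:
        temp = series.temp.copy()
        temp[missing] = np.nan
    return MinuteSeries(subject_id=series.subject_id, timestamps=series.timestamps,
                        pa=pa, temp=temp)


def generate_cohort(
    n_ds: int,
    n_ns: int,
    n_days: int = 7,
    params: GenParams | None = None,
    seed: int = 0,
) -> Cohort:
    """Generate a cohort of DS and NS subjects (series + diary + metadata).

    Per-subject generator parameters default to the shift group's study
    conditions (`default_params`); passing ``params`` overrides them for
    every subject.  Deterministic under ``seed``.
    """
    if n_ds < 0 or n_ns < 0:
        raise ValueError("cohort sizes must be non-negative")
    if n_days < 2:
        raise EligibilityError("n_days < 2 cannot satisfy >=1 workday and >=1 free day")
    rng = np.random.default_rng(seed)
    subjects = {}
    roster = [("DS", i) for i in range(n_ds)] + [("NS", i) for i in range(n_ns)]
    for shift, i in roster:
        sid = f"{shift}{i + 1:03d}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        p = params if params is not None else default_params(shift, seed=sub_seed)
        schedule = make_schedule(shift, n_days=n_days)
        act = simulate_activity(schedule, p, seed=sub_seed)
        temp = simulate_temperature(schedule, p, act.rest_mask, seed=sub_seed + 1)
        series = MinuteSeries(subject_id=sid, timestamps=act.timestamps,
                              pa=act.pa, temp=temp)
        series = inject_missingness(series, p.missing_frac, seed=sub_seed + 2)

        srng = np.random.default_rng(sub_seed + 3)
        age = float(np.round(srng.uniform(22, 62), 1))
        cs = int(srng.integers(24, 75))
        ynw = 0.0 if shift == "DS" else float(np.round(srng.uniform(0, 35), 1))
        ideal = float(np.round(srng.normal(8.0, 0.5), 1))
        debt = float(srng.normal(2.2 if shift == "NS" else 1.0, 0.6))
        meta = SubjectMeta(
            subject_id=sid, shift_type=shift, age=age, chronotype_score=cs,
            years_night_work=ynw, sex="F" if srng.uniform() < 0.95 else "M",
            ideal_tst_h=ideal, reported_tst_h=float(np.round(ideal - debt, 1)),
        )
        # diary: work intervals from the schedule; sleep intervals as the
        # nominal window around the acrophase on each day
        diary = Diary(work_intervals=schedule.work_intervals(),
                      sleep_intervals=_nominal_sleep(schedule, p))
        subjects[sid] = Subject(series=series, diary=diary, meta=meta)
    return Cohort(subjects=subjects)


def _nominal_sleep(schedule: ScheduleSpec, p: GenParams) -> list[tuple[datetime, datetime]]:
    out = []
    for d in range(schedule.n_days):
        phase = p.acrophase_work if schedule.work_day_flags[d] else p.acrophase_free
        centre = schedule.start + timedelta(days=d, hours=float(phase))
        out.append((centre - timedelta(hours=3.5), centre + timedelta(hours=3.5)))
    return out
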