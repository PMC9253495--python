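"""Period estimation for temperature and activity rhythms.

The period content of hourly chest-temperature series is estimated with a
missing-tolerant least-squares periodogram (Lomb-Scargle, mean-removed,
lightly Daniell-smoothed) over a 2-40 h period grid.  Peak periods get 90%
confidence intervals from a day-block bootstrap: whole 24-h blocks of the
series are resampled with replacement and the peak re-located near its
original period in each replicate.  The dominant period is the largest
peak; subjects are classified by the band it falls in (circadian ~24 h,
circa-12 h, circa-8 h, other, undetectable).

Ultradian (< 12 h) cyclicity during sleep is probed inside "rest bouts" —
decoded rest spans lasting 2-12 h — on 5-min temperature and on LIDS
(Locomotor Inactivity During Sleep), an inverse transform of activity that
amplifies low movement.  Each subject's ultradian sub-period is the median
of per-bout dominant periods on a 0.5-6 h grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lombscargle

from .cohort import DayPartition
from .hhmm import StateProbabilities

__all__ = [
    "Peak",
    "SpectrumEstimate",
    "RestBout",
    "sr_spectrum",
    "classify_dominant",
    "gravity_centre",
    "lids",
    "extract_rest_bouts",
    "ultradian_subperiod",
    "DEFAULT_BANDS",
]

DEFAULT_PERIOD_GRID = np.round(np.arange(2.0, 40.0 + 1e-9, 0.1), 10)

# the circadian band is a design choice (the circa-12 and circa-8 bands are
# the printed ones)
DEFAULT_BANDS = {"circadian": (20.0, 28.0), "circa12": (10.0, 14.0), "circa8": (7.0, 9.0)}


@dataclass
class Peak:
    period_h: float
    ci_low: float
    ci_high: float
    height: float


@dataclass
class SpectrumEstimate:
    periods: np.ndarray
    density: np.ndarray
    peaks: list[Peak] = field(default_factory=list)
    dominant_period: float | None = None  # None = undetectable
    tag: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"period_h": self.periods, "density": self.density})

    def plot(self, ax=None, **kwargs):
        """Plot the spectral density over the period grid, marking peaks
        and their confidence intervals."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.periods, self.density, label=self.tag or None, **kwargs)
        for p in self.peaks:
            ax.axvline(p.period_h, ls="--", lw=0.8, color="grey")
            ax.axvspan(p.ci_low, p.ci_high, alpha=0.15, color="grey")
        ax.set_xlabel("period (h)")
        ax.set_ylabel("normalized density")
        return ax


def _ls_density(t_h: np.ndarray, y: np.ndarray, periods: np.ndarray,
                smooth: int = 3) -> np.ndarray:
    """Normalized Lomb-Scargle density over a period grid, mean-removed and
    Daniell-smoothed; tolerant of missing samples (t_h holds observed times)."""
    y = y - y.mean()
    if np.allclose(y, 0):
        return np.zeros_like(periods)
    w = 2 * np.pi / periods
    dens = lombscargle(t_h, y, w, normalize=True)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        dens = np.convolve(dens, kernel, mode="same")
    return dens


def _local_maxima(density: np.ndarray, floor: float) -> np.ndarray:
    idx = np.flatnonzero(
        (density[1:-1] > density[:-2]) & (density[1:-1] >= density[2:])
        & (density[1:-1] >= floor)
    ) + 1
    return idx


def sr_spectrum(
    values: np.ndarray,
    dt_h: float = 1.0,
    period_grid: np.ndarray | None = None,
    n_boot: int = 100,
    seed: int = 0,
    noise_floor: float = 0.1,
    smooth: int = 3,
    ci_level: float = 0.90,
    tag: str = "",
) -> SpectrumEstimate:
    """Spectrum with resampling confidence intervals for peak periods.

    Parameters
    ----------
    values : evenly binned series (NaN = missing), bin width ``dt_h`` hours.
    period_grid : candidate periods in hours (default 2-40 h by 0.1 h);
        truncated with a warning when the series spans fewer than 3 cycles
        of the longest period.
    n_boot : day-block bootstrap replicates for the peak-period CIs.
    noise_floor : minimum normalized density for a local maximum to count
        as a peak; with nothing above the floor the dominant period is
        undetectable.
    """
    values = np.asarray(values, dtype=float)
    mask = ~np.isnan(values)
    if not mask.any():
        raise ValueError("all-missing series")
    periods = np.asarray(DEFAULT_PERIOD_GRID if period_grid is None else period_grid,
                         dtype=float)
    span_h = len(values) * dt_h
    if span_h < 3 * periods.max():
        keep = periods <= span_h / 3
        if not keep.any():
            warnings.warn("series too short for any grid period: undetectable")
            return SpectrumEstimate(periods=periods, density=np.zeros_like(periods),
                                    dominant_period=None, tag=tag)
        warnings.warn(
            f"series spans {span_h:.0f} h < 3x the longest grid period; truncating grid"
        )
        periods = periods[keep]

    t_h = np.arange(len(values)) * dt_h
    dens = _ls_density(t_h[mask], values[mask], periods, smooth)
    peak_idx = _local_maxima(dens, noise_floor)

    peaks: list[Peak] = []
    if len(peak_idx) > 0 and n_boot > 0:
        ci_bounds = _bootstrap_peak_cis(
            t_h, values, mask, periods, smooth, peak_idx, n_boot, seed, ci_level
        )
    else:
        ci_bounds = [(float(periods[i]), float(periods[i])) for i in peak_idx]
    half_step = np.median(np.diff(periods)) / 2 if len(periods) > 1 else 0.0
    for i, (lo, hi) in zip(peak_idx, ci_bounds):
        peaks.append(Peak(period_h=float(periods[i]),
                          ci_low=float(lo - half_step), ci_high=float(hi + half_step),
                          height=float(dens[i])))
    peaks.sort(key=lambda p: -p.height)
    dominant = peaks[0].period_h if peaks else None
    return SpectrumEstimate(periods=periods, density=dens, peaks=peaks,
                            dominant_period=dominant, tag=tag)


def _bootstrap_peak_cis(t_h, values, mask, periods, smooth, peak_idx,
                        n_boot, seed, ci_level):
    """Day-block bootstrap: resample whole 24-h blocks, re-estimate the
    spectrum, track each peak inside a +/-25% period window."""
    rng = np.random.default_rng(seed)
    day = (t_h // 24.0).astype(int)
    days = np.unique(day[mask])
    boot_periods = {int(i): [] for i in peak_idx}
    for _ in range(n_boot):
        chosen = rng.choice(days, size=len(days), replace=True)
        ts, ys = [], []
        for slot, d in enumerate(chosen):
            sel = mask & (day == d)
            ts.append(t_h[sel] % 24.0 + 24.0 * slot)
            ys.append(values[sel])
        tb = np.concatenate(ts)
        yb = np.concatenate(ys)
        if len(tb) < 4:
            continue
        db = _ls_density(tb, yb, periods, smooth)
        for i in peak_idx:
            p0 = periods[i]
            win = (periods >= 0.75 * p0) & (periods <= 1.25 * p0)
            j = np.flatnonzero(win)[np.argmax(db[win])]
            boot_periods[int(i)].append(periods[j])
    alpha = (1 - ci_level) / 2
    out = []
    for i in peak_idx:
        bp = boot_periods[int(i)]
        if bp:
            out.append((np.quantile(bp, alpha), np.quantile(bp, 1 - alpha)))
        else:
            out.append((float(periods[i]), float(periods[i])))
    return out


def classify_dominant(spec: SpectrumEstimate,
                      bands: dict[str, tuple[float, float]] | None = None) -> str:
    """Band classification of the dominant period: circadian (20-28 h),
    circa-12 h (10-14 h), circa-8 h (7-9 h), other, or undetectable."""
    if spec.dominant_period is None:
        return "undetectable"
    bands = DEFAULT_BANDS if bands is None else bands
    p = spec.dominant_period
    for name in ("circadian", "circa12", "circa8"):
        lo, hi = bands[name]
        if lo <= p <= hi:
            return name
    return "other"


def gravity_centre(spec: SpectrumEstimate) -> float:
    """Density-weighted mean period (trapezoid rule); values between 12 h
    and 24 h indicate mixed 12-h/24-h periodicity."""
    total = np.trapezoid(spec.density, spec.periods)
    if total <= 0:
        raise ValueError("zero total density: gravity centre undefined")
    return float(np.trapezoid(spec.periods * spec.density, spec.periods) / total)


def lids(pa_5min: np.ndarray, smooth_bins: int = 6) -> np.ndarray:
    """Locomotor Inactivity During Sleep: 100 / (activity + 1) after a
    30-min moving average of 5-min activity.  Monotone decreasing in
    activity; missing values propagate."""
    pa = np.asarray(pa_5min, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(pa[~np.isnan(pa)] < 0):
            raise ValueError("negative activity in LIDS input")
    if smooth_bins > 1:
        sm = pd.Series(pa).rolling(smooth_bins, center=True, min_periods=1).mean()
        sm[np.isnan(pa)] = np.nan  # do not impute through gaps
        pa = sm.to_numpy()
    return 100.0 / (pa + 1.0)


@dataclass
class RestBout:
    start_bin: int
    end_bin: int  # exclusive
    duration_h: float
    start: pd.Timestamp | None = None
    end: pd.Timestamp | None = None


def extract_rest_bouts(
    decoded: StateProbabilities,
    partition: DayPartition | None = None,
    min_h: float = 2.0,
    max_h: float = 12.0,
    merge_gap_min: float = 10.0,
    bin_minutes: float = 5.0,
) -> list[RestBout]:
    """Maximal runs of locally-decoded rest, merged across gaps shorter
    than ``merge_gap_min`` (brief decode flickers should not split a sleep
    episode), then filtered to [2, 12] h durations."""
    rest = decoded.states == 0
    n = len(rest)
    runs: list[list[int]] = []
    i = 0
    while i < n:
        if rest[i]:
            j = i
            while j < n and rest[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    gap_bins = merge_gap_min / bin_minutes
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < gap_bins:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    bouts = []
    for s, e in merged:
        dur = (e - s) * bin_minutes / 60.0
        if min_h <= dur <= max_h:
            ts = decoded.timestamps
            bouts.append(RestBout(
                start_bin=s, end_bin=e, duration_h=dur,
                start=ts[s] if ts is not None else None,
                end=ts[e - 1] + pd.Timedelta(minutes=bin_minutes) if ts is not None else None,
            ))
    return bouts


def ultradian_subperiod(
    series_5min: np.ndarray,
    bouts: list[RestBout],
    bin_minutes: float = 5.0,
    grid_step_h: float = 0.05,
    min_period_h: float = 0.5,
    max_period_h: float = 6.0,
    min_observed_h: float = 2.0,
) -> tuple[float | None, list[float]]:
    """Per-subject median ultradian period within rest bouts.

    Each bout is linearly detrended and its dominant period located on a
    0.5 h - min(6, duration/2) h grid; the subject's value is the median
    over usable bouts (None when no bout has >= 2 h of observed data).
    Returns (median, per-bout periods).
    """
    y_all = np.asarray(series_5min, dtype=float)
    per_bout: list[float] = []
    for bout in bouts:
        y = y_all[bout.start_bin: bout.end_bin]
        t = np.arange(len(y)) * bin_minutes / 60.0
        m = ~np.isnan(y)
        if m.sum() * bin_minutes / 60.0 < min_observed_h:
            continue
        tm, ym = t[m], y[m]
        slope, icpt = np.polyfit(tm, ym, 1)
        ym = ym - (slope * tm + icpt)
        top = min(max_period_h, bout.duration_h / 2.0)
        if top <= min_period_h:
            continue
        grid = np.arange(min_period_h, top + 1e-9, grid_step_h)
        dens = _ls_density(tm, ym, grid, smooth=3)
        if not np.any(dens > 0):
            continue
        per_bout.append(float(grid[np.argmax(dens)]))
    if not per_bout:
        return None, []
    return float(np.median(per_bout)), per_bout
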