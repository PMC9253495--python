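"""Spectral period estimation, LIDS, rest bouts and ultradian sub-periods."""

import numpy as np
import pytest

from circarest.hhmm import StateProbabilities
from circarest.spectral import (
    RestBout,
    SpectrumEstimate,
    classify_dominant,
    extract_rest_bouts,
    gravity_centre,
    lids,
    sr_spectrum,
    ultradian_subperiod,
)


def hourly_signal(days=7, periods=(24.0,), amps=None, noise_sd=0.0, seed=0):
    t = np.arange(days * 24, dtype=float)
    amps = amps or [1.0] * len(periods)
    rng = np.random.default_rng(seed)
    y = sum(a * np.cos(2 * np.pi * t / p) for p, a in zip(periods, amps))
    return np.asarray(y) + rng.normal(0, noise_sd, len(t))


class TestSRSpectrum:
    def test_pure_24h_dominant_with_ci(self):
        spec = sr_spectrum(hourly_signal(), n_boot=50, seed=1)
        assert spec.dominant_period == pytest.approx(24.0, abs=0.2)
        dom = spec.peaks[0]
        assert dom.ci_low <= 24.0 <= dom.ci_high

    def test_two_component_signal_shows_both_peaks(self):
        """24 h + 12 h at equal amplitude, SNR 10: both peaks found in at
        least 9 of 10 seeds."""
        hits = 0
        for seed in range(10):
            y = hourly_signal(periods=(24.0, 12.0), noise_sd=np.sqrt(0.1), seed=seed)
            spec = sr_spectrum(y, n_boot=0, seed=0)
            found = [p.period_h for p in spec.peaks]
            ok24 = any(abs(p - 24) < 2 for p in found)
            ok12 = any(abs(p - 12) < 1 for p in found)
            hits += ok24 and ok12
        assert hits >= 9

    def test_white_noise_mostly_undetectable(self):
        """False-peak rate at the default floor stays at or below 10%."""
        false_peaks = 0
        for seed in range(20):
            y = np.random.default_rng(seed).normal(0, 1, 7 * 24)
            spec = sr_spectrum(y, n_boot=0, seed=0)
            false_peaks += spec.dominant_period is not None
        assert false_peaks <= 2

    def test_mean_shift_invariance(self):
        y = hourly_signal(noise_sd=0.2, seed=3)
        a = sr_spectrum(y, n_boot=0)
        b = sr_spectrum(y + 37.0, n_boot=0)
        np.testing.assert_allclose(a.density, b.density, atol=1e-12)

    def test_missing_tolerance(self):
        y = hourly_signal(noise_sd=0.1, seed=4)
        y[10:30] = np.nan
        spec = sr_spectrum(y, n_boot=0)
        assert spec.dominant_period == pytest.approx(24.0, abs=0.3)

    def test_short_series_truncates_grid(self):
        with pytest.warns(UserWarning, match="truncating"):
            spec = sr_spectrum(hourly_signal(days=3), n_boot=0)
        assert spec.periods.max() <= 24.0 + 1e-9

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="all-missing"):
            sr_spectrum(np.full(168, np.nan))


class TestClassifyDominant:
    @pytest.mark.parametrize("period, expected", [
        (24.0, "circadian"), (21.0, "circadian"), (11.0, "circa12"),
        (8.5, "circa8"), (16.0, "other"), (None, "undetectable")])
    def test_bands(self, period, expected):
        grid = np.arange(2, 40.1, 0.1)
        spec = SpectrumEstimate(periods=grid, density=np.zeros_like(grid),
                                dominant_period=period)
        assert classify_dominant(spec) == expected


class TestGravityCentre:
    def _spec(self, density, grid=None):
        grid = np.arange(2, 40.05, 0.1) if grid is None else grid
        return SpectrumEstimate(periods=grid, density=density)

    def test_single_narrow_peak(self):
        grid = np.arange(2, 40.05, 0.1)
        density = np.exp(-0.5 * ((grid - 24.0) / 0.2) ** 2)
        assert gravity_centre(self._spec(density, grid)) == pytest.approx(24.0, abs=0.05)

    def test_equal_masses_at_12_and_24(self):
        grid = np.arange(2, 40.05, 0.1)
        density = (np.exp(-0.5 * ((grid - 12.0) / 0.2) ** 2)
                   + np.exp(-0.5 * ((grid - 24.0) / 0.2) ** 2))
        assert gravity_centre(self._spec(density, grid)) == pytest.approx(18.0, abs=0.1)

    def test_uniform_density_gives_midpoint(self):
        grid = np.arange(2, 40.05, 0.1)
        assert gravity_centre(self._spec(np.ones_like(grid), grid)) == pytest.approx(21.0, abs=0.01)

    def test_zero_density_undefined(self):
        grid = np.arange(2, 40.05, 0.1)
        with pytest.raises(ValueError, match="undefined"):
            gravity_centre(self._spec(np.zeros_like(grid), grid))


class TestLIDS:
    def test_boundary_values_without_smoothing(self):
        out = lids(np.array([0.0, 99.0]), smooth_bins=1)
        np.testing.assert_allclose(out, [100.0, 1.0])

    def test_monotone_decreasing_in_activity(self):
        a = np.linspace(0, 50, 20)
        out = lids(a, smooth_bins=1)
        assert (np.diff(out) < 0).all()

    def test_missing_propagates(self):
        out = lids(np.array([1.0, np.nan, 3.0]))
        assert np.isnan(out[1])

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            lids(np.array([-1.0]))


def _decoded_states(states):
    T = len(states)
    post = np.zeros((T, 3))
    post[np.arange(T), states] = 1.0
    return StateProbabilities(post, np.asarray(states), times_h=(np.arange(T) % 288) / 12.0)


class TestRestBouts:
    def test_continuous_8h_run_is_one_bout(self):
        states = np.ones(288, dtype=int)
        states[12: 12 + 96] = 0  # 8 h
        bouts = extract_rest_bouts(_decoded_states(states))
        assert len(bouts) == 1 and bouts[0].duration_h == pytest.approx(8.0)

    @pytest.mark.parametrize("hours", [1.0, 13.0])
    def test_out_of_range_durations_excluded(self, hours):
        states = np.ones(2 * 288, dtype=int)
        states[12: 12 + int(hours * 12)] = 0
        assert extract_rest_bouts(_decoded_states(states)) == []

    def test_short_gaps_merged(self):
        states = np.ones(288, dtype=int)
        states[12:60] = 0
        states[61:108] = 0  # 5-min flicker inside an 8-h episode
        bouts = extract_rest_bouts(_decoded_states(states))
        assert len(bouts) == 1
        assert bouts[0].duration_h == pytest.approx(8.0)

    def test_long_gaps_split(self):
        states = np.ones(288, dtype=int)
        states[12:48] = 0   # 3 h
        states[60:96] = 0   # 3 h, separated by 1 h of activity
        bouts = extract_rest_bouts(_decoded_states(states))
        assert len(bouts) == 2


class TestUltradianSubperiod:
    def _bout_series(self, period_h, duration_h=8.0, n_bouts=3, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        nb = int(duration_h * 12)
        series, bouts, pos = [], [], 0
        for _ in range(n_bouts):
            t = np.arange(nb) / 12.0
            series.append(np.cos(2 * np.pi * t / period_h) + rng.normal(0, noise, nb))
            bouts.append(RestBout(pos, pos + nb, duration_h))
            pos += nb
        return np.concatenate(series), bouts

    def test_planted_period_recovered(self):
        y, bouts = self._bout_series(1.5)
        med, per = ultradian_subperiod(y, bouts)
        assert med == pytest.approx(1.5, abs=0.1)

    def test_median_over_bouts(self):
        ys, bouts, pos = [], [], 0
        for p in (1.5, 2.0, 2.5):
            y, b = self._bout_series(p, n_bouts=1, seed=int(p * 10))
            bouts.append(RestBout(pos, pos + (b[0].end_bin - b[0].start_bin),
                                  b[0].duration_h))
            ys.append(y)
            pos = bouts[-1].end_bin
        med, per = ultradian_subperiod(np.concatenate(ys), bouts)
        assert len(per) == 3
        assert med == pytest.approx(2.0, abs=0.1)

    def test_no_usable_bouts_gives_none(self):
        y = np.full(288, np.nan)
        med, per = ultradian_subperiod(y, [RestBout(0, 96, 8.0)])
        assert med is None and per == []

    def test_linear_trend_removed(self):
        y, bouts = self._bout_series(2.0, noise=0.0)
        trend = np.linspace(0, 3.0, len(y))
        med, _ = ultradian_subperiod(y + trend, bouts)
        assert med == pytest.approx(2.0, abs=0.1)

    def test_correlated_channels_give_positive_spearman(self):
        """Subjects with longer planted PA periods also have longer planted
        temperature periods; recovered medians preserve the association."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(5)
        pa_periods, temp_periods = [], []
        for i in range(12):
            base = rng.uniform(1.2, 3.0)
            y1, b1 = self._bout_series(base, seed=100 + i, noise=0.1)
            y2, b2 = self._bout_series(base + rng.normal(0, 0.1), seed=200 + i,
                                       noise=0.1)
            m1, _ = ultradian_subperiod(y1, b1)
            m2, _ = ultradian_subperiod(y2, b2)
            pa_periods.append(m1)
            temp_periods.append(m2)
        rho, _ = spearmanr(pa_periods, temp_periods)
        assert rho > 0.5
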