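"""Circadian summary statistics: profiles, p1-1, rest amount, centre, RI."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circarest.hhmm import StateProbabilities
from circarest.metrics import (
    N_SLOTS,
    RestProfile,
    alt_centre_max_daytime,
    centre_of_rest,
    p11,
    rest_amount,
    rest_profile,
    rhythm_index,
)


def rect_profile(start_h: float, end_h: float, level: float = 1.0,
                 base: float = 0.0) -> RestProfile:
    """Rectangular profile: ``level`` on [start_h, end_h) (circular), else base."""
    clock = (np.arange(N_SLOTS) + 0.5) / 12.0
    if start_h <= end_h:
        inside = (clock >= start_h) & (clock < end_h)
    else:
        inside = (clock >= start_h) | (clock < end_h)
    return RestProfile(np.where(inside, level, base))


def one_hot_decoded(rest_slots_per_day: np.ndarray, n_days: int) -> StateProbabilities:
    """Decoded posteriors that equal 1 on the rest state in given clock slots."""
    T = n_days * N_SLOTS
    post = np.zeros((T, 3))
    slots = np.arange(T) % N_SLOTS
    rest = np.isin(slots, rest_slots_per_day)
    post[rest, 0] = 1.0
    post[~rest, 1] = 1.0
    return StateProbabilities(posteriors=post, states=post.argmax(1),
                              times_h=slots / 12.0,
                              observed=np.ones(T, bool))


class TestRestProfile:
    def test_rectangular_daily_pattern(self):
        slots = np.arange(12 * 1, 12 * 5)  # rest 01:00-05:00 every day
        dec = one_hot_decoded(slots, n_days=4)
        prof = rest_profile(dec)
        expected = np.zeros(N_SLOTS)
        expected[slots] = 1.0
        np.testing.assert_allclose(prof.values, expected)

    def test_slot_mean_over_days(self):
        T = 2 * N_SLOTS
        post = np.zeros((T, 3))
        post[:, 0] = np.r_[np.full(N_SLOTS, 0.4), np.full(N_SLOTS, 0.6)]
        post[:, 1] = 1 - post[:, 0]
        dec = StateProbabilities(post, post.argmax(1),
                                 times_h=(np.arange(T) % N_SLOTS) / 12.0,
                                 observed=np.ones(T, bool))
        np.testing.assert_allclose(rest_profile(dec).values, 0.5)

    def test_missing_bins_excluded_from_slot_mean(self):
        T = 2 * N_SLOTS
        post = np.zeros((T, 3))
        post[:, 0] = np.r_[np.full(N_SLOTS, 0.2), np.full(N_SLOTS, 0.8)]
        post[:, 1] = 1 - post[:, 0]
        observed = np.ones(T, bool)
        observed[:N_SLOTS] = False  # first day entirely unobserved
        dec = StateProbabilities(post, post.argmax(1),
                                 times_h=(np.arange(T) % N_SLOTS) / 12.0,
                                 observed=observed)
        np.testing.assert_allclose(rest_profile(dec).values, 0.8)

    def test_reanchoring_rolls_values(self):
        prof = rect_profile(1.0, 5.0)
        again = prof.reanchored(20.0).reanchored(0.0)
        np.testing.assert_allclose(again.values, prof.values)

    def test_ns_generator_occupancy_peak_after_7am(self):
        """Latent NS workday rest concentrates after the night shift."""
        from circarest.simulate import default_params, make_schedule, simulate_activity

        act = simulate_activity(make_schedule("NS", 7), default_params("NS"), seed=8)
        wk = act.day_labels_5min == "workday"
        T = len(act.states_5min)
        post = np.zeros((T, 3))
        post[np.arange(T), act.states_5min] = 1.0
        dec = StateProbabilities(post[wk], act.states_5min[wk],
                                 times_h=(np.arange(T)[wk] % N_SLOTS) / 12.0,
                                 observed=np.ones(wk.sum(), bool))
        prof = rest_profile(dec)
        assert prof.slot_clock_h()[np.argmax(prof.values)] > 7.0


class _StubFit:
    """Duck-typed fit exposing rest_row_p11/oscillator_set for p11 tests."""

    def __init__(self, p11_fn):
        self._fn = p11_fn
        self.model = self
        self.oscillator_set = ("all",)

    def rest_row_p11(self, t_hours, day_type=None):
        return self._fn(t_hours)


class TestP11:
    def _decoded(self, gamma1):
        T = len(gamma1)
        post = np.column_stack([gamma1, 1 - gamma1, np.zeros(T)])
        return StateProbabilities(post, post.argmax(1),
                                  times_h=(np.arange(T) % N_SLOTS) / 12.0,
                                  observed=np.ones(T, bool))

    def test_homogeneous_chain_returns_p11(self):
        dec = self._decoded(np.full(N_SLOTS, 0.5))
        assert p11(_StubFit(lambda t: 0.9), dec) == pytest.approx(0.9)

    def test_probability_one_everywhere(self):
        dec = self._decoded(np.random.default_rng(0).uniform(0.1, 0.9, N_SLOTS))
        assert p11(_StubFit(lambda t: 1.0), dec) == pytest.approx(1.0)

    def test_two_level_equal_occupancy(self):
        dec = self._decoded(np.full(N_SLOTS, 0.5))
        fit = _StubFit(lambda t: 0.8 if t < 12 else 1.0)
        assert p11(fit, dec) == pytest.approx(0.9)

    def test_occupancy_weighting_matters(self):
        gamma1 = np.r_[np.full(N_SLOTS // 2, 0.9), np.full(N_SLOTS // 2, 0.1)]
        dec = self._decoded(gamma1)
        fit = _StubFit(lambda t: 0.99 if t < 12 else 0.80)
        weighted = p11(fit, dec)
        unweighted = p11(fit, dec, weighted=False)
        assert weighted > unweighted  # mass sits where P11 is high

    def test_zero_occupancy_undefined(self):
        dec = self._decoded(np.zeros(N_SLOTS))
        with pytest.raises(ValueError, match="undefined"):
            p11(_StubFit(lambda t: 0.9), dec)


class TestRestAmount:
    @pytest.mark.parametrize("profile, expected", [
        (RestProfile(np.ones(N_SLOTS)), 24.0),
        (RestProfile(np.full(N_SLOTS, 0.5)), 12.0),
        (rect_profile(1.0, 5.0), 4.0),
    ])
    def test_area(self, profile, expected):
        assert rest_amount(profile) == pytest.approx(expected)


class TestCentreOfRest:
    def test_symmetric_window(self):
        assert centre_of_rest(rect_profile(1.0, 5.0)) == pytest.approx(3.0, abs=0.01)

    def test_wraps_midnight(self):
        c = centre_of_rest(rect_profile(23.0, 1.0))
        assert min(c, 24 - c) == pytest.approx(0.0, abs=0.01)

    def test_shift_equivariance(self):
        base = rect_profile(1.0, 5.0)
        shifted = RestProfile(np.roll(base.values, 24))  # +2 h
        assert centre_of_rest(shifted) == pytest.approx(
            centre_of_rest(base) + 2.0, abs=0.01)

    def test_flat_profile_undefined(self):
        assert centre_of_rest(RestProfile(np.full(N_SLOTS, 0.4))) is None
        assert centre_of_rest(RestProfile(np.zeros(N_SLOTS))) is None


class TestAltCentre:
    def test_value_in_window(self):
        prof = rect_profile(8.0, 12.0, level=0.6)
        assert 7.0 <= alt_centre_max_daytime(prof) <= 20.0

    def test_ignores_global_max_outside_window(self):
        v = np.full(N_SLOTS, 0.1)
        v[3 * 12] = 1.0    # global max 03:00 (outside window)
        v[11 * 12] = 0.7   # local max 11:00 (inside)
        t = alt_centre_max_daytime(RestProfile(v))
        assert t == pytest.approx(11.0, abs=0.05)

    def test_flat_window_ties_to_earliest(self):
        prof = RestProfile(np.full(N_SLOTS, 0.3))
        assert alt_centre_max_daytime(prof) == pytest.approx(7.0, abs=0.05)


class TestRhythmIndex:
    def test_perfect_rest_window_gives_one(self):
        assert rhythm_index(rect_profile(23.0, 7.0)) == pytest.approx(1.0)

    @pytest.mark.parametrize("level", [0.0, 0.4, 1.0])
    def test_flat_profile_gives_zero(self, level):
        assert rhythm_index(RestProfile(np.full(N_SLOTS, level))) == 0.0

    def test_two_level_contrast_exact(self):
        # 144 slots at 0.75 inside, 0.25 outside: window width = 12 h exactly
        prof = rect_profile(21.0, 9.0, level=0.75, base=0.25)
        assert rhythm_index(prof) == pytest.approx(0.5)

    def test_two_level_contrast_self_consistent_region(self):
        """0.8 inside its own RI window, 0.3 outside -> contrast 0.5.

        Self-consistency (region width = rest amount) requires a 14.4-h
        region for the 0.8/0.3 levels; slot rounding leaves ~0.01 slack.
        """
        prof = rect_profile(19.8, 10.2, level=0.8, base=0.3)
        assert rhythm_index(prof) == pytest.approx(0.5, abs=0.02)

    def test_sharper_contrast_scores_higher(self):
        """RI orders profiles by inside/outside contrast.  (RI is not
        invariant to adding a constant: the window width equals the rest
        amount, which grows with the constant.)"""
        strong = rect_profile(23.0, 7.0, level=0.9, base=0.1)
        weak = rect_profile(23.0, 7.0, level=0.6, base=0.4)
        assert rhythm_index(strong) > rhythm_index(weak) > 0.0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_output_ranges(self, seed):
        rng = np.random.default_rng(seed)
        prof = RestProfile(rng.uniform(0, 1, N_SLOTS))
        ri = rhythm_index(prof)
        assert 0.0 <= ri <= 1.0
        assert 0.0 <= rest_amount(prof) <= 24.0
        c = centre_of_rest(prof)
        assert c is None or 0.0 <= c < 24.0
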