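"""Shared fixtures: small synthetic subjects and amortized HMM fits."""

import numpy as np
import pandas as pd
import pytest

from circarest.cohort import MinuteSeries, partition_days
from circarest.hhmm import HarmonicHMM
from circarest.simulate import default_params, generate_cohort, make_schedule, simulate_activity


def subject_span(subj):
    ts = subj.series.timestamps
    return (ts[0].to_pydatetime(),
            (ts[-1] + pd.Timedelta(minutes=1)).to_pydatetime())


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(2, 2, 7, seed=3)


@pytest.fixture(scope="session")
def ds_sim():
    """One DS subject's simulated activity with its generating parameters."""
    params = default_params("DS")
    schedule = make_schedule("DS", 7)
    act = simulate_activity(schedule, params, seed=11)
    series = MinuteSeries("DS_fix", act.timestamps, act.pa)
    return {"params": params, "schedule": schedule, "act": act, "series": series}


@pytest.fixture(scope="session")
def ds_fit(ds_sim):
    """Single-oscillator harmonic HMM fitted to the DS fixture subject."""
    model = HarmonicHMM.from_series(ds_sim["series"])
    return model.fit(n_restarts=2, seed=0)


@pytest.fixture(scope="session")
def ns_two_osc(small_cohort):
    """A fitted two-oscillator model + decode for one NS cohort subject."""
    subj = small_cohort["NS001"]
    part = partition_days(subj.diary, subj.meta, subject_span(subj))
    fit = HarmonicHMM.from_series(subj.series, part).fit(n_restarts=2, seed=0)
    return {"subject": subj, "partition": part, "fit": fit, "decoded": fit.decode()}


def brute_force_posteriors(pi0, B, Pseq):
    """Exhaustive path-enumeration oracle for the smoothed posteriors of a
    time-inhomogeneous HMM (tiny T only)."""
    T, K = B.shape
    post = np.zeros((T, K))
    total = 0.0
    import itertools

    for path in itertools.product(range(K), repeat=T):
        w = pi0[path[0]] * B[0, path[0]]
        for t in range(1, T):
            w *= Pseq[t - 1, path[t - 1], path[t]] * B[t, path[t]]
        total += w
        for t in range(T):
            post[t, path[t]] += w
    return post / total, np.log(total)
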