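"""Harmonic hidden Markov models for rest-activity telemonitoring.

A three-state Gaussian-emission HMM is fitted to square-root 5-minute
average activity.  States are ordered by emission mean: inactive/rest (IA),
moderately active (MA), highly active (HA).  The transition probabilities
are time-inhomogeneous: each row of the transition matrix is a multinomial
logit (reference category = the self-transition) whose non-reference logits
carry sinusoidal terms of fundamental period 24 h, so a circadian
oscillator modulates the chain.  The two-oscillator variant (2-HHMM) gives
work days and free days separate harmonic coefficients while sharing the
emissions and baseline logits.

Estimation is by EM: the E-step is the scaled forward-backward recursion
with per-bin transition matrices (missing bins contribute emission
likelihood 1 to every state); the M-step updates emissions in closed form
and each transition row by a weighted multinomial-logit fit (an ECM step,
so the likelihood is non-decreasing).  Decoding is local (per-bin argmax of
the smoothed posterior), not Viterbi.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .cohort import DayPartition, MinuteSeries, resample, sqrt_pa

__all__ = [
    "HarmonicHMM",
    "HHMMResults",
    "StateProbabilities",
    "aicc",
    "forward_backward",
]

_PERIOD_H = 24.0

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco


@_njit(cache=True)
def _fb_kernel(pi0, B, Pseq):  # pragma: no cover - numba-compiled
    T, K = B.shape
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    c = np.empty(T)
    a = pi0 * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = np.zeros(K)
        for j in range(K):
            aj = alpha[t - 1, j]
            for k in range(K):
                a[k] += aj * Pseq[t - 1, j, k]
        a = a * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        for j in range(K):
            s = 0.0
            for k in range(K):
                s += Pseq[t, j, k] * B[t + 1, k] * beta[t + 1, k]
            beta[t, j] = s / c[t + 1]
    gamma = alpha * beta
    xi = np.empty((T - 1, K, K))
    for t in range(1, T):
        for j in range(K):
            for k in range(K):
                xi[t - 1, j, k] = (
                    alpha[t - 1, j] * Pseq[t - 1, j, k] * B[t, k] * beta[t, k] / c[t]
                )
    loglik = np.log(c).sum()
    return gamma, xi, loglik


def forward_backward(pi0: np.ndarray, B: np.ndarray, Pseq: np.ndarray):
    """Scaled forward-backward for a time-inhomogeneous chain.

    Parameters
    ----------
    pi0 : (K,) initial distribution
    B : (T, K) emission likelihoods (1.0 in rows with missing data)
    Pseq : (T-1, K, K) transition matrix from bin t to t+1

    Returns (gamma, xi, loglik): smoothed posteriors (T, K), transition
    posteriors (T-1, K, K) and the log-likelihood.
    """
    pi0 = np.ascontiguousarray(pi0, dtype=float)
    B = np.ascontiguousarray(B, dtype=float)
    Pseq = np.ascontiguousarray(Pseq, dtype=float)
    return _fb_kernel(pi0, B, Pseq)


@dataclass
class StateProbabilities:
    """Smoothed posteriors P(state | all observations) and local decoding."""

    posteriors: np.ndarray  # (T, K), rows sum to 1
    states: np.ndarray  # (T,) argmax state index, 0 = rest
    times_h: np.ndarray  # clock hour of each bin
    timestamps: pd.DatetimeIndex | None = None
    observed: np.ndarray | None = None  # bool mask, False where input missing

    def to_frame(self) -> pd.DataFrame:
        K = self.posteriors.shape[1]
        df = pd.DataFrame(self.posteriors, columns=[f"p_state{k}" for k in range(K)])
        df["state"] = self.states
        df["clock_h"] = self.times_h
        if self.observed is not None:
            df["observed"] = self.observed
        if self.timestamps is not None:
            df.index = self.timestamps
        return df


def aicc(loglik: float, n_params: int, n_obs: int) -> float:
    """Corrected Akaike information criterion AIC + 2k(k+1)/(n-k-1)."""
    if n_obs <= n_params + 1:
        raise ValueError(f"AICc undefined for n={n_obs} <= k+1={n_params + 1}")
    aic = 2 * n_params - 2 * loglik
    return aic + 2 * n_params * (n_params + 1) / (n_obs - n_params - 1)


def _harmonic_design(times_h: np.ndarray, day_types: np.ndarray | None,
                     n_harmonics: int, n_osc: int) -> np.ndarray:
    """Design matrix for the transition logits: intercept plus per-oscillator
    cos/sin pairs (period 24/h hours for harmonic h)."""
    T = len(times_h)
    p = 1 + 2 * n_harmonics * n_osc
    X = np.zeros((T, p))
    X[:, 0] = 1.0
    col = 1
    for d in range(n_osc):
        sel = np.ones(T, dtype=bool) if day_types is None else (day_types == d)
        for h in range(1, n_harmonics + 1):
            w = 2 * np.pi * h / _PERIOD_H
            X[sel, col] = np.cos(w * times_h[sel])
            X[sel, col + 1] = np.sin(w * times_h[sel])
            col += 2
    return X


def _row_logits_to_P(Z: np.ndarray) -> np.ndarray:
    """(T, K, K) logits with zero diagonal -> row-softmax transition matrices."""
    Zmax = Z.max(axis=2, keepdims=True)
    E = np.exp(Z - Zmax)
    return E / E.sum(axis=2, keepdims=True)


class HarmonicHMM:
    """Harmonic HMM for square-root-scale 5-minute activity.

    Parameters
    ----------
    obs : array of sqrt-scale activity per bin; NaN marks missing bins.
    times_h : clock hour-of-day (0-24) of each bin.
    n_states : number of hidden states (3 in the rest/moderate/high model).
    n_harmonics : sinusoidal harmonics on the transition logits (1 or 2).
    day_types : optional per-bin 0/1 labels (0 = work, 1 = free) selecting
        the two-oscillator variant; None fits a single oscillator.
    """

    def __init__(
        self,
        obs: Sequence[float],
        times_h: Sequence[float],
        n_states: int = 3,
        n_harmonics: int = 1,
        day_types: Sequence[int] | None = None,
        timestamps: pd.DatetimeIndex | None = None,
    ):
        self.obs = np.asarray(obs, dtype=float)
        self.times_h = np.asarray(times_h, dtype=float) % _PERIOD_H
        if self.obs.shape != self.times_h.shape:
            raise ValueError("obs and times_h must have equal length")
        self.n_states = int(n_states)
        self.n_harmonics = int(n_harmonics)
        self.day_types = None if day_types is None else np.asarray(day_types, dtype=int)
        if self.day_types is not None and self.day_types.shape != self.obs.shape:
            raise ValueError("day_types must align with obs")
        self.timestamps = timestamps
        self.n_osc = 1 if self.day_types is None else int(self.day_types.max()) + 1
        self.oscillator_set = ("all",) if self.n_osc == 1 else ("work", "free")
        obs_mask = ~np.isnan(self.obs)
        if obs_mask.mean() < 0.5:
            raise ValueError("more than 50% of bins are missing")
        if obs_mask.sum() < 2 * 288:
            warnings.warn("fewer than 2 days of observed data; fit may be unstable")
        self._obs_mask = obs_mask

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_series(
        cls,
        series: MinuteSeries,
        partition: DayPartition | None = None,
        n_states: int = 3,
        n_harmonics: int = 1,
    ) -> "HarmonicHMM":
        """Build the model from a per-minute series: 5-min binning, sqrt
        transform, clock times from timestamps, and (if a day partition is
        given) work/free day types for the two-oscillator variant."""
        binned = resample(series, "5min")
        y = sqrt_pa(binned["pa"].to_numpy())
        idx = binned.index
        times_h = idx.hour + idx.minute / 60.0
        day_types = None
        if partition is not None:
            labels = partition.day_type_of(idx)
            day_types = np.where(np.asarray(labels) == "freeday", 1, 0)
        return cls(
            y, np.asarray(times_h, dtype=float), n_states=n_states,
            n_harmonics=n_harmonics, day_types=day_types, timestamps=idx,
        )

    # -- internals ----------------------------------------------------------

    def _emission_likelihood(self, means, sds):
        B = np.ones((len(self.obs), self.n_states))
        m = self._obs_mask
        y = self.obs[m][:, None]
        B[m] = np.exp(-0.5 * ((y - means[None, :]) / sds[None, :]) ** 2) / (
            np.sqrt(2 * np.pi) * sds[None, :]
        )
        np.clip(B, 1e-300, None, out=B)
        return B

    def _transition_seq(self, alpha, coefs, X):
        """Per-bin transition matrices from bin t to t+1, evaluated at the
        clock time of the source bin.  coefs: (K, K, p-1) harmonic part."""
        K = self.n_states
        T = X.shape[0]
        Z = np.zeros((T - 1, K, K))
        Xs = X[:-1]  # source-bin covariates
        for j in range(K):
            for k in range(K):
                if j == k:
                    continue
                Z[:, j, k] = alpha[j, k] + Xs[:, 1:] @ coefs[j, k]
        return _row_logits_to_P(Z)

    def _init_params(self, rng: np.random.Generator, restart: int):
        y = self.obs[self._obs_mask]
        K = self.n_states
        qs = np.linspace(25, 95, K) if K != 3 else np.array([25.0, 60.0, 95.0])
        means = np.percentile(y, qs)
        spread = max(means[-1] - means[0], 1e-3)
        sds = np.full(K, max(y.std() / K, 1e-2))
        alpha = np.full((K, K), np.log(0.05 / 0.9))
        np.fill_diagonal(alpha, 0.0)
        p_h = 2 * self.n_harmonics * self.n_osc
        coefs = np.zeros((K, K, p_h))
        if restart > 0:
            means = np.sort(means + rng.normal(0, 0.15 * spread, K))
            sds = sds * rng.uniform(0.5, 1.5, K)
            alpha = alpha + rng.normal(0, 0.5, (K, K))
            np.fill_diagonal(alpha, 0.0)
            coefs = rng.normal(0, 0.2, coefs.shape)
        pi0 = np.full(K, 1.0 / K)
        return means, sds, alpha, coefs, pi0

    # Weak ridge on the logit update: near-zero expected counts for a rare
    # transition type make the weighted multinomial logit quasi-separable,
    # sending coefficients to +-inf (and the realized curves haywire); the
    # penalty is negligible against hundreds of observed transitions.
    _RIDGE_HARMONIC = 1.0
    _RIDGE_BASELINE = 0.01

    def _mstep_row(self, j, xi, X, alpha, coefs):
        """Weighted multinomial-logit update of transition row j."""
        K = self.n_states
        W = xi[:, j, :]  # (T-1, K) expected counts out of state j
        Xs = X[:-1]
        others = [k for k in range(K) if k != j]
        p = X.shape[1]
        theta0 = np.empty((K - 1, p))
        for i, k in enumerate(others):
            theta0[i, 0] = alpha[j, k]
            theta0[i, 1:] = coefs[j, k]
        r = W.sum(axis=1)
        lam = np.full(p, self._RIDGE_HARMONIC)
        lam[0] = self._RIDGE_BASELINE

        def negQ(theta_flat):
            th = theta_flat.reshape(K - 1, p)
            Z = np.zeros((Xs.shape[0], K))
            for i, k in enumerate(others):
                Z[:, k] = Xs @ th[i]
            lse = logsumexp(Z, axis=1)
            val = -(np.sum(W * Z) - np.sum(r * lse)) + 0.5 * np.sum(lam * th**2)
            P = np.exp(Z - lse[:, None])
            grad = np.empty_like(th)
            for i, k in enumerate(others):
                grad[i] = -Xs.T @ (W[:, k] - r * P[:, k]) + lam * th[i]
            return val, grad.ravel()

        res = minimize(negQ, theta0.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": 200, "ftol": 1e-12})
        th = (res.x if res.fun <= negQ(theta0.ravel())[0] else theta0.ravel()).reshape(K - 1, p)
        for i, k in enumerate(others):
            alpha[j, k] = th[i, 0]
            coefs[j, k] = th[i, 1:]

    def fit(
        self,
        n_restarts: int = 5,
        tol: float = 1e-5,
        maxiter: int = 500,
        seed: int = 0,
        estimate_pi0: bool = True,
    ) -> "HHMMResults":
        """EM estimation with ordered-percentile initialization plus random
        restarts; the best log-likelihood wins."""
        y = self.obs[self._obs_mask]
        if y.std() < 1e-8:
            warnings.warn("constant series: single-state fallback")
            return self._degenerate_results(y)
        X = _harmonic_design(self.times_h, self.day_types, self.n_harmonics, self.n_osc)
        rng = np.random.default_rng(seed)
        best = None
        restart_logliks = []
        for restart in range(n_restarts):
            out = self._fit_once(X, rng, restart, tol, maxiter, estimate_pi0)
            restart_logliks.append(out["loglik"])
            if best is None or out["obj"] > best["obj"]:
                best = out
        return self._package(best, restart_logliks, seed, estimate_pi0)

    def _ridge_penalty(self, alpha, coefs) -> float:
        off = ~np.eye(self.n_states, dtype=bool)
        return float(0.5 * self._RIDGE_BASELINE * np.sum(alpha[off] ** 2)
                     + 0.5 * self._RIDGE_HARMONIC * np.sum(coefs[off] ** 2))

    def _fit_once(self, X, rng, restart, tol, maxiter, estimate_pi0):
        means, sds, alpha, coefs, pi0 = self._init_params(rng, restart)
        K = self.n_states
        m = self._obs_mask
        prev_obj = -np.inf
        ll = -np.inf
        trace = []  # penalized objective: the quantity EM makes monotone
        converged = False
        for it in range(maxiter):
            B = self._emission_likelihood(means, sds)
            Pseq = self._transition_seq(alpha, coefs, X)
            gamma, xi, ll = forward_backward(pi0, B, Pseq)
            obj = ll - self._ridge_penalty(alpha, coefs)
            trace.append(obj)
            if obj < prev_obj - 1e-8 * max(1.0, abs(prev_obj)):
                warnings.warn(f"EM objective decreased at iter {it}")
            if abs(obj - prev_obj) < tol:
                converged = True
                break
            prev_obj = obj
            # M-step: emissions (observed bins only)
            g = gamma[m]
            yv = self.obs[m]
            wsum = g.sum(axis=0)
            means = (g * yv[:, None]).sum(axis=0) / wsum
            sds = np.sqrt((g * (yv[:, None] - means[None, :]) ** 2).sum(axis=0) / wsum)
            sds = np.maximum(sds, 1e-3)
            # M-step: transition rows (ridge-penalized multinomial logit)
            for j in range(K):
                self._mstep_row(j, xi, X, alpha, coefs)
            if estimate_pi0:
                pi0 = gamma[0] / gamma[0].sum()
        if not converged:
            # the last M-step moved the parameters after the last E-step
            B = self._emission_likelihood(means, sds)
            Pseq = self._transition_seq(alpha, coefs, X)
            _, _, ll = forward_backward(pi0, B, Pseq)
        # order states by emission mean
        order = np.argsort(means)
        means, sds = means[order], sds[order]
        pi0 = pi0[order]
        alpha = alpha[np.ix_(order, order)]
        coefs = coefs[np.ix_(order, order)]
        return {
            "means": means, "sds": sds, "alpha": alpha, "coefs": coefs,
            "pi0": pi0, "loglik": ll,
            "obj": ll - self._ridge_penalty(alpha, coefs),
            "trace": trace, "converged": converged,
        }

    def _package(self, best, restart_logliks, seed, estimate_pi0):
        K = self.n_states
        n_trans = K * (K - 1) * (1 + 2 * self.n_harmonics * self.n_osc)
        n_params = 2 * K + n_trans + (K - 1 if estimate_pi0 else 0)
        flags = []
        if not best["converged"]:
            flags.append("non-convergence")
        return HHMMResults(
            model=self,
            means=best["means"], sds=best["sds"], alpha=best["alpha"],
            harmonic_coefs=best["coefs"], pi0=best["pi0"],
            loglik=best["loglik"], n_params=n_params,
            n_obs=int(self._obs_mask.sum()), converged=best["converged"],
            flags=flags, loglik_trace=list(best["trace"]),
            restart_logliks=restart_logliks, seed=seed,
        )

    def _degenerate_results(self, y):
        K = self.n_states
        means = np.full(K, y.mean())
        means += np.arange(K) * 1e-6  # keep ordering well-defined
        return HHMMResults(
            model=self, means=means, sds=np.full(K, 1e-3),
            alpha=np.where(np.eye(K, dtype=bool), 0.0, -10.0),
            harmonic_coefs=np.zeros((K, K, 2 * self.n_harmonics * self.n_osc)),
            pi0=np.r_[1.0, np.zeros(K - 1)], loglik=np.nan, n_params=2 * K,
            n_obs=len(y), converged=False, flags=["degenerate:single-state"],
            loglik_trace=[], restart_logliks=[], seed=0,
        )


@dataclass
class HHMMResults:
    """Fitted harmonic HMM: emissions, harmonic transition structure,
    decoding and information criteria."""

    model: HarmonicHMM
    means: np.ndarray
    sds: np.ndarray
    alpha: np.ndarray  # baseline logits, zero diagonal (reference = self)
    harmonic_coefs: np.ndarray  # (K, K, 2*H*n_osc) cos/sin coefficient pairs
    pi0: np.ndarray
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    flags: list[str] = field(default_factory=list)
    # trace of the ridge-penalized objective (the quantity EM keeps
    # non-decreasing); `loglik` itself is the raw log-likelihood
    loglik_trace: list[float] = field(default_factory=list)
    restart_logliks: list[float] = field(default_factory=list)
    seed: int = 0

    # -- realized transition structure --------------------------------------

    def _osc_index(self, day_type: str | None) -> int:
        osc = self.model.oscillator_set
        if len(osc) == 1:
            if day_type not in (None, "all"):
                raise ValueError(
                    f"single-oscillator fit has no day type {day_type!r}"
                )
            return 0
        if day_type not in osc:
            raise ValueError(f"day_type must be one of {osc}, got {day_type!r}")
        return osc.index(day_type)

    def transition_matrix(self, t_hours: float, day_type: str | None = None) -> np.ndarray:
        """Realized stochastic transition matrix at clock time ``t_hours``."""
        d = self._osc_index(day_type)
        K = self.model.n_states
        H = self.model.n_harmonics
        t = float(t_hours) % _PERIOD_H
        x = []
        for h in range(1, H + 1):
            w = 2 * np.pi * h / _PERIOD_H
            x += [np.cos(w * t), np.sin(w * t)]
        x = np.asarray(x)
        Z = np.zeros((K, K))
        for j in range(K):
            for k in range(K):
                if j == k:
                    continue
                c = self.harmonic_coefs[j, k]
                Z[j, k] = self.alpha[j, k] + c[2 * H * d: 2 * H * (d + 1)] @ x
        return _row_logits_to_P(Z[None])[0]

    def rest_row_p11(self, t_hours: float, day_type: str | None = None) -> float:
        """P(rest -> rest) at clock time t (rest = lowest-mean state)."""
        return float(self.transition_matrix(t_hours, day_type)[0, 0])

    # -- decoding ------------------------------------------------------------

    def decode(
        self,
        obs: np.ndarray | None = None,
        times_h: np.ndarray | None = None,
        day_types: np.ndarray | None = None,
        timestamps: pd.DatetimeIndex | None = None,
    ) -> StateProbabilities:
        """Forward-backward smoothed posteriors + local decoding.

        Defaults to the training series.  Missing bins contribute emission
        likelihood 1 to all states, so the posterior there follows the
        prior propagated through the transition structure.
        """
        m = self.model
        if obs is None:
            obs, times_h, day_types, timestamps = (
                m.obs, m.times_h, m.day_types, m.timestamps)
        obs = np.asarray(obs, dtype=float)
        times_h = np.asarray(times_h, dtype=float) % _PERIOD_H
        X = _harmonic_design(times_h, day_types, m.n_harmonics, m.n_osc)
        mask = ~np.isnan(obs)
        B = np.ones((len(obs), m.n_states))
        y = obs[mask][:, None]
        B[mask] = np.exp(-0.5 * ((y - self.means[None, :]) / self.sds[None, :]) ** 2) / (
            np.sqrt(2 * np.pi) * self.sds[None, :]
        )
        np.clip(B, 1e-300, None, out=B)
        tmp = HarmonicHMM.__new__(HarmonicHMM)
        tmp.n_states = m.n_states
        Pseq = HarmonicHMM._transition_seq(tmp, self.alpha, self.harmonic_coefs, X)
        gamma, _, _ = forward_backward(self.pi0, B, Pseq)
        return StateProbabilities(
            posteriors=gamma, states=gamma.argmax(axis=1),
            times_h=times_h, timestamps=timestamps, observed=mask,
        )

    # -- information criteria & reporting ------------------------------------

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.n_params, self.n_obs)

    def summary(self) -> str:
        K = self.model.n_states
        names = ["IA (rest)", "MA", "HA"] if K == 3 else [f"state{k}" for k in range(K)]
        lines = [
            "Harmonic HMM results",
            "=" * 60,
            f"states: {K}   harmonics: {self.model.n_harmonics}   "
            f"oscillators: {'/'.join(self.model.oscillator_set)}",
            f"n_obs: {self.n_obs}   n_params: {self.n_params}",
            f"loglik: {self.loglik:.3f}   AICc: {self.aicc:.3f}   "
            f"converged: {self.converged}",
            "-" * 60,
            f"{'state':<12}{'mean (sqrt-PA)':>16}{'sd':>10}{'pi0':>10}",
        ]
        for k in range(K):
            lines.append(
                f"{names[k]:<12}{self.means[k]:>16.4f}{self.sds[k]:>10.4f}{self.pi0[k]:>10.4f}"
            )
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)

    # -- serialization --------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "n_states": self.model.n_states,
            "n_harmonics": self.model.n_harmonics,
            "oscillator_set": list(self.model.oscillator_set),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "alpha": self.alpha.tolist(),
            "harmonic_coefs": self.harmonic_coefs.tolist(),
            "pi0": self.pi0.tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "flags": self.flags,
            "seed": self.seed,
            "restart_logliks": self.restart_logliks,
            "loglik_trace": self.loglik_trace,
        }
        return json.dumps(payload, indent=1)
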