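"""Bivariate copula regression and cohort-level inference.

Each circadian parameter yields a paired response per subject — its value
on work days and on free days.  The two marginal regressions (on shift
type ShT, age, chronotype score CS, years of night work YNW, and pairwise
interactions) are bound into a joint bivariate model by a copula whose
parameter theta captures the within-subject dependence between work-day
and free-day responses:

    g_work(mu_work) = eta_work = X_work @ beta_work
    g_free(mu_free) = eta_free = X_free @ beta_free

with Gaussian margins, identity or log links, and a Gaussian, Clayton,
Frank or Gumbel copula.  Probability-valued responses (p1-1, RI) enter as
log odds (LOP1-1, LORI).  Estimation is joint maximum likelihood started
from the inference-for-margins (IFM) fit; standard errors come from the
observed information; model selection is greedy backward elimination under
AICc respecting marginality (an interaction keeps both its main effects in
the model).  Covariates are not centred.

The module also wraps the nonparametric group tests used cohort-wide and
the noncentral-t sample-size computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .hhmm import aicc as _aicc

__all__ = [
    "logit_transform",
    "inv_logit",
    "ModelSpec",
    "CopulaRegression",
    "CopulaResults",
    "fit_copula",
    "select_model",
    "wald_z",
    "group_tests",
    "power_sample_size",
    "cohens_d",
]

MAIN_EFFECTS = ("ShT", "Age", "CS", "YNW")
ALL_TERMS = MAIN_EFFECTS + (
    "ShT:Age", "ShT:CS", "ShT:YNW", "Age:CS", "Age:YNW", "CS:YNW",
)


def logit_transform(x, clip: bool = False, eps: float = 1e-6):
    """Log odds log(x / (1 - x)) for responses in (0, 1) (LOP1-1, LORI)."""
    x = np.asarray(x, dtype=float)
    if clip:
        x = np.clip(x, eps, 1 - eps)
    if np.any((x <= 0) | (x >= 1)):
        raise ValueError("logit requires values strictly inside (0, 1)")
    return np.log(x / (1 - x))


def inv_logit(z):
    z = np.asarray(z, dtype=float)
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class ModelSpec:
    """Terms and links of the two margins.

    Terms are drawn from ShT, Age, CS, YNW and their pairwise interactions
    ("A:B"); an interaction requires both main effects (marginality).
    """

    response: str
    terms_work: tuple[str, ...] = ALL_TERMS
    terms_free: tuple[str, ...] = ALL_TERMS
    link_work: str = "identity"
    link_free: str = "identity"

    def __post_init__(self) -> None:
        for terms in (self.terms_work, self.terms_free):
            for t in terms:
                if ":" in t:
                    a, b = t.split(":")
                    if a not in terms or b not in terms:
                        raise ValueError(
                            f"interaction {t} requires both main effects in the margin"
                        )
                elif t not in MAIN_EFFECTS:
                    raise ValueError(f"unknown term {t!r}")
        for link in (self.link_work, self.link_free):
            if link not in ("identity", "log"):
                raise ValueError(f"unsupported link {link!r}")

    def drop(self, margin: str, term: str) -> "ModelSpec":
        terms = list(self.terms_work if margin == "work" else self.terms_free)
        terms.remove(term)
        kw = {"terms_work": tuple(terms)} if margin == "work" else {"terms_free": tuple(terms)}
        return ModelSpec(response=self.response,
                         terms_work=kw.get("terms_work", self.terms_work),
                         terms_free=kw.get("terms_free", self.terms_free),
                         link_work=self.link_work, link_free=self.link_free)

    def droppable(self, margin: str) -> list[str]:
        """Terms removable without violating marginality."""
        terms = self.terms_work if margin == "work" else self.terms_free
        inter = [t for t in terms if ":" in t]
        out = list(inter)
        for t in terms:
            if ":" not in t and not any(t in i.split(":") for i in inter):
                out.append(t)
        return out


def build_design(data: pd.DataFrame, terms: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    """Intercept + main effects + product interactions, uncentred."""
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            cols.append(data[a].to_numpy(float) * data[b].to_numpy(float))
        else:
            cols.append(data[t].to_numpy(float))
        names.append(t)
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# Copula log-densities on (u1, u2) in (0,1)^2, with an unconstrained raw
# parameterization mapped into each family's admissible range.
# ---------------------------------------------------------------------------

_EPS_U = 1e-10


def _theta_from_raw(family: str, raw: float) -> float:
    if family == "gaussian":
        return float(np.tanh(raw))
    if family == "clayton":
        return float(np.exp(raw))
    if family == "frank":
        return float(raw)
    if family == "gumbel":
        return float(1.0 + np.exp(raw))
    raise ValueError(f"unknown copula family {family!r}")


def _raw_from_theta(family: str, theta: float) -> float:
    if family == "gaussian":
        return float(np.arctanh(np.clip(theta, -0.999, 0.999)))
    if family == "clayton":
        return float(np.log(max(theta, 1e-6)))
    if family == "frank":
        return float(theta)
    if family == "gumbel":
        return float(np.log(max(theta - 1.0, 1e-6)))
    raise ValueError(f"unknown copula family {family!r}")


def copula_logpdf(u1: np.ndarray, u2: np.ndarray, family: str, theta: float) -> np.ndarray:
    u1 = np.clip(u1, _EPS_U, 1 - _EPS_U)
    u2 = np.clip(u2, _EPS_U, 1 - _EPS_U)
    if family == "gaussian":
        th = np.clip(theta, -0.9999, 0.9999)
        q1, q2 = stats.norm.ppf(u1), stats.norm.ppf(u2)
        om = 1 - th**2
        return (-0.5 * np.log(om)
                - (th**2 * (q1**2 + q2**2) - 2 * th * q1 * q2) / (2 * om))
    if family == "clayton":
        th = max(theta, 1e-8)
        lu, lv = np.log(u1), np.log(u2)
        s = u1 ** (-th) + u2 ** (-th) - 1.0
        return (np.log1p(th) - (1 + th) * (lu + lv)
                - (2 + 1 / th) * np.log(s))
    if family == "frank":
        th = theta
        if abs(th) < 1e-6:
            return np.zeros_like(u1)
        em1 = -np.expm1(-th)  # 1 - e^{-theta}
        num = np.log(abs(th)) + np.log(em1) - th * (u1 + u2)
        den = em1 - (-np.expm1(-th * u1)) * (-np.expm1(-th * u2))
        return num - 2 * np.log(np.abs(den))
    if family == "gumbel":
        th = max(theta, 1.0 + 1e-8)
        x, y = -np.log(u1), -np.log(u2)
        A = x**th + y**th
        logC = -(A ** (1 / th))
        return (logC - np.log(u1) - np.log(u2) + (th - 1) * (np.log(x) + np.log(y))
                + (2 / th - 2) * np.log(A) + np.log1p((th - 1) * A ** (-1 / th)))
    raise ValueError(f"unknown copula family {family!r}")


def kendalls_tau(family: str, theta: float) -> float:
    """Closed-form Kendall's tau (numeric Debye integral for Frank)."""
    if family == "gaussian":
        return float(2 * np.arcsin(theta) / np.pi)
    if family == "clayton":
        return float(theta / (theta + 2))
    if family == "gumbel":
        return float(1 - 1 / theta)
    if family == "frank":
        if abs(theta) < 1e-8:
            return 0.0
        from scipy.integrate import quad

        debye, _ = quad(lambda t: t / np.expm1(t), 0, theta)
        return float(1 + 4 * (debye / theta - 1) / theta)
    raise ValueError(f"unknown copula family {family!r}")


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class CopulaRegression:
    """Bivariate copula regression model for paired work/free responses.

    Parameters
    ----------
    y_work, y_free : response vectors (already transformed, e.g. log odds).
    data : DataFrame with the covariate columns ShT, Age, CS, YNW.
    spec : ModelSpec giving the terms and links per margin.
    copula : 'gaussian' | 'clayton' | 'frank' | 'gumbel' | 'independence'.
    """

    def __init__(self, y_work, y_free, data: pd.DataFrame, spec: ModelSpec,
                 copula: str = "gaussian"):
        self.y1 = np.asarray(y_work, dtype=float)
        self.y2 = np.asarray(y_free, dtype=float)
        self.data = data.reset_index(drop=True)
        self.spec = spec
        self.copula = copula
        ok = ~(np.isnan(self.y1) | np.isnan(self.y2)
               | self.data[list(MAIN_EFFECTS)].isna().any(axis=1).to_numpy())
        self.y1, self.y2 = self.y1[ok], self.y2[ok]
        self.data = self.data.loc[ok].reset_index(drop=True)
        self.X1, self.names1 = build_design(self.data, spec.terms_work)
        self.X2, self.names2 = build_design(self.data, spec.terms_free)
        self.n = len(self.y1)
        self.n_params = (self.X1.shape[1] + self.X2.shape[1] + 2
                         + (0 if copula == "independence" else 1))
        if self.n < 10 * max(self.X1.shape[1], self.X2.shape[1]):
            warnings.warn(
                f"only {self.n} complete cases for "
                f"{max(self.X1.shape[1], self.X2.shape[1])} coefficients"
            )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, work_col: str, free_col: str,
                       spec: ModelSpec, copula: str = "gaussian") -> "CopulaRegression":
        return cls(data[work_col], data[free_col], data, spec, copula)

    # -- likelihood ----------------------------------------------------------

    def _margin(self, X, beta, log_sigma, y, link):
        eta = X @ beta
        mu = np.exp(eta) if link == "log" else eta
        sigma = np.exp(log_sigma)
        z = (y - mu) / sigma
        logf = -0.5 * z**2 - log_sigma - 0.5 * np.log(2 * np.pi)
        u = stats.norm.cdf(z)
        return logf, u

    def _unpack(self, params):
        p1, p2 = self.X1.shape[1], self.X2.shape[1]
        beta1 = params[:p1]
        beta2 = params[p1:p1 + p2]
        ls1, ls2 = params[p1 + p2], params[p1 + p2 + 1]
        raw = params[p1 + p2 + 2] if self.copula != "independence" else None
        return beta1, beta2, ls1, ls2, raw

    def loglike(self, params: np.ndarray) -> float:
        beta1, beta2, ls1, ls2, raw = self._unpack(params)
        lf1, u1 = self._margin(self.X1, beta1, ls1, self.y1, self.spec.link_work)
        lf2, u2 = self._margin(self.X2, beta2, ls2, self.y2, self.spec.link_free)
        ll = lf1.sum() + lf2.sum()
        if raw is not None:
            theta = _theta_from_raw(self.copula, raw)
            ll += copula_logpdf(u1, u2, self.copula, theta).sum()
        return float(ll)

    # -- estimation ----------------------------------------------------------

    def _ifm_start(self) -> np.ndarray:
        """Inference-for-margins start: margins fitted separately, then the
        copula parameter profiled on the PIT residuals."""
        import statsmodels.api as sm

        parts = []
        us = []
        for X, y, link in ((self.X1, self.y1, self.spec.link_work),
                           (self.X2, self.y2, self.spec.link_free)):
            if link == "log":
                glm = sm.GLM(y, X, family=sm.families.Gaussian(sm.families.links.Log()))
                res = glm.fit()
                mu = res.fittedvalues
                beta = res.params
            else:
                res = sm.OLS(y, X).fit()
                mu = res.fittedvalues
                beta = res.params
            resid = y - mu
            sigma = max(resid.std(ddof=X.shape[1]), 1e-6)
            parts.append((beta, np.log(sigma)))
            us.append(stats.norm.cdf(resid / sigma))
        x0 = np.concatenate([parts[0][0], parts[1][0],
                             [parts[0][1], parts[1][1]]])
        if self.copula == "independence":
            return x0
        grid = np.linspace(-2, 2, 41)
        lls = [copula_logpdf(us[0], us[1], self.copula, _theta_from_raw(self.copula, r)).sum()
               for r in grid]
        return np.r_[x0, grid[int(np.argmax(lls))]]

    def fit(self, maxiter: int = 500) -> "CopulaResults":
        x0 = self._ifm_start()
        res = optimize.minimize(lambda p: -self.loglike(p), x0, method="BFGS",
                                options={"maxiter": maxiter, "gtol": 1e-6})
        flags = []
        if not res.success:
            flags.append(f"non-convergence:{res.message}")
        params = res.x
        from statsmodels.tools.numdiff import approx_hess

        H = approx_hess(params, lambda p: -self.loglike(p))
        try:
            cov = np.linalg.inv(H)
            bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            cov = np.full((len(params), len(params)), np.nan)
            bse = np.full(len(params), np.nan)
            flags.append("singular-information")
        beta1, beta2, ls1, ls2, raw = self._unpack(params)
        theta = None if raw is None else _theta_from_raw(self.copula, raw)
        if theta is not None:
            if self.copula == "gaussian" and abs(theta) > 0.995:
                flags.append("theta-at-boundary")
            if self.copula == "gumbel" and theta > 50:
                flags.append("theta-at-boundary")
        return CopulaResults(
            model=self, params=params, bse=bse, cov=cov,
            loglik=float(-res.fun), theta=theta, flags=flags,
        )


@dataclass
class CopulaResults:
    """Joint ML fit of the bivariate copula regression."""

    model: CopulaRegression
    params: np.ndarray
    bse: np.ndarray
    cov: np.ndarray
    loglik: float
    theta: float | None
    flags: list[str] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return self.model.n_params

    @property
    def aicc(self) -> float:
        return _aicc(self.loglik, self.n_params, self.model.n)

    @property
    def tau(self) -> float | None:
        if self.theta is None:
            return None
        return kendalls_tau(self.model.copula, self.theta)

    def _coef_names(self) -> list[str]:
        m = self.model
        names = [f"work:{n}" for n in m.names1] + [f"free:{n}" for n in m.names2]
        names += ["log_sigma_work", "log_sigma_free"]
        if m.copula != "independence":
            names += [f"theta_raw({m.copula})"]
        return names

    def coef_table(self) -> pd.DataFrame:
        """Estimates, standard errors and two-sided Wald z-tests, in the
        layout of a standard regression coefficient table."""
        est = self.params
        se = self.bse
        with np.errstate(divide="ignore", invalid="ignore"):
            z = est / se
        p = 2 * stats.norm.sf(np.abs(z))
        tab = pd.DataFrame({
            "Estimate": est, "Std.Error": se, "z-value": z, "Pr(>|z|)": p,
        }, index=self._coef_names())
        tab.loc[np.asarray(se) == 0, "z-value"] = np.nan
        return tab

    def summary(self) -> str:
        m = self.model
        lines = [
            "Bivariate copula regression results",
            "=" * 64,
            f"response: {m.spec.response}   copula: {m.copula}   n: {m.n}",
            f"links: work={m.spec.link_work}, free={m.spec.link_free}",
            f"loglik: {self.loglik:.3f}   AICc: {self.aicc:.3f}   "
            f"theta: {self.theta if self.theta is None else round(self.theta, 4)}"
            + (f"   Kendall tau: {self.tau:.4f}" if self.theta is not None else ""),
            "-" * 64,
            self.coef_table().to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)


def fit_copula(spec: ModelSpec, data: pd.DataFrame, work_col: str, free_col: str,
               copula_family: str = "gaussian") -> CopulaResults:
    """Convenience wrapper: build and fit the bivariate model."""
    return CopulaRegression.from_dataframe(data, work_col, free_col, spec,
                                           copula_family).fit()


def _ifm_loglik(model: CopulaRegression) -> float:
    """Log-likelihood at the IFM estimate (margins + profiled theta) —
    the fast surrogate used inside the backward search."""
    return model.loglike(model._ifm_start())


def select_model(
    data: pd.DataFrame,
    work_col: str,
    free_col: str,
    response: str,
    copula_family: str = "gaussian",
    links: tuple[str, str] = ("identity", "identity"),
    full_terms: tuple[str, ...] = ALL_TERMS,
    log: list[str] | None = None,
) -> CopulaResults:
    """Greedy backward elimination from the full 10-term model per margin,
    respecting marginality, minimizing AICc.

    For speed the search scores candidates at their IFM estimates; the
    winning specification is refitted by joint ML.  Ties in AICc go to the
    model with fewer parameters.
    """
    spec = ModelSpec(response=response, terms_work=full_terms, terms_free=full_terms,
                     link_work=links[0], link_free=links[1])

    def score(sp: ModelSpec) -> tuple[float, int]:
        m = CopulaRegression.from_dataframe(data, work_col, free_col, sp, copula_family)
        return _aicc(_ifm_loglik(m), m.n_params, m.n), m.n_params

    cur_aicc, cur_k = score(spec)
    if log is not None:
        log.append(f"start: AICc={cur_aicc:.3f} k={cur_k} {spec.terms_work}|{spec.terms_free}")
    improved = True
    while improved:
        improved = False
        best = None
        for margin in ("work", "free"):
            for term in spec.droppable(margin):
                cand = spec.drop(margin, term)
                a, k = score(cand)
                if best is None or (a, k) < best[0]:
                    best = ((a, k), cand, margin, term)
        if best is not None and (best[0][0] < cur_aicc
                                 or (best[0][0] == cur_aicc and best[0][1] < cur_k)):
            (cur_aicc, cur_k), spec, margin, term = best
            improved = True
            if log is not None:
                log.append(f"drop {margin}:{term} -> AICc={cur_aicc:.3f} k={cur_k}")
    if log is not None:
        log.append(f"final: {spec.terms_work}|{spec.terms_free}")
    return CopulaRegression.from_dataframe(data, work_col, free_col, spec,
                                           copula_family).fit()


def wald_z(fit: CopulaResults) -> pd.DataFrame:
    """Coefficient table (estimate, SE, z = estimate/SE, two-sided p)."""
    return fit.coef_table()


def group_tests(values, grouping=None, paired: bool = False,
                kind: str = "mann_whitney") -> tuple[float, float]:
    """Thin wrappers around the standard nonparametric tests.

    kind:
      mann_whitney        values + 2-level grouping (independent samples)
      wilcoxon_signed_rank paired (x, y) in ``values``
      spearman            (x, y) in ``values`` -> (rho, p)
      kruskal_wallis      values + multi-level grouping
      chi_square          contingency table in ``values``
    Returns (statistic, p-value).
    """
    if kind == "mann_whitney":
        g = np.asarray(grouping)
        levels = np.unique(g)
        if len(levels) != 2:
            raise ValueError("mann_whitney needs exactly 2 groups")
        x = np.asarray(values)[g == levels[0]]
        y = np.asarray(values)[g == levels[1]]
        r = stats.mannwhitneyu(x, y, alternative="two-sided")
    elif kind == "wilcoxon_signed_rank":
        x, y = values
        if np.allclose(np.asarray(x), np.asarray(y)):
            return 0.0, 1.0  # no differences: nothing to rank
        r = stats.wilcoxon(np.asarray(x), np.asarray(y))
    elif kind == "spearman":
        x, y = values
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)
    elif kind == "kruskal_wallis":
        g = np.asarray(grouping)
        groups = [np.asarray(values)[g == lev] for lev in np.unique(g)]
        if len(groups) < 2:
            raise ValueError("kruskal_wallis needs >= 2 groups")
        r = stats.kruskal(*groups)
    elif kind == "chi_square":
        r = stats.chi2_contingency(np.asarray(values))
        return float(r.statistic), float(r.pvalue)
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    return float(r.statistic), float(r.pvalue)


def power_sample_size(d: float, alpha: float = 0.05, power: float = 0.80,
                      n_max: int = 100000) -> int:
    """Smallest per-group n for a two-sided two-sample t-test to reach the
    requested power at effect size Cohen's d, via the noncentral t."""
    if d <= 0:
        raise ValueError("effect size must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1 or power <= alpha:
        raise ValueError("need 0 < alpha < power < 1")
    for n in range(2, n_max):
        df = 2 * n - 2
        nc = d * np.sqrt(n / 2)
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        pw = (1 - stats.nct.cdf(tcrit, df, nc)) + stats.nct.cdf(-tcrit, df, nc)
        if pw >= power:
            return n
    raise RuntimeError("sample size exceeds n_max")


def cohens_d(delta: float, sd: float) -> float:
    """Standardized mean difference delta / sd."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return delta / sd
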