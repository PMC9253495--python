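"""Copula regression, transforms, group tests, power computation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circarest.regression import (
    CopulaRegression,
    ModelSpec,
    cohens_d,
    copula_logpdf,
    fit_copula,
    group_tests,
    inv_logit,
    kendalls_tau,
    logit_transform,
    power_sample_size,
    select_model,
    wald_z,
)


def simulate_paired(n=140, beta_sht_work=-0.35, theta=0.5, seed=0,
                    sigma=0.3):
    """Paired work/free responses from a Gaussian-copula model with
    covariate ranges matching the cohort questionnaire."""
    rng = np.random.default_rng(seed)
    data = pd.DataFrame({
        "ShT": rng.integers(0, 2, n).astype(float),
        "Age": rng.uniform(22, 62, n),
        "CS": rng.uniform(24, 74, n),
        "YNW": rng.uniform(0, 35, n),
    })
    mu_w = 3.3 + beta_sht_work * data["ShT"] - 0.009 * data["Age"]
    mu_f = 2.95 - 0.24 * data["ShT"]
    z = rng.multivariate_normal([0, 0], [[1, theta], [theta, 1]], size=n)
    y_w = mu_w + sigma * z[:, 0]
    y_f = mu_f + sigma * z[:, 1]
    return data, y_w.to_numpy(), y_f.to_numpy()


class TestLogit:
    def test_midpoint(self):
        assert logit_transform(0.5) == pytest.approx(0.0)

    def test_ln24(self):
        assert logit_transform(0.96) == pytest.approx(np.log(24), abs=1e-12)
        assert logit_transform(0.96) == pytest.approx(3.178, abs=1e-3)

    def test_inverse_of_printed_intercept(self):
        assert inv_logit(2.951) == pytest.approx(0.950, abs=5e-4)

    @pytest.mark.parametrize("x", [0.0, 1.0, -0.1, 1.5])
    def test_boundary_rejected_without_clip(self, x):
        with pytest.raises(ValueError):
            logit_transform(x)

    def test_clip_option(self):
        assert np.isfinite(logit_transform(1.0, clip=True))


class TestCopulaDensities:
    @pytest.mark.parametrize("family, theta", [
        ("gaussian", 0.5), ("clayton", 2.0), ("frank", 4.0), ("gumbel", 1.8)])
    def test_density_integrates_to_one(self, family, theta):
        u = np.linspace(0.005, 0.995, 100)
        U, V = np.meshgrid(u, u)
        c = np.exp(copula_logpdf(U.ravel(), V.ravel(), family, theta))
        integral = c.mean()  # uniform grid on the unit square
        assert integral == pytest.approx(1.0, abs=0.05)

    def test_gaussian_zero_theta_is_independence(self):
        u = np.random.default_rng(0).uniform(0.01, 0.99, 50)
        v = np.random.default_rng(1).uniform(0.01, 0.99, 50)
        np.testing.assert_allclose(copula_logpdf(u, v, "gaussian", 0.0), 0.0,
                                   atol=1e-12)

    def test_kendall_tau_closed_forms(self):
        assert kendalls_tau("gaussian", 0.5) == pytest.approx(1 / 3)
        assert kendalls_tau("clayton", 2.0) == pytest.approx(0.5)
        assert kendalls_tau("gumbel", 2.0) == pytest.approx(0.5)
        assert kendalls_tau("frank", 0.0) == 0.0


class TestModelSpec:
    def test_marginality_enforced(self):
        with pytest.raises(ValueError, match="marginality|main effects"):
            ModelSpec(response="x", terms_work=("ShT", "ShT:Age"),
                      terms_free=("ShT",))

    def test_droppable_respects_marginality(self):
        spec = ModelSpec(response="x", terms_work=("ShT", "Age", "ShT:Age"),
                         terms_free=("ShT",))
        d = spec.droppable("work")
        assert "ShT:Age" in d and "ShT" not in d and "Age" not in d


class TestCopulaRegression:
    def test_independence_fit_factorizes(self):
        """With the copula dropped the joint loglik equals the sum of the
        two separately fitted Gaussian margins."""
        import statsmodels.api as sm

        data, yw, yf = simulate_paired(n=120, theta=0.0, seed=2)
        spec = ModelSpec(response="t", terms_work=("ShT", "Age", "CS", "YNW"),
                         terms_free=("ShT", "Age", "CS", "YNW"))
        model = CopulaRegression(yw, yf, data, spec, copula="independence")
        fit = model.fit()
        ll = 0.0
        for y, X in ((yw, model.X1), (yf, model.X2)):
            res = sm.OLS(y, X).fit()
            sig2 = (res.resid**2).mean()
            ll += (-0.5 * len(y) * np.log(2 * np.pi * sig2)
                   - 0.5 * (res.resid**2).sum() / sig2)
        assert fit.loglik == pytest.approx(ll, abs=1e-4)

    def test_theta_recovery_and_tau(self):
        data, yw, yf = simulate_paired(n=300, theta=0.5, seed=3)
        spec = ModelSpec(response="t", terms_work=("ShT", "Age"),
                         terms_free=("ShT",))
        fit = CopulaRegression(yw, yf, data, spec).fit()
        assert fit.theta == pytest.approx(0.5, abs=0.12)
        assert fit.tau == pytest.approx(1 / 3, abs=0.09)

    def test_beta_recovery_within_2se(self):
        hits = 0
        for seed in range(5):
            data, yw, yf = simulate_paired(seed=seed)
            spec = ModelSpec(response="t",
                             terms_work=("ShT", "Age", "CS", "YNW"),
                             terms_free=("ShT", "Age", "CS", "YNW"))
            fit = CopulaRegression(yw, yf, data, spec).fit()
            i = fit._coef_names().index("work:ShT")
            hits += abs(fit.params[i] - (-0.35)) <= 2 * fit.bse[i]
        assert hits >= 4

    def test_small_sample_warns(self):
        data, yw, yf = simulate_paired(n=30, seed=4)
        spec = ModelSpec(response="t", terms_work=("ShT", "Age", "CS", "YNW"),
                         terms_free=("ShT", "Age", "CS", "YNW"))
        with pytest.warns(UserWarning, match="complete cases"):
            CopulaRegression(yw, yf, data, spec)

    def test_summary_structure(self):
        data, yw, yf = simulate_paired(n=120, seed=5)
        spec = ModelSpec(response="LOP1-1", terms_work=("ShT",), terms_free=("ShT",))
        fit = CopulaRegression(yw, yf, data, spec).fit()
        s = fit.summary()
        assert "LOP1-1" in s and "Kendall tau" in s and "work:ShT" in s


class TestSelectModel:
    def test_backward_search_finds_sparse_truth(self):
        """Only ShT (work) and ShT (free) matter: the search keeps ShT and
        drops most noise terms in the majority of replicates."""
        wins = 0
        for seed in range(6):
            data, yw, yf = simulate_paired(n=140, seed=10 + seed)
            data["_yw"], data["_yf"] = yw, yf
            path: list[str] = []
            fit = select_model(data, "_yw", "_yf", response="t", log=path)
            tw, tf = fit.model.spec.terms_work, fit.model.spec.terms_free
            wins += ("ShT" in tw) and ("ShT" in tf) and (len(tw) + len(tf) <= 8)
            assert path[0].startswith("start")
        assert wins >= 5

    def test_single_term_model_returned_intact(self):
        data, yw, yf = simulate_paired(n=120, seed=20)
        data["_yw"], data["_yf"] = yw, yf
        fit = select_model(data, "_yw", "_yf", response="t",
                           full_terms=("ShT",))
        assert fit.model.spec.terms_work in ((), ("ShT",))


class TestWaldZ:
    def test_table_consistency_on_fit(self):
        data, yw, yf = simulate_paired(n=120, seed=6)
        spec = ModelSpec(response="t", terms_work=("ShT",), terms_free=("ShT",))
        fit = CopulaRegression(yw, yf, data, spec).fit()
        tab = wald_z(fit)
        np.testing.assert_allclose(tab["z-value"],
                                   tab["Estimate"] / tab["Std.Error"])
        np.testing.assert_allclose(tab["Pr(>|z|)"],
                                   2 * stats.norm.sf(np.abs(tab["z-value"])))

    def test_printed_night_shift_row(self):
        """The night-shift effect on work-day rest quality: z = beta/SE."""
        assert -0.350 / 0.073 == pytest.approx(-4.783, abs=0.02)

    @pytest.mark.parametrize("ratio, p", [(1.96, 0.05), (0.0, 1.0)])
    def test_z_to_p(self, ratio, p):
        assert 2 * stats.norm.sf(abs(ratio)) == pytest.approx(p, abs=1e-3)


class TestGroupTests:
    def test_wilcoxon_identical_samples(self):
        x = np.arange(10.0)
        stat, p = group_tests((x, x.copy()), paired=True,
                              kind="wilcoxon_signed_rank")
        assert p == 1.0

    def test_mann_whitney_shifted_samples(self):
        rng = np.random.default_rng(1)
        vals = np.r_[rng.normal(0, 1, 60), rng.normal(1.5, 1, 60)]
        groups = np.r_[np.zeros(60), np.ones(60)]
        _, p = group_tests(vals, groups, kind="mann_whitney")
        assert p < 0.001

    def test_spearman_perfect_monotone(self):
        x = np.arange(20.0)
        rho, p = group_tests((x, np.exp(x / 5)), kind="spearman")
        assert rho == pytest.approx(1.0)

    def test_kruskal_wallis_three_groups(self):
        rng = np.random.default_rng(2)
        vals = np.r_[rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(3, 1, 30)]
        groups = np.repeat([0, 1, 2], 30)
        _, p = group_tests(vals, groups, kind="kruskal_wallis")
        assert p < 0.001

    def test_chi_square_contingency(self):
        stat, p = group_tests(np.array([[30, 10], [10, 30]]), kind="chi_square")
        assert p < 0.001

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown test"):
            group_tests([1, 2], kind="median")


class TestPower:
    def test_medium_effect_gives_64(self):
        assert power_sample_size(0.5, 0.05, 0.80) == 64

    def test_large_effect_gives_17(self):
        assert power_sample_size(1.0, 0.05, 0.80) == 17

    def test_power_increases_with_n(self):
        assert power_sample_size(0.5, 0.05, 0.90) > 64

    @pytest.mark.parametrize("d,alpha,power", [(0, 0.05, 0.8), (0.5, 0.9, 0.5)])
    def test_invalid_inputs(self, d, alpha, power):
        with pytest.raises(ValueError):
            power_sample_size(d, alpha, power)

    def test_cohens_d_from_study_quantities(self):
        assert cohens_d(0.015, 0.03) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            cohens_d(0.1, 0.0)
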