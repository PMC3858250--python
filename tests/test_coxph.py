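"""Cox fitting: brute-force partial-likelihood oracle, cross-checks, invariants."""

import numpy as np
import pandas as pd
import pytest

from mrsig.containers import outcomes_to_arrays
from mrsig.coxph import cox_multivariate, cox_score_statistic, cox_univariate, screen_cox

from conftest import make_outcomes, random_survival


def efron_loglik(beta_grid, x, time, event):
    """Direct evaluation of the Efron partial log-likelihood on a beta grid.

    Written independently of the fitting code: explicit loops over distinct
    event times and tied death sets.
    """
    beta_grid = np.atleast_1d(beta_grid)
    ll = np.zeros_like(beta_grid, dtype=float)
    for k, u in enumerate(np.unique(time[event == 1])):
        risk = x[time >= u]
        deaths = x[(time == u) & (event == 1)]
        d = len(deaths)
        ll += beta_grid * deaths.sum()
        e_risk = np.exp(np.outer(beta_grid, risk)).sum(axis=1)
        e_dead = np.exp(np.outer(beta_grid, deaths)).sum(axis=1)
        for r in range(d):
            ll -= np.log(e_risk - (r / d) * e_dead)
    return ll


def grid_argmax_beta(x, time, event, lo=-5.0, hi=5.0, step=1e-4):
    grid = np.arange(lo, hi + step, step)
    return grid[np.argmax(efron_loglik(grid, x, time, event))]


class TestUnivariateOracle:
    def test_six_sample_binary_instance_matches_grid_search(self):
        # interleaved group labels keep the maximizer interior
        time = np.array([1.0, 2, 3, 4, 5, 6])
        event = np.ones(6, dtype=int)
        x = np.array([1.0, 0, 1, 0, 1, 0])
        fit = cox_univariate(x, make_outcomes(time, event))
        oracle = grid_argmax_beta(x, time, event)
        assert abs(fit.beta - oracle) < 1e-3

    @pytest.mark.parametrize("seed", range(25))
    def test_random_small_instances_match_grid_search(self, seed):
        """Newton-Raphson equals exhaustive grid maximization on <=8 samples."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        x = rng.standard_normal(n).round(2)
        time = rng.choice([1.0, 2.0, 3.0, 4.0], size=n)  # deliberate ties
        event = rng.integers(0, 2, n)
        if event.sum() < 2:
            event[:2] = 1
        fit = cox_univariate(x, make_outcomes(time, event))
        if not fit.converged or abs(fit.beta) > 4.5:
            return  # separation: grid oracle is capped at +-5 anyway
        oracle = grid_argmax_beta(x, time, event)
        assert abs(fit.beta - oracle) < 1e-3

    def test_matches_lifelines_on_moderate_data(self):
        rng = np.random.default_rng(10)
        x, outcomes = random_survival(rng, 120, beta=0.6)
        fit = cox_univariate(x, outcomes)
        from lifelines import CoxPHFitter

        _, time, event, _ = outcomes_to_arrays(outcomes)
        cf = CoxPHFitter().fit(pd.DataFrame({"T": time, "E": event, "x": x}), "T", "E")
        assert fit.beta == pytest.approx(cf.params_["x"], abs=1e-6)
        assert fit.se == pytest.approx(cf.standard_errors_["x"], abs=1e-6)


class TestDegenerateAndErrors:
    def test_constant_covariate_is_degenerate(self):
        fit = cox_univariate(np.ones(6), make_outcomes([1, 2, 3, 4, 5, 6], [1] * 6))
        assert fit.degenerate
        assert fit.beta == 0.0 and fit.p == 1.0 and np.isinf(fit.se)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            cox_univariate(np.arange(4.0), make_outcomes([1, 2, 3, 4], [0, 0, 0, 0]))


class TestInvariances:
    def test_time_rescaling_leaves_fit_unchanged(self):
        rng = np.random.default_rng(2)
        x, outcomes = random_survival(rng, 60, beta=0.5)
        _, time, event, _ = outcomes_to_arrays(outcomes)
        fit1 = cox_univariate(x, outcomes)
        fit2 = cox_univariate(x, make_outcomes(time * 12.0, event))
        assert fit1.beta == pytest.approx(fit2.beta, abs=1e-12)
        assert fit1.p == pytest.approx(fit2.p, abs=1e-12)

    def test_covariate_scaling_equivariance(self):
        rng = np.random.default_rng(3)
        x, outcomes = random_survival(rng, 60, beta=0.5)
        fit1 = cox_univariate(x, outcomes)
        fit2 = cox_univariate(2.5 * x, outcomes)
        assert fit2.beta == pytest.approx(fit1.beta / 2.5, rel=1e-8)
        assert fit2.z == pytest.approx(fit1.z, rel=1e-8)
        assert fit2.p == pytest.approx(fit1.p, rel=1e-8)

    def test_batch_screen_agrees_with_single_fits(self):
        rng = np.random.default_rng(4)
        n, G = 50, 6
        X = rng.standard_normal((n, G))
        _, outcomes = random_survival(rng, n, beta=0.0)
        _, time, event, _ = outcomes_to_arrays(outcomes)
        batch = screen_cox(X, time, event, [f"g{i}" for i in range(G)])
        for j, res in enumerate(batch):
            single = cox_univariate(X[:, j], outcomes)
            assert res.beta == pytest.approx(single.beta, abs=1e-9)
            assert res.p == pytest.approx(single.p, abs=1e-9)


class TestScoreStatistic:
    def test_score_statistic_matches_chi2_of_null_wald_asymptotics(self):
        # score statistic at beta=0 should be close to z^2 for weak effects
        rng = np.random.default_rng(5)
        x, outcomes = random_survival(rng, 200, beta=0.1)
        _, time, event, _ = outcomes_to_arrays(outcomes)
        stat = cox_score_statistic(x, time, event)
        fit = cox_univariate(x, outcomes)
        assert stat == pytest.approx(fit.z**2, rel=0.2)

    def test_constant_covariate_gives_zero(self):
        assert cox_score_statistic(
            np.ones(5), np.arange(1.0, 6.0), np.ones(5, dtype=int)
        ) == 0.0


class TestMultivariate:
    def test_single_covariate_reduces_to_univariate(self):
        rng = np.random.default_rng(6)
        x, outcomes = random_survival(rng, 80, beta=0.4)
        uni = cox_univariate(x, outcomes)
        multi = cox_multivariate(x[:, None], outcomes, names=("x",))
        assert multi.beta[0] == pytest.approx(uni.beta, abs=1e-10)
        assert multi.se[0] == pytest.approx(uni.se, abs=1e-10)

    def test_collinear_design_rejected_with_names(self):
        rng = np.random.default_rng(7)
        x, outcomes = random_survival(rng, 40, beta=0.0)
        X = np.column_stack([x, x])
        with pytest.raises(ValueError, match="collinear"):
            cox_multivariate(X, outcomes, names=("a", "b"))

    def test_two_planted_covariates_recovered(self):
        """log-HRs 0.7 and 0.4 on independent covariates recovered within 3 se."""
        rng = np.random.default_rng(8)
        n = 500
        X = rng.standard_normal((n, 2))
        t = rng.exponential(np.exp(-(0.7 * X[:, 0] + 0.4 * X[:, 1])))
        c = rng.exponential(2.0, n)
        outcomes = make_outcomes(np.minimum(t, c), (t <= c).astype(int))
        fit = cox_multivariate(X, outcomes, names=("a", "b"))
        for j, true in enumerate((0.7, 0.4)):
            assert abs(fit.beta[j] - true) < 3 * fit.se[j]
        # Wald CI brackets the hazard-ratio point estimate
        assert np.all(fit.ci_low < fit.hr) and np.all(fit.hr < fit.ci_high)

    def test_matches_lifelines_two_covariates(self):
        rng = np.random.default_rng(9)
        n = 100
        X = rng.standard_normal((n, 2))
        _, outcomes = random_survival(rng, n, beta=0.0)
        _, time, event, _ = outcomes_to_arrays(outcomes)
        fit = cox_multivariate(X, outcomes, names=("a", "b"))
        from lifelines import CoxPHFitter

        df = pd.DataFrame({"T": time, "E": event, "a": X[:, 0], "b": X[:, 1]})
        cf = CoxPHFitter().fit(df, "T", "E")
        assert fit.beta == pytest.approx(cf.params_.to_numpy(), abs=1e-6)
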