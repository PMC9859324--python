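"""Gibbs samplers, DIC, adjusted R^2 and the Moran model gate."""

import numpy as np
import pytest

from oxylife import bayes
from oxylife.spatial import MoranResult, inverse_distance_weights
from oxylife.synthetic import SyntheticConfig, generate_regions


def _sim_iid(rng, n=120, beta=(0.5, -1.2), sigma=1.0):
    X = rng.normal(size=(n, len(beta)))
    y = 2.0 + X @ np.array(beta) + rng.normal(0, sigma, n)
    return y, X


class TestIIDFit:
    def test_flat_prior_matches_least_squares(self, rng):
        """With essentially flat coefficient priors and the noise precision
        fixed at truth, the posterior mean equals the OLS solution."""
        y, X = _sim_iid(rng)
        spec = bayes.ModelSpec(model="iid", n_chains=2, n_iter=6000,
                               n_burnin=1000, seed=4,
                               fixed_tau_coef=1e-10, fixed_tau_v=1.0)
        fit = bayes.fit_iid(y, X, spec)
        Z = np.column_stack([np.ones(len(y)), X])
        ols = np.linalg.lstsq(Z, y, rcond=None)[0]
        assert fit.posterior_mean("alpha") == pytest.approx(ols[0], abs=0.01)
        assert fit.posterior_mean("beta") == pytest.approx(ols[1:], abs=0.01)

    def test_intercept_only_posterior_is_ybar(self, rng):
        y = rng.normal(5.0, 1.0, size=80)
        X = np.empty((80, 0))
        spec = bayes.ModelSpec(model="iid", n_chains=2, n_iter=6000,
                               n_burnin=1000, seed=5,
                               fixed_tau_coef=1e-10, fixed_tau_v=1.0)
        fit = bayes.fit_iid(y, X, spec)
        mc_se = 3 * y.std() / np.sqrt(fit.n_draws / 10)
        assert fit.posterior_mean("alpha") == pytest.approx(y.mean(),
                                                            abs=max(mc_se, 0.02))

    def test_zero_variance_column_rejected(self, rng):
        y, X = _sim_iid(rng, n=40)
        X[:, 1] = 3.0
        with pytest.raises(ValueError, match="zero variance"):
            bayes.fit_iid(y, X, bayes.ModelSpec(model="iid"))

    def test_collinear_design_rejected(self, rng):
        y, X = _sim_iid(rng, n=40)
        X = np.column_stack([X, X[:, 0] * 2.0])
        with pytest.raises(ValueError, match="rank deficient"):
            bayes.fit_iid(y, X, bayes.ModelSpec(model="iid"))

    def test_chain_agreement_and_rhat(self, rng):
        y, X = _sim_iid(rng)
        fits = [bayes.fit_iid(y, X, bayes.ModelSpec(
            model="iid", n_chains=2, n_iter=4000, n_burnin=1000, seed=s))
            for s in (1, 2)]
        b = [f.posterior_mean("beta") for f in fits]
        sd = fits[0].summaries.loc["beta[x0]", "sd"]
        assert np.allclose(b[0], b[1], atol=3 * sd / np.sqrt(600))
        rhats = fits[0].summaries["rhat"].dropna()
        assert (rhats < 1.05).all()


@pytest.fixture(scope="module")
def car_data():
    cfg = SyntheticConfig(n_regions=34, sigma_u=1.0, sigma_v=0.5)
    rt, W, truth = generate_regions(cfg, 20)
    df = rt.df.copy()
    g = df["gdp_per_capita"]
    df["gdp_per_capita"] = (g - g.mean()) / g.std(ddof=1)
    y = df["life_expectancy"].to_numpy()
    X = df[["oxygen", "gdp_per_capita", "health_tech_per_1000"]].to_numpy()
    return y, X, W, truth


class TestCARFit:
    def test_u_draws_sum_to_zero(self, car_data):
        y, X, W, _ = car_data
        fit = bayes.fit_car(y, X, W, bayes.ModelSpec(
            model="car", n_chains=1, n_iter=600, n_burnin=200, seed=0))
        sums = fit.stacked("u").sum(axis=1)
        assert np.abs(sums).max() < 1e-8

    def test_spatial_shrinkage_limit_matches_iid(self, car_data):
        """With the spatial precision pinned huge, u collapses to zero and
        the CAR fit reproduces the IID posterior."""
        y, X, W, _ = car_data
        common = dict(n_chains=2, n_iter=4000, n_burnin=1000, seed=9)
        car = bayes.fit_car(y, X, W, bayes.ModelSpec(
            model="car", fixed_tau_u=1e8, **common))
        iid = bayes.fit_iid(y, X, bayes.ModelSpec(model="iid", **common))
        sd = iid.summaries.loc["beta[x0]", "sd"]
        assert car.posterior_mean("beta") == pytest.approx(
            iid.posterior_mean("beta"), abs=3 * sd / np.sqrt(100))
        assert np.abs(car.posterior_mean("u")).max() < 1e-3

    def test_disconnected_graph_rejected(self, car_data):
        y, X, _, _ = car_data
        W = inverse_distance_weights(
            [(i % 2 * 100.0, i * 0.5) for i in range(len(y))],
            cutoff_km=500)
        with pytest.raises(ValueError, match="connected"):
            bayes.fit_car(y, X, W, bayes.ModelSpec(model="car"))

    def test_recovers_generating_coefficients(self, car_data):
        y, X, W, truth = car_data
        fit = bayes.fit_car(y, X, W, bayes.ModelSpec(
            model="car", n_chains=2, n_iter=3000, n_burnin=1000, seed=2))
        s = fit.summaries
        assert abs(s.loc["beta[x0]", "mean"] - 0.15) < 3 * s.loc["beta[x0]", "sd"]
        assert abs(s.loc["alpha", "mean"] - truth.alpha) < 3 * s.loc["alpha", "sd"]


class TestDIC:
    def test_true_covariate_lowers_dic(self, rng):
        """A strong generating covariate (effect 10 noise SDs over the
        design range) must drop DIC compared to the intercept-only fit."""
        n = 100
        x = rng.normal(size=(n, 1))
        y = 1.0 + 10.0 * x[:, 0] + rng.normal(0, 1.0, n)
        common = dict(n_chains=1, n_iter=2000, n_burnin=500, seed=3)
        with_x = bayes.fit_iid(y, x, bayes.ModelSpec(model="iid", **common))
        without = bayes.fit_iid(y, np.empty((n, 0)),
                                bayes.ModelSpec(model="iid", **common))
        assert with_x.dic < without.dic - 50
        assert with_x.p_d > 0

    def test_refuses_tiny_chains(self, rng):
        y, X = _sim_iid(rng, n=40)
        fit = bayes.fit_iid(y, X, bayes.ModelSpec(
            model="iid", n_chains=1, n_iter=260, n_burnin=200, seed=0))
        with pytest.raises(ValueError, match="100"):
            bayes.dic(fit)


class TestAdjustedR2:
    def test_perfect_fit(self):
        y = np.array([1.0, 2, 3, 4, 5])
        assert bayes.adjusted_r2_score(y, y, p=1) == pytest.approx(1.0)

    def test_constant_fit_negative(self):
        y = np.array([1.0, 2, 3, 4, 5, 6])
        out = bayes.adjusted_r2_score(y, np.full(6, y.mean()), p=2)
        assert out < 0

    def test_hand_computed_example(self):
        y = np.array([1.0, 2, 3, 4, 5])
        mu = np.array([1.1, 1.9, 3.2, 3.8, 5.0])
        assert bayes.adjusted_r2_score(y, mu, p=1) == pytest.approx(
            0.98667, abs=1e-5)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            bayes.adjusted_r2_score([1.0, 2.0], [1.0, 2.0], p=1)


class TestModelGate:
    @pytest.mark.parametrize("p, expected", [
        (0.0004, "car"),     # strong autocorrelation -> spatial model
        (0.238, "iid"),
        (0.05, "iid"),       # boundary is strict
    ])
    def test_gate(self, p, expected):
        moran = MoranResult(I=0.3, expected_I=-1 / 33, p_value=p,
                            n_permutations=9999, seed=0,
                            alternative="greater")
        assert bayes.select_spatial_model(moran) == expected
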