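import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from geoprev import core_io, synthetic
from geoprev import spatial_model as sm
from geoprev.core_io import ClusterRecord
from geoprev.spatial_model import (
    ChainConfig,
    MaternParams,
    Posterior,
    PriorSpec,
    build_covariance,
    compare_models,
    fit_mcmc,
    log_likelihood,
    log_posterior,
    matern_correlation,
    waic,
)


class TestMaternParams:
    def test_kappa_convention(self):
        p = MaternParams(range_rho=10.0, sigma=1.0, nu=1.0)
        assert p.kappa == pytest.approx(math.sqrt(8.0) / 10.0, rel=1e-12)

    @pytest.mark.parametrize(
        "kwargs", [dict(range_rho=0.0), dict(sigma=-1.0), dict(nu=0.0)]
    )
    def test_invalid(self, kwargs):
        base = dict(range_rho=10.0, sigma=1.0, nu=1.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            MaternParams(**base)


class TestMaternCorrelation:
    def test_unit_at_zero(self):
        assert matern_correlation(0.0, MaternParams(5.0, 1.0)) == 1.0

    def test_exponential_special_case(self):
        # nu = 1/2: r(d) = exp(-kappa d); at d = rho, kappa*d = 2
        p = MaternParams(range_rho=7.0, sigma=1.0, nu=0.5)
        assert matern_correlation(7.0, p) == pytest.approx(
            math.exp(-2.0), abs=1e-10
        )
        d = np.linspace(0.0, 40.0, 100)
        np.testing.assert_allclose(
            matern_correlation(d, p), np.exp(-p.kappa * d), atol=1e-10
        )

    def test_range_convention_approximately_point_one(self):
        p = MaternParams(range_rho=10.0, sigma=1.0, nu=1.0)
        r = matern_correlation(10.0, p)
        assert 0.09 <= r <= 0.15
        assert r == pytest.approx(0.1397, abs=5e-4)

    def test_strictly_decreasing_to_zero(self):
        p = MaternParams(range_rho=10.0, sigma=1.0, nu=1.0)
        d = np.linspace(0.0, 200.0, 500)
        r = matern_correlation(d, p)
        assert np.all(np.diff(r) < 0)
        assert r[-1] < 1e-8

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            matern_correlation(-1.0, MaternParams(5.0, 1.0))


class TestBuildCovariance:
    def test_single_point(self):
        cov = build_covariance(np.array([[0.0, 0.0]]), MaternParams(5.0, 2.0))
        assert cov.shape == (1, 1)
        assert cov[0, 0] == pytest.approx(4.0, rel=1e-6)

    def test_sigma_zero_is_jitter_identity(self):
        pts = np.random.default_rng(0).uniform(0, 10, (4, 2))
        cov = build_covariance(pts, MaternParams(5.0, 0.0), jitter=1e-9)
        np.testing.assert_allclose(cov, 1e-9 * np.eye(4), atol=1e-15)

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 50, (5, 2))
        p = MaternParams(20.0, 1.5)
        cov = build_covariance(pts, p, jitter=0.0)
        for i in range(5):
            for j in range(5):
                d = math.dist(pts[i], pts[j])
                assert cov[i, j] == pytest.approx(
                    p.sigma**2 * matern_correlation(d, p), rel=1e-12
                )

    def test_symmetric_positive_definite(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 100, (30, 2))
        cov = build_covariance(pts, MaternParams(30.0, 1.0))
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.linalg.eigvalsh(cov).min() > 0

    def test_duplicate_points_factorizable(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        cov = build_covariance(pts, MaternParams(10.0, 1.0))
        sm.cholesky_with_escalation(cov)  # must not raise


def one_record(y, n):
    return ClusterRecord(1, "2000", 38.0, 9.0, n, y, "A")


class TestLogLikelihood:
    def test_hand_value(self):
        # y=1, n=2, eta=0: log C(2,1) - 2 log 2 = -log 2
        got = log_likelihood([one_record(1, 2)], np.array([0.0]))
        assert got == pytest.approx(-math.log(2.0), abs=1e-12)

    def test_limit_y_zero_eta_minus_inf(self):
        got = log_likelihood([one_record(0, 5)], np.array([-40.0]))
        assert got == pytest.approx(0.0, abs=1e-15)

    def test_extreme_eta_finite(self):
        for eta in (-40.0, 40.0):
            val = log_likelihood([one_record(3, 10)], np.array([eta]))
            assert math.isfinite(val)

    def test_nonfinite_eta_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood([one_record(1, 2)], np.array([np.inf]))


class TestPriors:
    def test_beta_prior_closed_form_at_zero(self):
        priors = PriorSpec()
        z = 3
        expected = z * 0.5 * (math.log(1e-4) - math.log(2.0 * math.pi))
        assert priors.log_beta_prior(np.zeros(z)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_doubling_precision_lowers_nonzero_beta_prior(self):
        lo = PriorSpec(beta_precision=1e-4)
        hi = PriorSpec(beta_precision=2e-4)
        b = np.array([150.0])
        assert hi.log_beta_prior(b) < lo.log_beta_prior(b)

    def test_pc_prior_tail_probabilities(self):
        priors = PriorSpec(rho0=25.0, p_rho=0.05, sigma0=1.5, p_sigma=0.1)

        def rho_density(r):
            lam = -math.log(priors.p_rho) * priors.rho0
            return lam / r**2 * math.exp(-lam / r)

        mass_below, _ = quad(rho_density, 1e-9, priors.rho0)
        assert mass_below == pytest.approx(priors.p_rho, rel=1e-6)

        def sigma_density(s):
            lam = -math.log(priors.p_sigma) / priors.sigma0
            return lam * math.exp(-lam * s)

        mass_above, _ = quad(sigma_density, priors.sigma0, np.inf)
        assert mass_above == pytest.approx(priors.p_sigma, rel=1e-6)

    def test_hyperprior_matches_densities_plus_jacobian(self):
        priors = PriorSpec()
        log_rho, log_sigma = math.log(20.0), math.log(0.7)
        lam_r = -math.log(priors.p_rho) * priors.rho0
        lam_s = -math.log(priors.p_sigma) / priors.sigma0
        rho, sigma = 20.0, 0.7
        expected = (
            math.log(lam_r) - 2 * math.log(rho) - lam_r / rho + log_rho
            + math.log(lam_s) - lam_s * sigma + log_sigma
        )
        assert priors.log_field_hyperprior(log_rho, log_sigma) == pytest.approx(
            expected, rel=1e-12
        )

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            PriorSpec(beta_precision=0.0)
        with pytest.raises(ValueError):
            PriorSpec(p_rho=1.5)


class TestLogPosterior:
    def _data(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        records = [
            ClusterRecord(i + 1, "2000", 38 + 0.1 * i, 9.0, 10,
                          int(rng.integers(0, 11)), "A")
            for i in range(n)
        ]
        design = rng.standard_normal((n, 2))
        km = core_io.project_points(
            np.array([[r.lon, r.lat] for r in records])
        )
        return records, design, km

    def test_field_vs_nofield_differ_by_hyperprior_terms(self):
        records, design, km = self._data()
        priors = PriorSpec()
        state = {
            "alpha": 0.3,
            "beta": np.array([0.1, -0.2]),
            "zeta": np.zeros(len(records)),
            "log_rho": math.log(15.0),
            "log_sigma": math.log(0.5),
        }
        with_field = log_posterior(state, records, design, km, priors)
        without = log_posterior(
            state, records, design, km, priors, include_field=False
        )
        params = MaternParams(15.0, 0.5)
        cov = build_covariance(km, params)
        chol = sm.cholesky_with_escalation(cov)
        expected_gap = sm.mvn_logpdf_chol(
            np.zeros(len(records)), chol
        ) + priors.log_field_hyperprior(state["log_rho"], state["log_sigma"])
        assert with_field - without == pytest.approx(expected_gap, rel=1e-10)

    def test_nonfinite_state_returns_neg_inf(self):
        records, design, km = self._data()
        state = {"alpha": np.inf, "beta": np.zeros(2)}
        assert log_posterior(
            state, records, design, km, PriorSpec(), include_field=False
        ) == -math.inf

    def test_likelihood_plus_prior_decomposition_nofield(self):
        records, design, km = self._data()
        priors = PriorSpec()
        state = {"alpha": -0.4, "beta": np.array([0.5, 0.25])}
        eta = state["alpha"] + design @ state["beta"]
        expected = log_likelihood(records, eta) + priors.log_beta_prior(
            state["beta"]
        )
        got = log_posterior(
            state, records, design, km, priors, include_field=False
        )
        assert got == pytest.approx(expected, rel=1e-12)


class TestFitMcmc:
    def _spatial_setup(self, n=40, seed=0):
        ds = synthetic.simulate_dataset(
            seed=seed,
            counts_per_wave=[n],
            grid_spec=synthetic.GridSpec(12, 12),
        )
        km = core_io.project_points(
            np.array([[r.lon, r.lat] for r in ds.records])
        )
        return ds, km

    def test_seed_reproducibility_bit_identical(self):
        ds, km = self._spatial_setup()
        cfg = ChainConfig(n_chains=2, n_iter=80, burn_in=30, thin=2, seed=5)
        a = fit_mcmc(ds.records, ds.design, points_km=km, config=cfg)
        b = fit_mcmc(ds.records, ds.design, points_km=km, config=cfg)
        np.testing.assert_array_equal(a.alpha, b.alpha)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.zeta, b.zeta)
        np.testing.assert_array_equal(a.log_rho, b.log_rho)

    def test_different_seeds_differ(self):
        ds, km = self._spatial_setup()
        cfg1 = ChainConfig(n_chains=1, n_iter=60, burn_in=20, thin=2, seed=1)
        cfg2 = ChainConfig(n_chains=1, n_iter=60, burn_in=20, thin=2, seed=2)
        a = fit_mcmc(ds.records, ds.design, points_km=km, config=cfg1)
        b = fit_mcmc(ds.records, ds.design, points_km=km, config=cfg2)
        assert not np.array_equal(a.alpha, b.alpha)

    def test_requires_min_records_for_spatial(self):
        ds, km = self._spatial_setup()
        with pytest.raises(ValueError, match=">= 10"):
            fit_mcmc(
                ds.records[:5], ds.design[:5], points_km=km[:5],
                config=ChainConfig(n_iter=10, burn_in=2, seed=0),
            )

    def test_summary_shape_and_interval_order(self):
        ds, km = self._spatial_setup()
        post = fit_mcmc(
            ds.records, ds.design, beta_names=["temp", "travel"],
            points_km=km,
            config=ChainConfig(n_chains=1, n_iter=150, burn_in=50, thin=2,
                               seed=3),
        )
        s = post.summary()
        assert list(s["parameter"]) == [
            "alpha", "temp", "travel", "range_rho", "sigma"
        ]
        assert (s["lower95"] <= s["mean"]).all()
        assert (s["mean"] <= s["upper95"]).all()
        assert np.isfinite(post.zeta).all()

    def test_null_coverage_small(self):
        # data generated with beta = 0: CrIs should usually cover 0
        hits = np.zeros(2)
        n_rep = 6
        for rep in range(n_rep):
            ds = synthetic.simulate_dataset(
                seed=100 + rep,
                counts_per_wave=[120],
                grid_spec=synthetic.GridSpec(15, 15),
                beta_true=(0.0, 0.0),
            )
            km = core_io.project_points(
                np.array([[r.lon, r.lat] for r in ds.records])
            )
            post = fit_mcmc(
                ds.records, ds.design, points_km=km,
                config=ChainConfig(n_chains=1, n_iter=2000, burn_in=800,
                                   thin=2, seed=rep),
            )
            s = post.summary().set_index("parameter")
            for k, name in enumerate(["x0", "x1"]):
                lo, hi = s.loc[name, ["lower95", "upper95"]]
                hits[k] += lo <= 0.0 <= hi
        assert (hits >= n_rep - 1).all()


def _posterior_from_alpha_draws(alphas, n_obs=1):
    alphas = np.asarray(alphas, dtype=float)
    s = alphas.shape[0]
    return Posterior(
        alpha=alphas,
        beta=np.zeros((s, 0)),
        zeta=np.empty((s, 0)),
        log_rho=np.empty(0),
        log_sigma=np.empty(0),
        beta_names=[],
        design=np.zeros((n_obs, 0)),
    )


class TestWaic:
    def test_zero_variance_closed_form(self):
        records = [one_record(2, 6)]
        post = _posterior_from_alpha_draws([0.3, 0.3, 0.3])
        out = waic(post, records)
        ll = log_likelihood(records, np.array([0.3]))
        assert out["p_waic"] == pytest.approx(0.0, abs=1e-12)
        assert out["lppd"] == pytest.approx(ll, rel=1e-12)
        assert out["waic"] == pytest.approx(-2.0 * ll, rel=1e-12)

    def test_two_draw_hand_example(self):
        # find eta values whose single-observation log-liks are -1 and -2
        records = [one_record(1, 2)]

        def ll(eta):
            return log_likelihood(records, np.array([eta]))

        eta1 = brentq(lambda e: ll(e) + 1.0, -10.0, 0.0)
        eta2 = brentq(lambda e: ll(e) + 2.0, -10.0, eta1 - 1e-9)
        post = _posterior_from_alpha_draws([eta1, eta2])
        out = waic(post, records)
        lppd = math.log((math.exp(-1.0) + math.exp(-2.0)) / 2.0)
        assert out["lppd"] == pytest.approx(lppd, abs=1e-9)
        assert out["lppd"] == pytest.approx(-1.3799, abs=1e-4)
        assert out["p_waic"] == pytest.approx(0.5, abs=1e-9)
        assert out["waic"] == pytest.approx(3.7598, abs=1e-4)

    def test_needs_two_draws(self):
        with pytest.raises(ValueError):
            waic(_posterior_from_alpha_draws([0.1]), [one_record(1, 2)])


class TestCompareModels:
    def test_single_model(self):
        out = compare_models([("m", {"waic": 5.0, "p_waic": 1.0, "lppd": 0.0})])
        assert out.loc[0, "delta_waic"] == 0.0

    def test_ordering(self):
        fits = [
            ("a", {"waic": 10.0, "p_waic": 0, "lppd": 0}),
            ("b", {"waic": 7.0, "p_waic": 0, "lppd": 0}),
            ("c", {"waic": 9.0, "p_waic": 0, "lppd": 0}),
        ]
        out = compare_models(fits)
        assert list(out["label"]) == ["b", "c", "a"]
        assert list(out["waic"]) == [7.0, 9.0, 10.0]
        assert out.loc[0, "delta_waic"] == 0.0
        assert (out["delta_waic"] >= 0).all()

    def test_tie_broken_by_label_order(self):
        fits = [
            ("second", {"waic": 4.0, "p_waic": 0, "lppd": 0}),
            ("first", {"waic": 4.0, "p_waic": 0, "lppd": 0}),
        ]
        out = compare_models(fits)
        assert list(out["label"]) == ["second", "first"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_models([])
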