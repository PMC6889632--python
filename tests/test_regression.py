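import numpy as np
import pytest

from paleopgls.covariance import bm_covariance, lambda_transform
from paleopgls.regression import (
    PGLSRegressor,
    fit_ols,
    fit_pgls_bm_lambda,
    fit_pgls_ou,
    gls_fit,
    within_taxon_regression,
)
from conftest import make_record


def random_spd(rng, n):
    A = rng.normal(size=(n, n))
    return A @ A.T + n * np.eye(n)


def whitened_ols_oracle(y, x, V):
    """The stated oracle: whiten by the inverse Cholesky factor, run OLS."""
    L = np.linalg.cholesky(V)
    Linv = np.linalg.inv(L)
    X = np.column_stack([np.ones_like(x), x])
    Xw, yw = Linv @ X, Linv @ y
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    return beta


class TestGLSFit:
    def test_perfect_line_is_exact(self):
        fit = gls_fit([0.0, 1.0, 2.0], [0.0, 1.0, 2.0], None)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)

    def test_identity_covariance_equals_plain_ols(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            x = rng.normal(size=n)
            y = 0.3 + 0.9 * x + rng.normal(size=n)
            fit = gls_fit(y, x, np.eye(n))
            # normal-equations oracle
            X = np.column_stack([np.ones(n), x])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
            assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    def test_matches_whitened_ols_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(5, 21))
            V = random_spd(rng, n)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            fit = gls_fit(y, x, V)
            beta = whitened_ols_oracle(y, x, V)
            assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
            assert fit.slope == pytest.approx(beta[1], abs=1e-8)

    def test_ci_contains_estimate_and_uses_t_quantile(self):
        rng = np.random.default_rng(2)
        n = 12
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        fit = gls_fit(y, x, None)
        lo, hi = fit.ci_slope
        assert lo < fit.slope < hi
        from scipy import stats

        half = stats.t.ppf(0.975, n - 2) * fit.se_slope
        assert hi - fit.slope == pytest.approx(half, rel=1e-12)

    def test_singular_covariance_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            gls_fit([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], np.ones((3, 3)))

    def test_collinear_design_raises(self):
        with pytest.raises((np.linalg.LinAlgError, ValueError)):
            gls_fit([1.0, 2.0, 3.0], [2.0, 2.0, 2.0], np.eye(3))


class TestOracleAgreementWithIndependentGLS:
    """Frozen results from an independent GLS implementation (R nlme::gls
    with a Pagel correlation structure and fixed tip-depth variance
    weights) on the 10-tip fossil fixture."""

    def test_reml_lambda_profile(self, oracle_tree, oracle_xy):
        x, y = oracle_xy
        fit = fit_pgls_bm_lambda(y, x, tree=oracle_tree, method="reml")[0]
        # values frozen from the independent implementation
        assert fit.signal == pytest.approx(0.964052385351, abs=2e-6)
        assert fit.intercept == pytest.approx(-0.178156778301, abs=1e-6)
        assert fit.slope == pytest.approx(0.975219261073, abs=1e-6)
        assert fit.se_slope == pytest.approx(0.254434289066, abs=1e-6)
        assert fit.loglik == pytest.approx(10.7422200254, abs=1e-6)

    def test_reml_fixed_lambda_one(self, oracle_tree, oracle_xy):
        x, y = oracle_xy
        V = lambda_transform(bm_covariance(oracle_tree), 1.0)
        fit = gls_fit(y, x, V, method="reml")
        assert fit.intercept == pytest.approx(-0.202890470202, abs=1e-8)
        assert fit.slope == pytest.approx(0.98636365406, abs=1e-8)
        assert fit.se_slope == pytest.approx(0.270824141259, abs=1e-8)
        assert fit.loglik == pytest.approx(10.5080094051, abs=1e-6)


class TestLambdaEstimation:
    def test_lambda_zero_pgls_equals_ols(self, oracle_tree, oracle_xy):
        x, y = oracle_xy
        V = lambda_transform(bm_covariance(oracle_tree), 0.0)
        fit = gls_fit(y, x, V)
        # lambda = 0 leaves tip variances on the diagonal (weighted OLS);
        # with the further normalization to the identity it is exactly OLS
        n = len(x)
        fit_id = gls_fit(y, x, np.eye(n))
        ols = fit_ols(y, x)
        assert ols.slope == pytest.approx(fit_id.slope, abs=1e-10)
        assert ols.intercept == pytest.approx(fit_id.intercept, abs=1e-10)
        assert fit.model == "GLS" and ols.model == "OLS"

    def test_optimum_beats_grid(self, oracle_tree, oracle_xy):
        x, y = oracle_xy
        bm = bm_covariance(oracle_tree)
        best = fit_pgls_bm_lambda(y, x, tree=oracle_tree)[0]
        for lam in np.linspace(0, 1, 101):
            f = gls_fit(y, x, lambda_transform(bm, lam))
            assert best.loglik >= f.loglik - 1e-9

    def test_independent_noise_estimates_low_lambda(self):
        # deep tree, phylogeny-free residuals -> lambda near 0
        from paleopgls.simulate import (
            SimulationConfig,
            simulate_birth_death_tree,
            simulate_traits,
        )

        rng = np.random.default_rng(11)
        cfg = SimulationConfig(n_species=300, signal=0.0, residual_scale=0.08,
                               seed=11)
        tree = simulate_birth_death_tree(cfg, rng)
        traits = simulate_traits(tree, cfg, rng)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        x = np.array([traits[l][0] for l in labels])
        y = np.array([traits[l][1] for l in labels])
        fit = fit_pgls_bm_lambda(y, x, tree=tree)[0]
        assert fit.signal < 0.1

    def test_fallback_returns_fixed_lambda_one_and_ols(self):
        # engineered non-identifiable input: n = 3 noiseless collinear
        # points leave no residual scale, so the likelihood is non-finite
        # over the whole lambda range and the fallback pair is returned
        from paleopgls.trees import parse_newick

        tree = parse_newick("((a1:1,a2:1):1,b:2);")
        x = np.array([1.0, 2.0, 3.0])
        y = 0.5 + 2.0 * x
        fits = fit_pgls_bm_lambda(y, x, tree=tree)
        assert [f.model for f in fits] == ["BM+lambda", "OLS"]
        assert [f.signal for f in fits] == [1.0, 0.0]
        assert all(not f.converged for f in fits)
        assert all(f.signal_fixed for f in fits)


class TestOUEstimation:
    def test_loglik_nests_to_bm_at_tiny_alpha(self, oracle_tree, oracle_xy):
        x, y = oracle_xy
        from paleopgls.covariance import ou_covariance

        V_bm = lambda_transform(bm_covariance(oracle_tree), 1.0)
        f_bm = gls_fit(y, x, V_bm)
        f_ou = gls_fit(y, x, ou_covariance(oracle_tree, 1e-6))
        assert abs(f_ou.loglik - f_bm.loglik) < 0.01

    def test_caution_flag_for_low_alpha_or_small_n(self, oracle_tree, oracle_xy):
        x, y = oracle_xy
        fit = fit_pgls_ou(y, x, oracle_tree)[0]
        assert fit.caution  # n = 10 < 50

    def test_alpha_recovery_from_ou_simulations(self):
        # traits generated with alpha = 0.02 on ~100-My-deep trees (a scale
        # at which alpha is identifiable; much larger values decorrelate all
        # tips and leave the likelihood flat from above): the estimate should
        # land within a factor of 3 of the truth in at least 90% of replicates
        from paleopgls.simulate import (
            SimulationConfig,
            simulate_birth_death_tree,
            simulate_traits,
        )

        alpha0 = 0.02
        ok = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(500 + rep)
            cfg = SimulationConfig(
                n_species=150, signal_model="ou", signal=alpha0,
                residual_scale=0.08, seed=500 + rep,
            )
            tree = simulate_birth_death_tree(cfg, rng)
            traits = simulate_traits(tree, cfg, rng)
            labels = [l.taxon.label for l in tree.leaf_node_iter()]
            x = np.array([traits[l][0] for l in labels])
            y = np.array([traits[l][1] for l in labels])
            fit = fit_pgls_ou(y, x, tree)[0]
            ok += alpha0 / 3 <= fit.signal <= alpha0 * 3
        assert ok / reps >= 0.9


class TestWithinTaxon:
    def test_collinear_specimens_exact_slope(self):
        records = [
            make_record(f"s{i}", fl=10 ** (2 + 0.1 * i),
                        hl=10 ** (1 + 0.12 * i))
            for i in range(3)
        ]
        res = within_taxon_regression(records)
        assert res.fit is not None
        assert res.fit.slope == pytest.approx(1.2, abs=1e-9)
        lo, hi = res.fit.ci_slope
        assert hi - lo == pytest.approx(0.0, abs=1e-6)

    def test_two_specimens_reported_not_raised(self):
        records = [make_record("s1"), make_record("s2")]
        res = within_taxon_regression(records)
        assert res.fit is None
        assert "fewer than 3" in res.reason

    def test_recovers_ontogenetic_slope(self):
        # synthetic size series with slope 1.2 and small noise: the CI
        # should cover the truth in >= 90% of replicates
        hits = 0
        reps = 200
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            logfl = rng.uniform(1.8, 2.6, size=12)
            loghl = 0.1 + 1.2 * logfl + rng.normal(0, 0.02, size=12)
            records = [
                make_record(f"s{i}", fl=10 ** fl, hl=10 ** hl)
                for i, (fl, hl) in enumerate(zip(logfl, loghl))
            ]
            res = within_taxon_regression(records)
            lo, hi = res.fit.ci_slope
            hits += lo <= 1.2 <= hi
        assert hits / reps >= 0.9


class TestPGLSRegressorEstimator:
    def test_sklearn_contract(self):
        reg = PGLSRegressor(model="ols")
        params = reg.get_params()
        assert params["model"] == "ols"
        reg.set_params(conf_level=0.9)
        reg.fit(np.array([[1.0], [2.0], [3.0], [4.0]]),
                np.array([1.0, 2.0, 3.0, 4.0]))
        assert reg.coef_[0] == pytest.approx(1.0, abs=1e-10)
        assert reg.intercept_ == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(reg.predict([[5.0]]), [5.0], atol=1e-10)

    def test_tree_fit_with_label_alignment(self, oracle_tree):
        from conftest import ORACLE_DATA

        labels = sorted(ORACLE_DATA)  # deliberately not tip order
        X = np.array([[ORACLE_DATA[s][0]] for s in labels])
        y = np.array([ORACLE_DATA[s][1] for s in labels])
        reg = PGLSRegressor(model="bm_lambda").fit(
            X, y, tree=oracle_tree, labels=labels
        )
        direct = fit_pgls_bm_lambda(
            *_tip_ordered(oracle_tree), tree=oracle_tree
        )[0]
        assert reg.coef_[0] == pytest.approx(direct.slope, abs=1e-10)
        assert reg.signal_ == pytest.approx(direct.signal, abs=1e-10)

    def test_label_mismatch_is_error(self, oracle_tree):
        X = np.zeros((10, 1))
        y = np.zeros(10)
        with pytest.raises(ValueError, match="labels"):
            PGLSRegressor().fit(X, y, tree=oracle_tree,
                                labels=[f"wrong{i}" for i in range(10)])


def _tip_ordered(tree):
    from conftest import ORACLE_DATA

    order = [l.taxon.label for l in tree.leaf_node_iter()]
    y = np.array([ORACLE_DATA[s][1] for s in order])
    x = np.array([ORACLE_DATA[s][0] for s in order])
    return y, x
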