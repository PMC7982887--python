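import math

import numpy as np
import pytest

from ploidypath import (FitError, brownian_cov, build_design, endemic_spec,
                        filter_lineages, fit_weighted_pgls,
                        marginal_prediction, ploidy_spec, simulate_tree)
from conftest import make_record, random_gls_instance


def gls_oracle(X, y, R, w, variance_power=1.0):
    """Closed-form GLS by dense inversion (independent of the engine)."""
    V = np.diag((1.0 / w) ** (variance_power / 2)) @ R \
        @ np.diag((1.0 / w) ** (variance_power / 2))
    Vi = np.linalg.inv(V)
    G = X.T @ Vi @ X
    beta = np.linalg.solve(G, X.T @ Vi @ y)
    e = y - X @ beta
    n, p = X.shape
    s2 = float(e @ Vi @ e) / (n - p)
    se = np.sqrt(s2 * np.diag(np.linalg.inv(G)))
    return beta, se, s2


class TestEstimation:
    def test_intercept_only_reduces_to_ols(self):
        y = np.array([1.0, 2.0, 3.0])
        fit = fit_weighted_pgls(np.ones((3, 1)), y, np.eye(3),
                                np.ones(3), method="REML")
        assert fit.beta[0] == pytest.approx(2.0)
        assert fit.sigma2 == pytest.approx(1.0)
        assert fit.se[0] == pytest.approx(1 / math.sqrt(3), abs=1e-4)

    def test_matches_dense_closed_form(self):
        rng = np.random.default_rng(0)
        X, y, R, w = random_gls_instance(rng, n=6, p=2)
        fit = fit_weighted_pgls(X, y, R, w)
        beta, se, s2 = gls_oracle(X, y, R, w)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-10)
        np.testing.assert_allclose(fit.se, se, atol=1e-10)
        assert fit.sigma2_resid == pytest.approx(s2)

    def test_star_tree_unit_weights_equal_ols(self):
        rng = np.random.default_rng(2)
        n = 20
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        fit = fit_weighted_pgls(X, y, np.eye(n), np.ones(n))
        import statsmodels.api as sm
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.beta, ols.params, atol=1e-10)
        np.testing.assert_allclose(fit.se, ols.bse, atol=1e-10)
        np.testing.assert_allclose(fit.t, ols.tvalues, atol=1e-10)

    def test_agrees_with_statsmodels_gls(self):
        rng = np.random.default_rng(3)
        X, y, R, w = random_gls_instance(rng, n=15, p=3)
        fit = fit_weighted_pgls(X, y, R, w)
        import statsmodels.api as sm
        gls = sm.GLS(y, X, sigma=fit.V).fit()
        np.testing.assert_allclose(fit.beta, gls.params, atol=1e-9)
        np.testing.assert_allclose(fit.se, gls.bse, atol=1e-9)

    def test_weight_rescaling_leaves_inference_unchanged(self):
        rng = np.random.default_rng(4)
        X, y, R, w = random_gls_instance(rng, n=12, p=2)
        f1 = fit_weighted_pgls(X, y, R, w)
        f2 = fit_weighted_pgls(X, y, R, 7.3 * w)
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-10)
        np.testing.assert_allclose(f1.t, f2.t, atol=1e-10)
        np.testing.assert_allclose(f1.p, f2.p, atol=1e-10)

    def test_generalized_residual_orthogonality(self):
        rng = np.random.default_rng(5)
        X, y, R, w = random_gls_instance(rng, n=10, p=3)
        fit = fit_weighted_pgls(X, y, R, w)
        Vi_e = np.linalg.solve(fit.V, fit.resid)
        np.testing.assert_allclose(X.T @ Vi_e, 0.0, atol=1e-8)

    def test_reml_sigma2_is_the_maximizer(self):
        rng = np.random.default_rng(6)
        X, y, R, w = random_gls_instance(rng, n=10, p=2)
        fit = fit_weighted_pgls(X, y, R, w, method="REML")
        best = fit.reml_loglik(fit.sigma2)
        for eps in (0.9, 0.99, 1.01, 1.1):
            assert fit.reml_loglik(fit.sigma2 * eps) < best
        assert fit.loglik_reml == pytest.approx(best)

    def test_variance_power_flag(self):
        rng = np.random.default_rng(7)
        X, y, R, w = random_gls_instance(rng, n=8, p=2)
        fit = fit_weighted_pgls(X, y, R, w, variance_power=2.0)
        beta, se, _ = gls_oracle(X, y, R, w, variance_power=2.0)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-10)
        np.testing.assert_allclose(fit.se, se, atol=1e-10)

    def test_bad_inputs_rejected(self):
        X = np.ones((4, 1))
        y = np.zeros(4)
        with pytest.raises(FitError, match="weights"):
            fit_weighted_pgls(X, y, np.eye(4), np.array([1, 1, -1, 1]))
        with pytest.raises(FitError, match="dimension"):
            fit_weighted_pgls(X, y, np.eye(3), np.ones(4))
        with pytest.raises(FitError, match="method"):
            fit_weighted_pgls(X, y, np.eye(4), np.ones(4), method="GLM")


class TestDesign:
    def _two_arch_dataset(self):
        recs = [make_record(f"N{i}", "NZ", stem_age=5.0 + i,
                            n_ploidy_levels=1 + i % 3,
                            monophyletic=(i % 2 == 0),
                            source_pool=10 + 15 * i,
                            n_endemic=2 + i) for i in range(5)]
        recs += [make_record(f"C{i}", "CI", stem_age=3.0 + i,
                             n_ploidy_levels=1 + (i + 1) % 3,
                             source_pool=25 + 40 * i,
                             n_endemic=1 + i, ploidy_change=(i % 2 == 0))
                 for i in range(5)]
        return filter_lineages(recs)

    def test_column_count_matches_hand_enumeration(self):
        ds = self._two_arch_dataset()
        X, y, terms = build_design(ds, endemic_spec())
        # intercept + arch_CI + age + ploidy + ploidy:arch_CI + pool
        # + monophyletic + ploidy_change = 8
        assert X.shape == (10, 8)
        assert [t.name for t in terms] == [
            "intercept", "arch_CI", "log_stem_age", "ploidy_levels",
            "ploidy_levels:arch_CI", "source_pool", "monophyletic",
            "ploidy_change"]

    def test_log_transforms(self):
        from ploidypath.pgls_engine import predictor_values, response_values
        ds = filter_lineages([
            make_record("A", stem_age=1.0, n_endemic=1),
            make_record("B", stem_age=2.0, n_endemic=4)])
        spec = endemic_spec()
        age = predictor_values(ds, "log_stem_age", spec)
        assert age[0] == pytest.approx(0.0)          # ln 1
        assert age[1] == pytest.approx(math.log(2))
        y = response_values(ds, spec)
        assert y[0] == pytest.approx(0.0)            # ln 1
        assert y[1] == pytest.approx(math.log(4))

    def test_ploidy_spec_excludes_ploidy_and_monophyly(self):
        ds = self._two_arch_dataset()
        X, y, terms = build_design(ds, ploidy_spec())
        names = [t.name for t in terms]
        assert "ploidy_levels" not in names
        assert "monophyletic" not in names
        assert "log_stem_age:arch_CI" in names
        np.testing.assert_allclose(
            y, [r.n_ploidy_levels for r in ds.records])

    def test_rank_deficiency_names_columns(self):
        # a lone CI lineage makes its intercept and slope columns collinear
        recs = [make_record(f"N{i}", "NZ", stem_age=4.0 + i)
                for i in range(6)]
        recs.append(make_record("C0", "CI"))
        with pytest.raises(FitError, match="arch_CI"):
            build_design(filter_lineages(recs), endemic_spec())


class TestMarginalPrediction:
    def _fit(self):
        ds = TestDesign()._two_arch_dataset()
        tree = simulate_tree(10, 1.0, seed=8)
        labels = ds.lineage_ids
        from ploidypath.phylo_cov import tip_labels
        rename = dict(zip(tip_labels(tree), labels))
        for leaf in tree.leaf_node_iter():
            leaf.taxon.label = rename[leaf.taxon.label]
        cov = brownian_cov(tree, tip_order=labels)
        X, y, terms = build_design(ds, endemic_spec())
        return fit_weighted_pgls(X, y, cov.R, ds.weights_species,
                                 terms=terms)

    def test_zero_slope_gives_flat_prediction(self):
        fit = self._fit()
        j = fit.names.index("source_pool")
        fit.beta[j] = 0.0
        out = marginal_prediction(fit, "source_pool", np.array([10.0, 200.0]))
        assert out["prediction"][0] == pytest.approx(out["prediction"][1])
        assert out["change"] == pytest.approx(0.0)

    def test_change_equals_slope_times_span_without_interactions(self):
        fit = self._fit()
        out = marginal_prediction(fit, "source_pool", np.array([0.0, 10.0]))
        j = fit.names.index("source_pool")
        assert out["change"] == pytest.approx(10 * fit.beta[j])
        lo, hi = out["change_ci"]
        assert lo < out["change"] < hi

    def test_back_transform_exponentiates(self):
        fit = self._fit()
        raw = marginal_prediction(fit, "ploidy_levels", np.array([1.0, 3.0]))
        bt = marginal_prediction(fit, "ploidy_levels", np.array([1.0, 3.0]),
                                 back_transform=True)
        np.testing.assert_allclose(bt["prediction"],
                                   np.exp(raw["prediction"]))

    def test_unknown_term_rejected(self):
        fit = self._fit()
        with pytest.raises(KeyError):
            marginal_prediction(fit, "nope", np.array([0.0, 1.0]))
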