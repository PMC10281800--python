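import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cuculus.dag import DagSpec, ExoVar, MILESTONES, default_timing_dag
from cuculus.mcmc import MCMCSettings, batch_means_mcse
from cuculus.path_timing import (chain_variance_share, dsep_basis_set,
                                 dsep_test, edge_probability, encode_binary,
                                 fit_path_model, indirect_effect,
                                 residual_share, standardize, summarize_paths,
                                 support_tier, variance_explained)
from cuculus.synthetic import SimConfig, simulate_schedules, truth_milestone_table


def _standardized_truth(cfg, dag):
    truth = truth_milestone_table(simulate_schedules(cfg))
    data = encode_binary(truth, {"habitat": "upland", "route": "SE"})
    return standardize(data, dag.all_nodes())


class TestStandardize:
    def test_closed_form_zscores(self):
        df = pd.DataFrame({"x": [0.0, 10.0, 20.0]})
        out = standardize(df, ["x"])
        np.testing.assert_allclose(out["x"], [-1.2247, 0.0, 1.2247],
                                   atol=1e-4)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize(pd.DataFrame({"x": [1.0, 1.0]}), ["x"])

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(3, 7, 50)})
        once = standardize(df, ["x"])
        twice = standardize(once, ["x"])
        np.testing.assert_allclose(once["x"], twice["x"], atol=1e-12)

    def test_missing_entries_ignored_in_moments(self):
        df = pd.DataFrame({"x": [0.0, 10.0, 20.0, np.nan]})
        out = standardize(df, ["x"])
        assert np.isnan(out["x"].iloc[3])
        np.testing.assert_allclose(out["x"].iloc[:3],
                                   [-1.2247, 0.0, 1.2247], atol=1e-4)


class TestEdgeMath:
    def test_edge_probability_extremes(self):
        assert edge_probability(np.abs(np.random.default_rng(0).normal(
            1, 0.1, 500))) == 1.0
        sym = np.concatenate([np.ones(100), -np.ones(100)])
        assert edge_probability(sym) == 0.5

    def test_edge_probability_matches_normal_cdf(self):
        draws = np.random.default_rng(1).normal(1.0, 1.0, 4000)
        assert edge_probability(draws) == pytest.approx(0.8413, abs=0.02)

    def test_variance_explained_squares_the_coefficient(self):
        assert variance_explained(0.883)["pct"] == 78.0
        assert variance_explained(0.0)["pct"] == 0.0
        # sign-invariant: the share of a negative path is |coef|^2
        assert variance_explained(-0.329)["pct"] == 10.8

    def test_indirect_effect_is_product_of_steps(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.5, 0.01, 1000)
        b = rng.normal(0.8, 0.01, 1000)
        out = indirect_effect(a, b)
        assert out["effect"] == pytest.approx(0.4, abs=0.01)
        zero = np.zeros(1000)
        assert indirect_effect(a, zero)["effect"] == 0.0

    def test_chained_share_equals_product_of_stage_shares(self):
        assert chain_variance_share([0.158, 0.266, 0.883 ** 2]) == 3.3
        assert chain_variance_share([0.075, 0.883 ** 2]) == 5.8
        shares = [0.31, 0.22, 0.57]
        manual = 100.0 * np.prod(shares)
        assert abs(chain_variance_share(shares) - manual) < 0.05 + 1e-12

    def test_residual_share_closes_printed_decompositions(self):
        assert residual_share([78.0, 10.8]) == 11.2
        assert residual_share([11.6, 3.7]) == 84.7
        assert residual_share([11.6]) == 88.4

    def test_support_tiers(self):
        assert support_tier(0.96) == "very well-supported"
        assert support_tier(0.94) == "well-supported"
        assert support_tier(0.85) == "likely"
        assert support_tier(0.79) == "unsupported"


class TestFit:
    def test_posterior_matches_ols_on_complete_data(self, fast_mcmc):
        dag = default_timing_dag()
        cfg = SimConfig(n_birds=250, n_years=2, seed=40,
                        mortality_enabled=False)
        data = _standardized_truth(cfg, dag)[dag.all_nodes()]
        fit = fit_path_model(data, dag, fast_mcmc)
        assert fit.converged
        for v in dag.endogenous:
            pars = dag.parents(v)
            res = sm.OLS(data[v].to_numpy(),
                         sm.add_constant(data[pars].to_numpy())).fit()
            for i, p in enumerate(pars):
                draws = fit.coef[(p, v)].ravel()
                mcse = max(batch_means_mcse(draws), 1e-4)
                assert abs(draws.mean() - res.params[i + 1]) < max(
                    3 * mcse, 0.02), (p, v)

    def test_dominant_edge_recovered_at_study_scale(self, fast_mcmc):
        dag = default_timing_dag()
        cfg = SimConfig(n_birds=87, n_years=2, seed=41,
                        mortality_enabled=False)
        data = _standardized_truth(cfg, dag)[dag.all_nodes()]
        fit = fit_path_model(data, dag, fast_mcmc)
        d = fit.coef[("depart_west_africa", "arrive_breeding")].ravel()
        assert abs(d.mean() - 0.883) < 3 * d.std()
        assert fit.edge_probability("depart_west_africa",
                                    "arrive_breeding") > 0.99

    def test_imputation_handles_missing_predictors(self, fast_mcmc):
        dag = default_timing_dag()
        cfg = SimConfig(n_birds=150, n_years=2, seed=42,
                        mortality_enabled=False)
        data = _standardized_truth(cfg, dag)[dag.all_nodes()].copy()
        rng = np.random.default_rng(0)
        mask = rng.random(len(data)) < 0.2
        data.loc[mask, "depart_west_africa"] = np.nan
        fit = fit_path_model(data, dag, fast_mcmc)
        d = fit.coef[("depart_west_africa", "arrive_breeding")].ravel()
        assert abs(d.mean() - 0.883) < max(3 * d.std(), 0.1)

    def test_non_identifiable_node_rejected(self, fast_mcmc):
        dag = DagSpec(endogenous=["a", "b"], exogenous={},
                      edges={("a", "b"): 0.5})
        data = pd.DataFrame({"a": [0.1, -0.2, 0.3],
                             "b": [np.nan, np.nan, 0.1]})
        with pytest.raises(ValueError, match="identifiable"):
            fit_path_model(data, dag, fast_mcmc)

    def test_summary_table_flags_headline_edges(self, fast_mcmc):
        dag = default_timing_dag()
        cfg = SimConfig(n_birds=200, n_years=2, seed=43,
                        mortality_enabled=False)
        data = _standardized_truth(cfg, dag)[dag.all_nodes()]
        fit = fit_path_model(data, dag, fast_mcmc)
        table = summarize_paths(fit)
        strong = table[table["path"] ==
                       "depart_west_africa -> arrive_breeding"]
        assert strong["tier"].iloc[0] == "very well-supported"
        assert strong["headline"].iloc[0]
        # weak edges stay in the table but drop out of the headline set
        assert (~table["headline"]).any()
        assert len(table) == len(dag.edges)


class TestDsep:
    def test_saturated_dag_has_empty_basis(self):
        dag = DagSpec(endogenous=["a", "b", "c"], exogenous={},
                      edges={("a", "b"): 0.0, ("a", "c"): 0.0,
                             ("b", "c"): 0.0})
        assert dsep_basis_set(dag) == []
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
        out = dsep_test(dag, data)
        assert out["C"] == 0.0 and out["p"] == 1.0

    def test_exogenous_pairs_excluded_from_basis(self):
        dag = default_timing_dag()
        for a, b, _ in dsep_basis_set(dag):
            assert not (a in dag.exogenous and b in dag.exogenous)

    def test_true_dag_not_rejected_and_omitted_edge_detected(self):
        dag = default_timing_dag()
        cfg = SimConfig(n_birds=137, n_years=1, seed=44,
                        mortality_enabled=False)
        data = _standardized_truth(cfg, dag)
        assert dsep_test(dag, data)["p"] > 0.001
        reduced = default_timing_dag()
        del reduced.edges[("complete_sahara_south", "depart_west_africa")]
        claims = dsep_test(reduced, data)["claims"]
        row = claims[(claims["independent"] == "complete_sahara_south")
                     & (claims["dependent"] == "depart_west_africa")]
        assert row["p"].iloc[0] < 0.01
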