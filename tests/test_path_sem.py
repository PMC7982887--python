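import dataclasses
import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ploidypath import (CausalDiagram, PathConfig, SimulationParams,
                        basis_set, brownian_cov, compute_weights, dsep_test,
                        endemic_spec, fishers_c, fit_weighted_pgls,
                        island_dag, rsquared, run_path_analysis,
                        simulate_dataset, standardize)
from ploidypath.pgls_engine import build_design
from conftest import random_gls_instance


# --- brute-force d-separation oracle (path enumeration + blocking rules) ---

def is_d_separated_oracle(g: nx.DiGraph, x: str, y: str, Z: set) -> bool:
    desc = {n: nx.descendants(g, n) | {n} for n in g.nodes}
    und = g.to_undirected()
    for path in nx.all_simple_paths(und, x, y):
        blocked = False
        for i in range(1, len(path) - 1):
            a, m, b = path[i - 1], path[i], path[i + 1]
            collider = g.has_edge(a, m) and g.has_edge(b, m)
            if collider:
                if desc[m].isdisjoint(Z):
                    blocked = True
                    break
            elif m in Z:
                blocked = True
                break
        if not blocked:
            return False
    return True


def random_dag(rng, n_nodes=6, p_edge=0.4):
    names = [f"N{i}" for i in range(n_nodes)]
    order = list(rng.permutation(n_nodes))
    g = nx.DiGraph()
    g.add_nodes_from(names)
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < p_edge:
            a, b = order[i], order[j]
            g.add_edge(names[a], names[b])
    return CausalDiagram(g)


class TestBasisSet:
    def test_island_dag_has_exactly_two_claims(self):
        claims = basis_set(island_dag())
        assert len(claims) == 2
        by_added = {c.added: c for c in claims}
        c1 = by_added["RepeatColonization"]
        assert c1.response == "PloidyLevels"
        assert set(c1.conditioning) == {"StemAge", "PloidyChange",
                                        "SourcePool"}
        c2 = by_added["PloidyChange"]
        assert c2.response == "EndemicDiversity"
        assert set(c2.conditioning) == {"PloidyLevels", "StemAge",
                                        "SourcePool", "RepeatColonization"}

    def test_fully_connected_dag_has_empty_basis(self):
        g = nx.DiGraph([("A", "B"), ("A", "C"), ("B", "C")])
        assert basis_set(CausalDiagram(g)) == []

    def test_claims_are_d_separated_on_random_dags(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            dag = random_dag(rng)
            for claim in basis_set(dag):
                assert is_d_separated_oracle(
                    dag.graph, claim.added, claim.response,
                    set(claim.conditioning)), claim.label()

    def test_no_exogenous_pairs_and_pairs_nonadjacent(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            dag = random_dag(rng)
            exo = set(dag.exogenous())
            for c in basis_set(dag):
                assert not (c.added in exo and c.response in exo)
                assert not dag.graph.has_edge(c.added, c.response)
                assert not dag.graph.has_edge(c.response, c.added)
                assert c.added not in c.conditioning
                assert c.response not in c.conditioning

    def test_cyclic_graph_rejected(self):
        g = nx.DiGraph([("A", "B"), ("B", "C"), ("C", "A")])
        with pytest.raises(ValueError, match="acyclic"):
            CausalDiagram(g)

    def test_adding_missing_path_drops_claim_and_df(self):
        dag = island_dag()
        before = basis_set(dag)
        after = basis_set(dag.with_edge("RepeatColonization", "PloidyLevels",
                                        "P8"))
        assert len(after) == len(before) - 1
        assert all(c.added != "RepeatColonization" for c in after)
        _, df_before, _ = fishers_c([0.5] * len(before))
        _, df_after, _ = fishers_c([0.5] * len(after))
        assert df_before - df_after == 2


class TestFishersC:
    def test_empty_basis(self):
        assert fishers_c([]) == (0.0, 0, 1.0)

    def test_single_claim_identity(self):
        C, df, p = fishers_c([0.25])
        assert C == pytest.approx(-2 * math.log(0.25), abs=1e-4)
        assert df == 2
        assert p == pytest.approx(0.25)          # df=2 tail is exp(-C/2)

    def test_two_claims_against_chi2_integration(self):
        C, df, p = fishers_c([0.5, 0.5])
        assert C == pytest.approx(2.7726, abs=1e-4)
        assert df == 4
        from scipy.integrate import quad
        tail, _ = quad(lambda u: stats.chi2.pdf(u, 4), C, np.inf)
        assert p == pytest.approx(tail, abs=1e-8)
        assert p == pytest.approx(0.5966, abs=1e-4)

    def test_additive_over_disjoint_sets_and_monotone(self):
        p1, p2 = [0.3, 0.8], [0.12, 0.6, 0.9]
        C_all, df_all, _ = fishers_c(p1 + p2)
        C1, df1, _ = fishers_c(p1)
        C2, df2, _ = fishers_c(p2)
        assert C_all == pytest.approx(C1 + C2)
        assert df_all == df1 + df2
        C_low, _, _ = fishers_c([0.3, 0.1])
        C_high, _, _ = fishers_c([0.3, 0.9])
        assert C_low > C_high

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fishers_c([0.0])
        with pytest.raises(ValueError):
            fishers_c([1.5])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=6),
           st.floats(1e-6, 1.0), st.floats(1e-6, 1.0))
    @settings(deadline=None, database=None, derandomize=True)
    def test_monotone_decreasing_in_each_p(self, ps, a, b):
        lo, hi = sorted((a, b))
        C_lo, df1, p_lo = fishers_c(ps + [lo])
        C_hi, df2, p_hi = fishers_c(ps + [hi])
        assert df1 == df2 == 2 * (len(ps) + 1)
        assert C_lo >= C_hi
        assert p_lo <= p_hi + 1e-12


class TestStandardize:
    def test_prestandardized_equals_raw(self):
        rng = np.random.default_rng(21)
        n = 30
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std(ddof=1)
        y = 0.5 * x + rng.normal(size=n)
        y = y / y.std(ddof=1)
        from ploidypath.pgls_engine import Term
        fit = fit_weighted_pgls(
            np.column_stack([np.ones(n), x]), y, np.eye(n), np.ones(n),
            terms=[Term("intercept", "intercept"), Term("x", "continuous")])
        out = standardize(fit).set_index("term")
        assert out.loc["x", "standardized"] == pytest.approx(
            out.loc["x", "raw"])

    def test_unit_change_invariance(self):
        rng = np.random.default_rng(22)
        n = 25
        x = rng.normal(size=n)
        y = 1.2 * x + rng.normal(size=n)
        from ploidypath.pgls_engine import Term
        terms = [Term("intercept", "intercept"), Term("x", "continuous")]
        f1 = fit_weighted_pgls(np.column_stack([np.ones(n), x]), y,
                               np.eye(n), np.ones(n), terms=terms)
        f2 = fit_weighted_pgls(np.column_stack([np.ones(n), 2 * x]), y,
                               np.eye(n), np.ones(n), terms=terms)
        s1 = standardize(f1).set_index("term")
        s2 = standardize(f2).set_index("term")
        assert f2.beta[1] == pytest.approx(f1.beta[1] / 2)
        assert s2.loc["x", "standardized"] == pytest.approx(
            s1.loc["x", "standardized"])

    def test_matches_sd_ratio_oracle(self, default_sim):
        dataset, tree, _ = default_sim
        cov = brownian_cov(tree, tip_order=dataset.lineage_ids)
        X, y, terms = build_design(dataset, endemic_spec())
        fit = fit_weighted_pgls(X, y, cov.R, dataset.weights_species,
                                terms=terms)
        out = standardize(fit).set_index("term")
        j = fit.names.index("ploidy_levels")
        expected = fit.beta[j] * np.std(X[:, j], ddof=1) / np.std(y, ddof=1)
        assert out.loc["ploidy_levels", "standardized"] == pytest.approx(
            expected)
        assert np.all(np.sign(out.standardized) == np.sign(out.raw))


class TestRSquared:
    def test_perfect_fit_gives_one(self):
        rng = np.random.default_rng(31)
        n = 12
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([1.0, 2.0])
        fit = fit_weighted_pgls(X, y + rng.normal(scale=1e-9, size=n),
                                np.eye(n), np.ones(n))
        assert rsquared(fit) == pytest.approx(1.0, abs=1e-6)

    def test_intercept_only_gives_zero(self):
        rng = np.random.default_rng(32)
        y = rng.normal(size=10)
        fit = fit_weighted_pgls(np.ones((10, 1)), y, np.eye(10), np.ones(10))
        assert rsquared(fit) == 0.0

    def test_pseudo_flavor_in_unit_interval(self, default_sim):
        dataset, tree, _ = default_sim
        result = run_path_analysis(dataset, tree=tree,
                                   config=PathConfig(r2_flavor="pseudo"))
        for v in result.r2.values():
            assert 0.0 <= v <= 1.0


class TestPathAnalysis:
    def test_full_run_reports_all_seven_paths(self, default_sim):
        dataset, tree, _ = default_sim
        result = run_path_analysis(dataset, tree=tree)
        assert set(result.path_table.edge) == {f"P{i}" for i in range(1, 8)}
        assert result.fisher_df == 2 * len(result.claims) == 4
        assert set(result.r2) == {"endemic", "ploidy"}
        # serialization round-trip
        report = result.to_dict()
        assert {p["edge"] for p in report["paths"]} == set(
            result.path_table.edge)
        assert len(report["dsep"]["claims"]) == 2

    def test_detects_known_strong_paths(self, default_sim):
        dataset, tree, _ = default_sim
        result = run_path_analysis(dataset, tree=tree)
        tab = result.path_table.set_index("edge")
        # generator defaults: P1, P3, P4 are strong effects
        for edge in ("P1", "P3", "P4"):
            assert tab.loc[edge, "significant"], edge
        assert tab.loc["P3", "estimate"] > 0

    def test_reduces_to_single_pgls_with_empty_basis(self, default_sim):
        dataset, tree, _ = default_sim
        # all five remaining nodes point into EndemicDiversity: no missing
        # edges involving an endogenous node, hence an empty basis set
        g = nx.DiGraph()
        for i, node in enumerate(["StemAge", "PloidyChange", "SourcePool",
                                  "RepeatColonization", "PloidyLevels"]):
            g.add_edge(node, "EndemicDiversity", label=f"E{i}")
        dag = CausalDiagram(g)
        specs = {"endemic": endemic_spec()}
        result = run_path_analysis(dataset, tree=tree, dag=dag, specs=specs)
        assert result.claims == []
        assert (result.fisher_c, result.fisher_df,
                result.fisher_p) == (0.0, 0, 1.0)
        cov = brownian_cov(tree, tip_order=dataset.lineage_ids)
        X, y, terms = build_design(dataset, endemic_spec())
        direct = fit_weighted_pgls(X, y, cov.R, dataset.weights_species,
                                   terms=terms)
        np.testing.assert_allclose(result.fits["endemic"].beta, direct.beta,
                                   atol=1e-12)

    def test_dsep_flags_a_truly_missing_path(self):
        # simulate with a real RepeatColonization -> PloidyLevels effect the
        # diagram omits; that claim should reject far more often than 5%
        rng = np.random.default_rng(55)
        rejected = n_ok = 0
        n_reps = 25
        for _ in range(n_reps):
            params = SimulationParams(seed=int(rng.integers(2**31 - 1)),
                                      round_counts=False)
            params.ploidy_coefs = dict(params.ploidy_coefs,
                                       monophyletic=0.8)
            dataset, tree, _ = simulate_dataset(params)
            try:
                result = run_path_analysis(dataset, tree=tree)
            except RuntimeError:
                continue  # rank-deficient draw (e.g. a lone JF lineage)
            claim = next(c for c in result.claims
                         if c.added == "RepeatColonization")
            rejected += int(claim.p_value < 0.05)
            n_ok += 1
        assert n_ok >= 20
        assert rejected / n_ok > 0.8

    def test_stage_error_is_labeled(self, default_sim):
        dataset, _, _ = default_sim
        with pytest.raises(RuntimeError, match="covariance"):
            run_path_analysis(dataset, tree=None, cov=None)
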