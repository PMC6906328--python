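"""DEG profile, random walk with restart, rank correlation, empirical null."""

import numpy as np
import networkx as nx
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import graftpath as gp
from graftpath.data import ConvergenceError
from graftpath.propagation import RWROperator

from conftest import make_expression


# ---------------------------------------------------------------------------
# DEG profile
# ---------------------------------------------------------------------------


class TestDEGProfile:
    def test_signed_ranking_descends_with_fold_change(self):
        expr = make_expression(
            {("S1", "t3"): [8.0, 4.0, 2.0], ("S2", "t3"): [2.0, 2.0, 2.0]},
            ["up2", "up1", "flat"],
        )
        deg = gp.build_deg_profile(expr, ("S1", "t3"), ("S2", "t3"))
        assert deg.ranks["up2"] == 1 and deg.ranks["up1"] == 2 and deg.ranks["flat"] == 3

    def test_ties_get_mid_ranks(self):
        expr = make_expression(
            {("S1", "t3"): [4.0, 4.0, 2.0], ("S2", "t3"): [2.0, 2.0, 2.0]},
            ["a", "b", "c"],
        )
        deg = gp.build_deg_profile(expr, ("S1", "t3"), ("S2", "t3"))
        assert deg.ranks["a"] == deg.ranks["b"] == 1.5
        assert deg.ranks["c"] == 3

    def test_low_abundance_gene_excluded_before_ranking(self):
        expr = make_expression(
            {("S1", "t3"): [5.0, 5.0], ("S2", "t3"): [0.99, 2.0]},
            ["filtered", "kept"],
        )
        deg = gp.build_deg_profile(expr, ("S1", "t3"), ("S2", "t3"))
        assert deg.gene_ids == ["kept"]

    def test_absolute_ranking_uses_magnitude(self):
        expr = make_expression(
            {("S1", "t3"): [1.0, 16.0], ("S2", "t3"): [16.0, 4.0]},
            ["down4", "up2"],
        )
        deg = gp.build_deg_profile(expr, ("S1", "t3"), ("S2", "t3"), rank_by="absolute")
        assert deg.ranks["down4"] == 1  # |−4| beats |+2|

    def test_empty_survivor_set_raises(self):
        expr = make_expression({("S1", "t3"): [0.1], ("S2", "t3"): [0.2]}, ["g"])
        with pytest.raises(ValueError, match="no gene survived"):
            gp.build_deg_profile(expr, ("S1", "t3"), ("S2", "t3"))


# ---------------------------------------------------------------------------
# Random walk with restart
# ---------------------------------------------------------------------------


def _dense_solve(graph, seeds, r, normalization="symmetric"):
    """Closed-form RWR: s = r (I − (1−r) W)^{-1} s0 on a dense matrix."""
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    a = nx.to_numpy_array(graph, nodelist=nodes)
    deg = a.sum(axis=1)
    w = np.zeros_like(a)
    nz = deg > 0
    if normalization == "symmetric":
        d = np.zeros_like(deg)
        d[nz] = 1.0 / np.sqrt(deg[nz])
        w = np.outer(d, d) * a
    else:
        w = a / np.where(deg > 0, deg, 1.0)[None, :]
    s0 = np.zeros(len(nodes))
    for s in seeds:
        s0[idx[s]] = 1.0 / len(seeds)
    sol = r * np.linalg.solve(np.eye(len(nodes)) - (1 - r) * w, s0)
    return pd.Series(sol, index=nodes)


class TestPropagate:
    def test_seed_dominates_on_two_node_graph(self):
        g = nx.Graph([("A", "B")])
        res = gp.propagate(g, {"A"}, restart_prob=0.5)
        assert res.scores["A"] > res.scores["B"] > 0

    def test_complete_graph_symmetry(self):
        g = nx.complete_graph(5)
        res = gp.propagate(g, {0})
        non_seed = res.scores[[1, 2, 3, 4]]
        assert np.allclose(non_seed, non_seed.iloc[0])

    @pytest.mark.parametrize("normalization", ["symmetric", "column"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_iterative_matches_dense_linear_solve(self, seed, normalization):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(10, 0.4, seed=seed)
        seeds = {int(s) for s in rng.choice(10, size=2, replace=False)}
        res = gp.propagate(g, seeds, restart_prob=0.5, tol=1e-12, normalization=normalization)
        oracle = _dense_solve(g, seeds, 0.5, normalization)
        assert np.allclose(res.scores[sorted(g.nodes)], oracle, atol=1e-8)

    def test_column_stochastic_preserves_mass(self):
        g = nx.barabasi_albert_graph(60, 3, seed=5)
        res = gp.propagate(g, {0, 1, 2}, normalization="column", tol=1e-12)
        assert res.scores.sum() == pytest.approx(1.0, abs=1e-9)

    def test_unmapped_seeds_dropped_with_warning(self, caplog):
        g = nx.path_graph(4)
        with caplog.at_level("WARNING", logger="graftpath"):
            res = gp.propagate(g, {0, "absent"})
        assert "dropped" in caplog.text
        assert res.parameters["n_seeds_used"] == 1

    def test_all_seeds_unmapped_raises(self):
        with pytest.raises(ValueError, match="no seed gene maps"):
            gp.propagate(nx.path_graph(4), {"absent"})

    def test_non_convergence_reports_residual(self):
        g = nx.path_graph(30)
        with pytest.raises(ConvergenceError, match="residual"):
            gp.propagate(g, {0}, tol=1e-15, max_iter=2)

    def test_ranks_descend_with_score(self):
        g = nx.barabasi_albert_graph(40, 2, seed=3)
        res = gp.propagate(g, {0})
        ordered = res.scores.sort_values(ascending=False)
        assert list(res.ranks[ordered.index]) == sorted(res.ranks)


# ---------------------------------------------------------------------------
# Rank correlation
# ---------------------------------------------------------------------------


def _prop_from_scores(scores: dict[str, float]) -> gp.PropagationResult:
    s = pd.Series(scores)
    from scipy.stats import rankdata

    return gp.PropagationResult(
        scores=s, ranks=pd.Series(rankdata(-s.to_numpy()), index=s.index)
    )


def _deg_from_ranks(ranks: dict[str, float]) -> gp.DEGProfile:
    r = pd.Series(ranks, dtype=float)
    l2fc = -r  # any anti-monotone transform of the ranks
    return gp.DEGProfile(log2fc=l2fc, ranks=r)


class TestRankCorrelation:
    def test_identical_rankings_give_one(self):
        prop = _prop_from_scores({"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0})
        deg = _deg_from_ranks({"a": 1, "b": 2, "c": 3, "d": 4})
        coeff, _ = gp.rank_correlation(prop, deg)
        assert coeff == pytest.approx(1.0)

    def test_reversed_rankings_give_minus_one(self):
        prop = _prop_from_scores({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        deg = _deg_from_ranks({"a": 1, "b": 2, "c": 3, "d": 4})
        coeff, _ = gp.rank_correlation(prop, deg)
        assert coeff == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # prop ranks 1,2,3,4 vs deg ranks 2,1,4,3: Pearson on ranks = 3/5
        prop = _prop_from_scores({"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0})
        deg = _deg_from_ranks({"a": 2, "b": 1, "c": 4, "d": 3})
        coeff, p = gp.rank_correlation(prop, deg)
        assert coeff == pytest.approx(0.6)
        assert 0 < p <= 1

    def test_restricted_to_intersection(self):
        prop = _prop_from_scores({"a": 4.0, "b": 3.0, "c": 2.0, "only_prop": 9.0})
        deg = _deg_from_ranks({"a": 1, "b": 2, "c": 3, "only_deg": 4})
        coeff, _ = gp.rank_correlation(prop, deg)
        assert coeff == pytest.approx(1.0)

    def test_too_few_common_genes_raises(self):
        prop = _prop_from_scores({"a": 1.0, "b": 2.0})
        deg = _deg_from_ranks({"a": 1, "b": 2})
        with pytest.raises(ValueError, match=">= 3 genes"):
            gp.rank_correlation(prop, deg)

    def test_matches_scipy_spearman_on_scores(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(50)]
        prop = _prop_from_scores(dict(zip(genes, rng.random(50))))
        l2fc = pd.Series(rng.normal(size=50), index=genes)
        from scipy.stats import rankdata

        deg = gp.DEGProfile(log2fc=l2fc, ranks=pd.Series(rankdata(-l2fc), index=genes))
        coeff, _ = gp.rank_correlation(prop, deg)
        expected = spearmanr(prop.scores[genes], l2fc[genes]).statistic
        assert coeff == pytest.approx(expected)


class TestTopK:
    def test_k_equal_to_all_genes_matches_full_correlation(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(20)]
        prop = _prop_from_scores(dict(zip(genes, rng.random(20))))
        deg = _deg_from_ranks(dict(zip(genes, rng.permutation(20) + 1.0)))
        assert gp.top_k_correlation(prop, deg, 20) == pytest.approx(
            gp.rank_correlation(prop, deg)
        )

    def test_toy_top3_matches_hand_enumeration(self):
        # prop scores pick {a, b, c}; their deg ranks 3,1,2 re-rank to the
        # same; Pearson([1,2,3],[3,1,2]) = -0.5
        prop = _prop_from_scores({"a": 5.0, "b": 4.0, "c": 3.0, "d": 2.0, "e": 1.0})
        deg = _deg_from_ranks({"a": 3, "b": 1, "c": 2, "d": 4, "e": 5})
        coeff, _ = gp.top_k_correlation(prop, deg, 3)
        assert coeff == pytest.approx(-0.5)

    def test_boundary_ties_resolved_by_gene_id(self):
        prop = _prop_from_scores({"a": 5.0, "b": 3.0, "c": 3.0, "d": 3.0, "e": 1.0})
        deg = _deg_from_ranks({"a": 1, "b": 2, "c": 3, "d": 4, "e": 5})
        # ties at the k=2 boundary: 'b' < 'c' < 'd', so {a, b} is selected
        coeff, _ = gp.top_k_correlation(prop, deg, 2)
        assert coeff == pytest.approx(1.0)

    def test_k_exceeding_common_genes_raises(self):
        prop = _prop_from_scores({"a": 1.0, "b": 2.0, "c": 3.0})
        deg = _deg_from_ranks({"a": 1, "b": 2, "c": 3})
        with pytest.raises(ValueError, match="exceeds"):
            gp.top_k_correlation(prop, deg, 4)


# ---------------------------------------------------------------------------
# Empirical null
# ---------------------------------------------------------------------------


class TestEmpiricalP:
    def test_reference_above_all_gives_zero(self):
        assert gp.empirical_p([0.1] * 1000, 0.5) == 0.0

    def test_reference_below_all_gives_one(self):
        assert gp.empirical_p([0.5] * 1000, 0.1) == 1.0

    def test_ten_of_thousand_gives_point_zero_one(self):
        coeffs = [0.9] * 10 + [0.1] * 990
        assert gp.empirical_p(coeffs, 0.5) == pytest.approx(0.010)

    def test_ties_do_not_count_as_exceeding(self):
        assert gp.empirical_p([0.5, 0.5, 0.4, 0.6], 0.5) == pytest.approx(0.25)

    def test_corrected_variant_never_zero(self):
        assert gp.empirical_p([0.1] * 99, 0.5, corrected=True) == pytest.approx(1 / 100)

    @settings(derandomize=True, max_examples=50)
    @given(
        coeffs=st.lists(st.floats(-1, 1, allow_nan=False), min_size=1, max_size=40),
        ref=st.floats(-1, 1, allow_nan=False),
    )
    def test_p_lies_on_the_lattice(self, coeffs, ref):
        p = gp.empirical_p(coeffs, ref)
        n = len(coeffs)
        assert p in {i / n for i in range(n + 1)}


@pytest.fixture(scope="module")
def toy():
    g = nx.barabasi_albert_graph(80, 3, seed=0)
    g = nx.relabel_nodes(g, {i: f"g{i:03d}" for i in range(80)})
    rng = np.random.default_rng(0)
    genes = sorted(g.nodes)
    l2fc = pd.Series(rng.normal(size=80), index=genes)
    from scipy.stats import rankdata

    deg = gp.DEGProfile(log2fc=l2fc, ranks=pd.Series(rankdata(-l2fc), index=genes))
    return g, deg


class TestEmpiricalPvalue:

    def test_deterministic_for_fixed_seed(self, toy):
        g, deg = toy
        p1, c1 = gp.empirical_pvalue(g, deg, 5, 0.2, n_sim=50, rng_seed=3)
        p2, c2 = gp.empirical_pvalue(g, deg, 5, 0.2, n_sim=50, rng_seed=3)
        assert p1 == p2 and np.array_equal(c1, c2)

    def test_degree_matched_sampler_runs(self, toy):
        g, deg = toy
        ref_seeds = sorted(g.nodes)[:5]
        p, coeffs = gp.empirical_pvalue(
            g, deg, 5, 0.0, n_sim=20, sampler="degree_matched",
            rng_seed=1, reference_seeds=ref_seeds,
        )
        assert len(coeffs) == 20 and 0 <= p <= 1

    def test_degree_matched_requires_reference_seeds(self, toy):
        g, deg = toy
        with pytest.raises(ValueError, match="reference_seeds"):
            gp.empirical_pvalue(g, deg, 5, 0.0, n_sim=5, sampler="degree_matched")


class TestEvaluateHypotheses:
    def test_identical_seed_sets_give_identical_coefficients(self, small_dataset):
        ds = small_dataset
        deg = gp.build_deg_profile(ds.expression, ("S1", "t3"), ("S2", "t3"))
        seeds = ds.seeds[ds.truth.causal_hypothesis]
        res = gp.evaluate_hypotheses(
            ds.ppi, deg, {"h1": seeds, "h2": seeds}, n_sim=0, rng_seed=0
        )
        assert res[0].coefficient == pytest.approx(res[1].coefficient)

    def test_single_hypothesis_gives_sorted_singleton(self, small_dataset):
        ds = small_dataset
        deg = gp.build_deg_profile(ds.expression, ("S1", "t3"), ("S2", "t3"))
        res = gp.evaluate_hypotheses(
            ds.ppi, deg, {"only": ds.seeds[ds.truth.causal_hypothesis]},
            n_sim=10, rng_seed=0,
        )
        assert len(res) == 1
        assert res[0].empirical_p in {i / 10 for i in range(11)}

    def test_results_sorted_by_descending_coefficient(self, small_dataset):
        ds = small_dataset
        deg = gp.build_deg_profile(ds.expression, ("S1", "t3"), ("S2", "t3"))
        res = gp.evaluate_hypotheses(ds.ppi, deg, ds.seeds, n_sim=0, rng_seed=0)
        coeffs = [r.coefficient for r in res]
        assert coeffs == sorted(coeffs, reverse=True)

    def test_no_hypotheses_raises(self, small_dataset):
        ds = small_dataset
        deg = gp.build_deg_profile(ds.expression, ("S1", "t3"), ("S2", "t3"))
        with pytest.raises(ValueError, match="at least one hypothesis"):
            gp.evaluate_hypotheses(ds.ppi, deg, {})
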