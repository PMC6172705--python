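"""Edge weighting, Z scoring, greedy module growth and null calibration."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from gensnet.gens import (
    EPS,
    Module,
    calibrate_modules,
    edge_weight,
    edge_z,
    grow_module,
    module_from_genes,
    module_null,
    module_score,
    module_significance,
    sample_random_module,
    score_edges,
    search_all,
    top_gene_network,
)


def z_graph(edges: dict[tuple[str, str], float]) -> nx.Graph:
    """Graph with explicit per-edge Z scores (bypasses p/correlation plumbing)."""
    g = nx.Graph()
    for (a, b), z in edges.items():
        g.add_edge(a, b, Z=float(z))
    return g


class TestEdgeWeight:
    def test_upper_clamp(self):
        assert edge_weight(1.0, 1.0, 1.0) == pytest.approx(1 - 1e-16)

    def test_direct_product(self):
        assert edge_weight(0.5, 0.01, 0.02) == pytest.approx(1.0e-4)

    def test_absent_correlation_defaults_to_one(self):
        assert edge_weight(None, 0.1, 0.1) == pytest.approx(0.01)

    def test_zero_correlation_floored(self):
        w = edge_weight(0.0, 0.5, 0.5)
        assert 0 < w <= EPS * 0.25 + EPS

    def test_negative_correlation_uses_magnitude(self):
        assert edge_weight(-0.5, 0.01, 0.02) == edge_weight(0.5, 0.01, 0.02)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_p_domain_error(self, bad):
        with pytest.raises(ValueError):
            edge_weight(0.5, bad, 0.5)

    @given(
        st.floats(1e-6, 1.0),
        st.floats(1e-6, 1.0),
        st.floats(1e-6, 1.0),
        st.floats(0.01, 0.2),
    )
    def test_monotone_in_each_argument(self, c, p_i, p_j, delta):
        base = edge_weight(c, p_i, p_j)
        assert edge_weight(min(c + delta, 1.0), p_i, p_j) >= base
        assert edge_weight(c, min(p_i + delta, 1.0), p_j) >= base
        # Z strictly decreasing in W
        w_lo, w_hi = sorted((base, edge_weight(c, p_i, min(p_j + delta, 1.0))))
        if w_lo < w_hi:
            assert edge_z(w_lo) > edge_z(w_hi)


class TestEdgeZ:
    @pytest.mark.parametrize(
        "w,expected",
        [
            (0.5, 0.0),
            (0.975, -1.959964),  # standard normal quantile, 2.5% lower tail
            (1e-4, 3.719016),
        ],
    )
    def test_quantile_values(self, w, expected):
        assert edge_z(w) == pytest.approx(expected, abs=1e-6)

    def test_out_of_domain(self):
        with pytest.raises(ValueError):
            edge_z(0.0)


class TestModuleScore:
    def test_mean(self):
        assert module_score([1, 2, 3]) == pytest.approx(2.0)

    def test_single_edge(self):
        assert module_score([5]) == pytest.approx(5.0)

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(1)
        zs = rng.normal(size=100)
        brute = sum(float(z) for z in zs) / len(zs)
        assert module_score(zs) == pytest.approx(brute, abs=1e-12)

    def test_sqrt_normalization(self):
        assert module_score([1, 2, 3], norm="sqrt") == pytest.approx(6 / np.sqrt(3))

    def test_edgeless_module_is_error(self):
        with pytest.raises(ValueError):
            module_score([])


class TestGrowModule:
    def test_zero_increment_rejected_on_homogeneous_triangle(self):
        g = z_graph({("A", "B"): 2.0, ("B", "C"): 2.0, ("A", "C"): 2.0})
        mod = grow_module(g, ("A", "B"))
        assert mod.genes == {"A", "B"}
        assert mod.z_m == pytest.approx(2.0)

    def test_improving_neighbor_admitted(self):
        g = z_graph({("A", "B"): 1.0, ("B", "C"): 10.0})
        mod = grow_module(g, ("A", "B"))
        assert mod.genes == {"A", "B", "C"}
        assert mod.z_m == pytest.approx(5.5)

    def test_subthreshold_improvement_rejected(self):
        # Z_m would rise from 10 to 10.25, an increment below 10 * r = 0.5
        g = z_graph({("A", "B"): 10.0, ("B", "C"): 10.5})
        mod = grow_module(g, ("A", "B"))
        assert mod.genes == {"A", "B"}

    def test_candidate_counts_all_edges_into_module(self):
        # C alone: (4+4)/3 < 4 rejected as single link, but both links count
        g = z_graph({("A", "B"): 4.0, ("A", "C"): 7.0, ("B", "C"): 7.0})
        mod = grow_module(g, ("A", "B"))
        assert mod.genes == {"A", "B", "C"}
        assert mod.z_m == pytest.approx(6.0)

    def test_missing_seed_edge(self):
        g = z_graph({("A", "B"): 1.0})
        with pytest.raises(ValueError):
            grow_module(g, ("A", "C"))

    def test_max_genes_caps_growth(self):
        g = z_graph({("A", "B"): 1.0, ("B", "C"): 5.0, ("C", "D"): 50.0})
        mod = grow_module(g, ("A", "B"), max_genes=3)
        assert len(mod.genes) == 3

    def test_score_never_below_seed_edge(self):
        rng = np.random.default_rng(7)
        g = nx.gnp_random_graph(30, 0.2, seed=3)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        for e in g.edges:
            g.edges[e]["Z"] = rng.normal(1, 2)
        for seed_edge in list(g.edges)[:20]:
            mod = grow_module(g, seed_edge)
            assert mod.z_m >= g.edges[seed_edge]["Z"] - 1e-12

    def test_planted_clique_recovered_under_sqrt_norm(self):
        # with sum/sqrt(k) scoring a strong 6-clique is absorbed exactly
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            g = nx.barabasi_albert_graph(200, 2, seed=seed)
            g = nx.relabel_nodes(g, {i: f"N{i:03d}" for i in g.nodes})
            for e in g.edges:
                g.edges[e]["Z"] = rng.normal(1.0, 0.3)
            clique = [f"N{i:03d}" for i in rng.choice(200, 6, replace=False)]
            best = None
            for i, a in enumerate(clique):
                for b in clique[i + 1:]:
                    g.add_edge(a, b, Z=rng.normal(8, 1))
                    if best is None or g.edges[a, b]["Z"] > g.edges[best]["Z"]:
                        best = (a, b)
            mod = grow_module(g, best, norm="sqrt")
            jac = len(mod.genes & set(clique)) / len(mod.genes | set(clique))
            if mod.genes >= set(clique) and jac >= 0.8:
                hits += 1
        assert hits >= 18

    def test_mean_norm_stays_at_seed_on_homogeneous_clique(self):
        # the printed mean score cannot rise above the best edge, so a
        # uniform-Z clique is never absorbed from its top seed edge
        clique = ["A", "B", "C", "D", "E"]
        g = z_graph(
            {(a, b): 6.0 for i, a in enumerate(clique) for b in clique[i + 1:]}
        )
        mod = grow_module(g, ("A", "B"))
        assert mod.genes == {"A", "B"}


class TestSearchAll:
    def test_two_components_two_modules(self):
        g = z_graph({("A", "B"): 1.0, ("C", "D"): 2.0})
        mods = search_all(g)
        assert len(mods) == 2
        assert mods[0].z_m >= mods[1].z_m

    def test_identical_gene_sets_deduplicated(self):
        g = z_graph({("A", "B"): 1.0, ("B", "C"): 10.0, ("A", "C"): 10.0})
        mods = search_all(g)
        gene_sets = [m.genes for m in mods]
        assert len(gene_sets) == len(set(gene_sets))

    def test_modules_connected_and_edge_induced(self):
        rng = np.random.default_rng(11)
        g = nx.gnp_random_graph(50, 0.08, seed=5)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        for e in g.edges:
            g.edges[e]["Z"] = rng.normal(1, 2)
        for mod in search_all(g):
            sub = g.subgraph(mod.genes)
            assert nx.is_connected(sub)
            assert mod.edges == {tuple(sorted(e)) for e in sub.edges}
            assert mod.z_m == pytest.approx(
                module_score([g.edges[e]["Z"] for e in mod.edges])
            )

    def test_top_q_policy_restricts_seeds(self):
        g = z_graph({("A", "B"): 9.0, ("C", "D"): 1.0, ("E", "F"): 1.0})
        mods = search_all(g, seed_policy="top-q-edges", top_q=0.34)
        assert len(mods) == 1 and mods[0].genes == {"A", "B"}


class TestRandomModules:
    def test_forced_path(self):
        g = z_graph({("A", "B"): 1.0, ("B", "C"): 1.0})
        rng = np.random.default_rng(0)
        assert sample_random_module(g, 3, rng) == {"A", "B", "C"}

    def test_star_two_sets_always_contain_hub(self):
        g = z_graph({("HUB", leaf): 1.0 for leaf in ("L1", "L2", "L3", "L4")})
        rng = np.random.default_rng(1)
        draws = [frozenset(sample_random_module(g, 2, rng)) for _ in range(200)]
        assert all("HUB" in d for d in draws)
        assert set(draws) == {frozenset({"HUB", leaf}) for leaf in ("L1", "L2", "L3", "L4")}

    def test_connectivity_contract(self):
        rng = np.random.default_rng(2)
        g = nx.gnp_random_graph(25, 0.12, seed=4)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        for _ in range(50):
            members = sample_random_module(g, 4, rng)
            assert nx.is_connected(g.subgraph(members))

    def test_component_too_small_is_error(self):
        g = z_graph({("A", "B"): 1.0, ("C", "D"): 1.0})
        with pytest.raises(ValueError):
            sample_random_module(g, 3, np.random.default_rng(0))


class TestModuleNull:
    def test_degenerate_flagged(self, caplog):
        g = z_graph({("A", "B"): 2.0, ("B", "C"): 2.0, ("A", "C"): 2.0})
        with caplog.at_level("WARNING"):
            null = module_null(g, 2, n_sim=50, seed=1)
        assert null.degenerate
        assert np.all(null.scores == 2.0)

    def test_nonpositive_n_sim_is_error(self):
        g = z_graph({("A", "B"): 1.0})
        with pytest.raises(ValueError):
            module_null(g, 2, n_sim=0, seed=1)

    def test_fixed_seed_identical(self):
        g = nx.gnp_random_graph(20, 0.2, seed=2)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        rng = np.random.default_rng(3)
        for e in g.edges:
            g.edges[e]["Z"] = rng.normal(1, 1)
        n1 = module_null(g, 4, n_sim=100, seed=5)
        n2 = module_null(g, 4, n_sim=100, seed=5)
        assert np.array_equal(n1.scores, n2.scores)


class TestModuleSignificance:
    def test_counting_rule(self):
        from gensnet.gens import ModuleNull

        null = ModuleNull(2, np.array([1.0, 1.0, 3.0]), 5 / 3, 1.1547, 3, 0)
        mod = Module(frozenset("AB"), frozenset({("A", "B")}), 2.0, ("A", "B"))
        p, _ = module_significance(mod, null)
        assert p == pytest.approx((1 + 1) / (3 + 1))

    def test_z_n(self):
        from gensnet.gens import ModuleNull

        null = ModuleNull(2, np.array([2.0, 4.0]), 3.0, 1.0, 2, 0)
        mod = Module(frozenset("AB"), frozenset({("A", "B")}), 5.0, ("A", "B"))
        p, z_n = module_significance(mod, null)
        assert z_n == pytest.approx(2.0)

    def test_low_score_p_near_one(self):
        from gensnet.gens import ModuleNull

        null = ModuleNull(2, np.arange(1.0, 101.0), 50.5, 29.0, 100, 0)
        mod = Module(frozenset("AB"), frozenset({("A", "B")}), 0.0, ("A", "B"))
        p, _ = module_significance(mod, null)
        assert p == pytest.approx(1.0)

    def test_size_mismatch(self):
        from gensnet.gens import ModuleNull

        null = ModuleNull(3, np.array([1.0, 2.0]), 1.5, 0.7, 2, 0)
        mod = Module(frozenset("AB"), frozenset({("A", "B")}), 1.0, ("A", "B"))
        with pytest.raises(ValueError):
            module_significance(mod, null)

    def test_degenerate_null_keeps_p_drops_z_n(self):
        from gensnet.gens import ModuleNull

        null = ModuleNull(2, np.array([2.0, 2.0]), 2.0, 0.0, 2, 0)
        mod = Module(frozenset("AB"), frozenset({("A", "B")}), 5.0, ("A", "B"))
        p, z_n = module_significance(mod, null)
        assert z_n is None and 0 < p <= 1


def _mod(genes, p):
    gs = sorted(genes)
    edges = frozenset((gs[i], gs[i + 1]) for i in range(len(gs) - 1))
    return Module(frozenset(gs), edges, 1.0, (gs[0], gs[1]), p_empirical=p)


class TestTopGeneNetwork:
    def test_degenerate_quartile_fallback(self, path4):
        modules = (
            [_mod(["A", "B"], 0.01)] * 10 + [_mod(["C", "D"], 0.01)]
        )
        graph = path4
        # counts A:10 B:10 C:1 D:1 → Q3=10, strictly-above empty → fallback >=
        top, freq = top_gene_network(modules, graph)
        assert set(top.nodes) == {"A", "B"}
        assert freq["A"] == 10 and freq["C"] == 1

    def test_single_module_keeps_all_genes(self, path4):
        top, freq = top_gene_network([_mod(["A", "B", "C"], 0.001)], path4)
        assert set(top.nodes) == {"A", "B", "C"}

    def test_no_significant_modules(self, path4, caplog):
        with caplog.at_level("WARNING"):
            top, freq = top_gene_network([_mod(["A", "B"], 0.9)], path4)
        assert top.number_of_nodes() == 0 and freq.empty

    def test_concentrated_modules_yield_planted_superset(self):
        clique = ["C1", "C2", "C3", "C4"]
        g = nx.complete_graph(4)
        g = nx.relabel_nodes(g, dict(enumerate(clique)))
        for i in range(30):
            g.add_edge("C1", f"X{i}")
        modules = []
        rng = np.random.default_rng(8)
        for i in range(100):
            extra = f"X{rng.integers(30)}"
            modules.append(_mod(clique + [extra], 0.01))
        top, _ = top_gene_network(modules, g)
        assert set(clique) <= set(top.nodes)


def test_score_edges_annotates_and_defaults(score_table):
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    table = score_table({"A": 0.1, "B": 0.2})  # C unscored → p=1
    scored = score_edges(g, table)
    assert scored.nodes["C"]["p"] == 1.0
    w = scored.edges["A", "B"]["W"]
    assert w == pytest.approx(0.02)
    assert scored.edges["A", "B"]["Z"] == pytest.approx(float(stats.norm.isf(0.02)))
    assert scored.edges["A", "B"]["C"] is None


def test_calibrate_modules_attaches_p_and_caches(score_table):
    rng = np.random.default_rng(4)
    g = nx.gnp_random_graph(30, 0.15, seed=6)
    g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
    table = score_table({n: float(rng.uniform(0.001, 1)) for n in g.nodes})
    scored = score_edges(g, table)
    mods = search_all(scored)
    cache = calibrate_modules(mods, scored, n_sim=200, seed=2)
    assert set(cache) == {len(m.genes) for m in mods}
    for m in mods:
        assert 0 < m.p_empirical <= 1


def test_module_from_genes_validates_connectivity():
    g = z_graph({("A", "B"): 1.0, ("C", "D"): 1.0})
    with pytest.raises(ValueError):
        module_from_genes(g, ["A", "B", "C"])
    mod = module_from_genes(g, ["A", "B"])
    assert mod.z_m == pytest.approx(1.0)
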