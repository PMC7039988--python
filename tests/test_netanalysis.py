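import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from diffinteractome.diffcore import DifferentialCall
from diffinteractome.netanalysis import (
    build_network,
    extract_modules,
    identify_dips,
    module_significance_kw,
    random_network_null,
    score_modules,
    topology,
)


def call(a, b, label="activated", q=None, state=5, f_ctrl=0.05, f_case=0.6):
    qv = np.full(9, np.nan)
    qv[state - 1] = q if q is not None else (0.95 if label == "activated" else 0.05)
    fc = np.zeros(9)
    ft = np.zeros(9)
    fc[state - 1] = f_ctrl
    ft[state - 1] = f_case
    passes = np.zeros(9, bool)
    passes[state - 1] = True
    return DifferentialCall(
        interaction=(a, b), q=qv, freq_control=fc, freq_case=ft,
        passes=passes, label=label, deciding_state=state,
    )


def graph_from_edges(edges, label="activated"):
    return build_network([call(a, b, label=label) for a, b in edges])


# -- independent topology oracle -------------------------------------------

def oracle_topology(g):
    """All metrics recomputed from first principles (Floyd-Warshall paths)."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    deg = np.array([g.degree(v) for v in nodes], dtype=float)

    # local clustering by direct triangle counting
    local = []
    for v in nodes:
        nb = list(g.neighbors(v))
        k = len(nb)
        if k < 2:
            local.append(0.0)
            continue
        links = sum(
            1 for i in range(k) for j in range(i + 1, k)
            if g.has_edge(nb[i], nb[j])
        )
        local.append(2 * links / (k * (k - 1)))
    clustering = float(np.mean(local))

    heterogeneity = float(deg.std() / deg.mean()) if deg.mean() > 0 else None
    centralization = (
        float((deg.max() - deg).sum() / ((n - 1) * (n - 2))) if n >= 3 else None
    )

    # Floyd-Warshall on the largest component
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for a, b in g.edges:
        dist[idx[a], idx[b]] = dist[idx[b], idx[a]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, k, None] + dist[None, k, :])
    comps = list(nx.connected_components(g))
    lcc = sorted(max(comps, key=len))
    li = [idx[v] for v in lcc]
    if len(li) >= 2:
        sub = dist[np.ix_(li, li)]
        pairs = sub[np.triu_indices(len(li), 1)]
        diameter = float(pairs.max())
        cpl = float(pairs.mean())
    else:
        diameter = cpl = None
    return clustering, heterogeneity, centralization, diameter, cpl


class TestBuildNetwork:
    def test_empty_input_gives_empty_graph(self):
        g = build_network([])
        assert g.number_of_nodes() == 0

    def test_shared_protein_star(self):
        g = graph_from_edges([("H", "A"), ("H", "B"), ("H", "C")])
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 3

    def test_unlabeled_call_rejected(self):
        c = call("A", "B")
        c.label = "none"
        with pytest.raises(ValueError):
            build_network([c])

    def test_labels_survive_file_round_trip(self, tmp_path):
        from diffinteractome.io_formats import read_network, write_network

        g = build_network(
            [call("A", "B", "activated"), call("B", "C", "repressed")]
        )
        rows = [(a, b, d["label"], d["q"], d["state"]) for a, b, d in g.edges(data=True)]
        write_network(rows, tmp_path / "n.tsv")
        back = read_network(tmp_path / "n.tsv")
        assert {(a, b, lab) for a, b, lab, _, _ in back} == {
            ("A", "B", "activated"), ("B", "C", "repressed")
        }


class TestTopology:
    def test_triangle_closed_forms(self):
        rep = topology(graph_from_edges([("A", "B"), ("B", "C"), ("A", "C")]))
        assert rep.clustering_coefficient == pytest.approx(1.0)
        assert rep.diameter == 1
        assert rep.centralization == pytest.approx(0.0)
        assert rep.characteristic_path_length == pytest.approx(1.0)
        assert rep.heterogeneity == pytest.approx(0.0)

    def test_star_with_three_leaves(self):
        rep = topology(graph_from_edges([("H", "A"), ("H", "B"), ("H", "C")]))
        assert rep.centralization == pytest.approx(1.0)
        # degrees (3,1,1,1): SD/mean = sqrt(3)/2 / 1.5
        assert rep.heterogeneity == pytest.approx(math.sqrt(3) / 2 / 1.5)
        assert rep.avg_neighbors == pytest.approx(1.5)
        assert rep.clustering_coefficient == pytest.approx(0.0)

    def test_path_graph_on_four_nodes(self):
        rep = topology(graph_from_edges([("A", "B"), ("B", "C"), ("C", "D")]))
        assert rep.diameter == 3
        # pair distances 1,1,1,2,2,3 over 6 pairs
        assert rep.characteristic_path_length == pytest.approx(10 / 6)

    def test_matches_oracle_on_small_random_graphs(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 9))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.9)),
                                    seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            h = graph_from_edges([(f"N{a}", f"N{b}") for a, b in g.edges])
            rep = topology(h)
            clus, het, cent, diam, cpl = oracle_topology(h)
            assert rep.clustering_coefficient == pytest.approx(clus)
            assert rep.heterogeneity == pytest.approx(het)
            if cent is not None:
                assert rep.centralization == pytest.approx(cent)
            assert rep.diameter == diam
            assert rep.characteristic_path_length == pytest.approx(cpl)

    def test_single_edge_graph_has_no_centralization(self):
        rep = topology(graph_from_edges([("A", "B")]))
        assert rep.centralization is None
        assert rep.diameter == 1

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            topology(nx.Graph())


class TestIdentifyDips:
    def test_degree_min_star_hub(self):
        g = graph_from_edges([("H", c) for c in "ABCDE"])
        dips = identify_dips(g, rule="degree_min", param=5)
        assert [d.protein for d in dips] == ["H"]
        assert dips[0].dip_class == "II"  # all edges activated

    def test_pure_repressed_is_class_one_mixed_is_neither(self):
        g = build_network([
            call("H", "A", "repressed"), call("H", "B", "repressed"),
            call("X", "Y", "repressed"), call("X", "Z", "activated"),
        ])
        recs = {d.protein: d for d in identify_dips(g, rule="degree_min", param=2)}
        assert recs["H"].dip_class == "I"
        assert recs["X"].dip_class == "mixed"
        assert recs["X"].repressed_degree + recs["X"].activated_degree == 2

    def test_top_fraction_includes_ties_at_cutoff(self):
        # 6 nodes; degrees: H=4, A=B=D=2 (tied at the cutoff), C=X=1
        g = graph_from_edges(
            [("H", "A"), ("H", "B"), ("H", "C"), ("H", "D"), ("A", "B"), ("X", "D")]
        )
        dips = identify_dips(g, rule="top_fraction", param=0.2, min_degree=2)
        # ceil(0.2*6)=2 slots; the rank-2 tie at degree 2 pulls in A, B and D
        assert {d.protein for d in dips} == {"H", "A", "B", "D"}

    def test_monotone_in_degree_min(self, rng):
        g = graph_from_edges(
            [(f"N{a}", f"N{b}") for a, b in
             nx.gnm_random_graph(15, 30, seed=7).edges]
        )
        prev = None
        for k in (1, 2, 3, 4, 5):
            now = {d.protein for d in identify_dips(g, rule="degree_min", param=k)}
            if prev is not None:
                assert now <= prev
            prev = now

    def test_param_validation(self):
        g = graph_from_edges([("A", "B")])
        with pytest.raises(ValueError):
            identify_dips(g, rule="top_fraction", param=1.5)
        with pytest.raises(ValueError):
            identify_dips(g, rule="degree_min", param=0)


class TestModules:
    def test_module_is_closed_neighborhood_of_center(self):
        g = graph_from_edges([("H", "A"), ("H", "B"), ("H", "C"), ("H", "D")])
        (dip,) = identify_dips(g, rule="degree_min", param=4)
        (mod,) = extract_modules(g, [dip])
        assert len(mod.proteins) == 5
        assert set(mod.partners) == {"A", "B", "C", "D"}

    def test_partner_partner_edges_excluded(self):
        # triangle through the center: edge (A,B) must not join H's module
        g = graph_from_edges([("H", "A"), ("H", "B"), ("A", "B")])
        mods = extract_modules(g, identify_dips(g, rule="degree_min", param=2))
        assert len(mods) == 3  # every triangle node qualifies
        for mod in mods:
            center = mod.center.protein
            for c in mod.edges:
                assert center in c.interaction

    def test_adjacent_dips_give_overlapping_modules(self):
        g = graph_from_edges(
            [("H1", "H2"), ("H1", "A"), ("H1", "B"), ("H2", "C"), ("H2", "D")]
        )
        dips = identify_dips(g, rule="degree_min", param=3)
        mods = {m.center.protein: m for m in extract_modules(g, dips)}
        assert "H2" in mods["H1"].partners and "H1" in mods["H2"].partners

    def test_module_edges_cover_all_dip_incident_edges(self):
        g = graph_from_edges(
            [(f"N{a}", f"N{b}") for a, b in nx.gnm_random_graph(12, 25, seed=3).edges]
        )
        dips = identify_dips(g, rule="top_fraction", param=0.25)
        mods = extract_modules(g, dips)
        assert len(mods) == len(dips)
        covered = {
            frozenset(c.interaction) for m in mods for c in m.edges
        }
        dip_names = {d.protein for d in dips}
        expected = {
            frozenset((a, b)) for a, b in g.edges if {a, b} & dip_names
        }
        assert covered == expected


class TestModuleSignificance:
    def _module(self, f_cases, f_ctrls):
        calls = [
            call("H", f"P{i}", f_ctrl=fc, f_case=ft)
            for i, (ft, fc) in enumerate(zip(f_cases, f_ctrls))
        ]
        g = build_network(calls)
        (dip,) = [d for d in identify_dips(g, rule="degree_min", param=1)
                  if d.protein == "H"]
        (mod,) = extract_modules(g, [dip])
        return mod

    def test_identical_frequency_vectors_give_p_one(self):
        mod = self._module([0.4, 0.4, 0.4], [0.4, 0.4, 0.4])
        assert module_significance_kw(mod) == pytest.approx(1.0)

    def test_separated_frequencies_significant(self):
        mod = self._module(
            [0.7, 0.72, 0.74, 0.76, 0.78], [0.05, 0.06, 0.07, 0.08, 0.09]
        )
        assert module_significance_kw(mod) < 0.05

    def test_two_group_kw_equals_scipy_on_same_vectors(self):
        f_cases = [0.61, 0.55, 0.70, 0.48, 0.66]
        f_ctrls = [0.12, 0.20, 0.05, 0.33, 0.15]
        mod = self._module(f_cases, f_ctrls)
        _, expected = stats.kruskal(f_cases, f_ctrls)
        assert module_significance_kw(mod) == pytest.approx(expected)

    def test_single_edge_module_untestable(self):
        mod = self._module([0.5], [0.1])
        assert module_significance_kw(mod) is None
        score_modules([mod])
        assert mod.kw_p is None


class TestRandomNull:
    def test_gnm_preserves_node_and_edge_counts(self):
        g = graph_from_edges(
            [(f"N{a}", f"N{b}") for a, b in nx.gnm_random_graph(20, 40, seed=1).edges]
        )
        res = random_network_null(g, n_reps=19, model="gnm", seed=0)
        assert res["n_reps"] == 19
        assert res["avg_neighbors"]["p"] >= 1 / 20  # same density every draw

    def test_degree_preserving_keeps_degree_sequence(self):
        g = nx.gnm_random_graph(15, 30, seed=2)
        g = graph_from_edges([(f"N{a}", f"N{b}") for a, b in g.edges])
        base = sorted(d for _, d in g.degree())
        # heterogeneity is a pure degree-sequence statistic: its null must
        # be degenerate at the observed value
        res = random_network_null(g, n_reps=19, model="degree_preserving", seed=0)
        het = res["heterogeneity"]
        assert het["null_sd"] == pytest.approx(0.0, abs=1e-12)
        assert het["null_mean"] == pytest.approx(het["observed"])
        assert sorted(d for _, d in g.degree()) == base

    def test_empirical_p_bounds(self):
        g = graph_from_edges(
            [(f"N{a}", f"N{b}") for a, b in nx.gnm_random_graph(12, 20, seed=5).edges]
        )
        res = random_network_null(g, n_reps=39, model="gnm", seed=1)
        for key in ("clustering_coefficient", "heterogeneity"):
            p = res[key]["p"]
            assert 1 / 40 <= p <= 1.0

    def test_too_few_reps_rejected(self):
        g = graph_from_edges([("A", "B")])
        with pytest.raises(ValueError):
            random_network_null(g, n_reps=5)


def test_regular_graph_heterogeneity_zero_and_tree_clustering_zero():
    cycle = graph_from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
    rep = topology(cycle)
    assert rep.heterogeneity == pytest.approx(0.0)
    tree = graph_from_edges([("A", "B"), ("B", "C"), ("B", "D"), ("D", "E")])
    assert topology(tree).clustering_coefficient == pytest.approx(0.0)
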