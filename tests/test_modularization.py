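import numpy as np
import pandas as pd
import pytest

from oncosignal.modularization import (
    ModuleLandscape,
    community_centrality,
    detect_modules,
    discrete_assignment,
    influence_zone,
    match_modules,
    name_modules,
    overlap_metrics,
)

from conftest import make_weighted


def clique(prefix, k, weight=1.0):
    names = [f"{prefix}{i}" for i in range(k)]
    edges = [(names[i], names[j]) for i in range(k) for j in range(i + 1, k)]
    return names, edges, {e: weight for e in edges}


def bridged_cliques(bridge_weight=0.5, k=5):
    a_names, a_edges, a_w = clique("A", k)
    b_names, b_edges, b_w = clique("B", k)
    edges = a_edges + b_edges + [("A0", "B0")]
    weights = {**a_w, **b_w, ("A0", "B0"): bridge_weight}
    return a_names, b_names, make_weighted(edges, weights)


class TestInfluenceZone:
    def test_isolated_seed_keeps_all_influence(self):
        edges = [("A", "B"), ("C", "C2")]
        w = make_weighted(edges, {e: 1.0 for e in edges})
        z = influence_zone(w, "C")
        assert z["C"] == pytest.approx(1.5, abs=0.51)  # self plus bounce within pair
        z_pair = influence_zone(w, "A")
        assert z_pair[["C", "C2"]].sum() == 0.0  # influence stays in the component

    def test_star_center_symmetric_over_leaves(self):
        edges = [("HUB", f"L{i}") for i in range(6)]
        w = make_weighted(edges, {e: 2.0 for e in edges})
        z = influence_zone(w, "HUB")
        leaves = z[[f"L{i}" for i in range(6)]]
        assert leaves.nunique() == 1
        assert z["HUB"] == z.max()

    def test_line_graph_matches_matrix_power_oracle(self):
        edges = [("N1", "N2"), ("N2", "N3"), ("N3", "N4"), ("N4", "N5")]
        w = make_weighted(edges, {e: 1.0 for e in edges})
        z = influence_zone(w, "N1", lam=0.5, eps=1e-6)
        nodes = sorted(w.base.nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        adj = np.zeros((5, 5))
        for a, b in edges:
            adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = 1.0
        p = adj / adj.sum(axis=1, keepdims=True)
        inc = np.eye(5)[idx["N1"]].copy()
        acc = inc.copy()
        while True:
            inc = 0.5 * inc @ p
            if inc.sum() < 1e-6:
                break
            acc += inc
        assert np.allclose(z.loc[nodes].to_numpy(), acc, atol=1e-12)

    def test_invalid_parameters_rejected(self):
        w = make_weighted([("A", "B")], {("A", "B"): 1.0})
        with pytest.raises(ValueError):
            influence_zone(w, "A", lam=1.5)
        with pytest.raises(KeyError):
            influence_zone(w, "Z")


class TestDetectModules:
    def test_clique_collapses_to_single_module(self):
        _, edges, weights = clique("C", 4, weight=2.0)
        ls = detect_modules(make_weighted(edges, weights))
        assert ls.n_modules == 1
        assert np.allclose(ls.assignment.to_numpy(), 1.0)

    def test_bridged_cliques_recovered_exactly(self):
        a_names, b_names, w = bridged_cliques(bridge_weight=0.5)
        ls = detect_modules(w)
        assert ls.n_modules == 2
        assign = discrete_assignment(ls)
        groups = {}
        for n, m in assign.items():
            groups.setdefault(m, set()).add(n)
        assert set(map(frozenset, groups.values())) == {
            frozenset(a_names),
            frozenset(b_names),
        }

    def test_bridge_endpoints_overlap_both_modules(self):
        _, _, w = bridged_cliques(bridge_weight=1.0)
        ls = detect_modules(w)
        row = ls.assignment.loc["A0"]
        assert (row > 1e-6).sum() == 2
        assert 0 < row.min() < row.max() < 1

    def test_assignment_rows_sum_to_one_and_cores_are_members(self, small_states):
        _, _, weighted = small_states
        ls = detect_modules(weighted["normal"])
        sums = ls.assignment.sum(axis=1).to_numpy()
        assert np.allclose(sums, 1.0, atol=1e-9)
        assign = discrete_assignment(ls)
        for core in ls.module_cores:
            assert assign[core] == core
        # every module keeps at least one discrete member
        assert set(assign.values()) == set(ls.module_cores)

    def test_label_permutation_equivariance(self):
        _, edges, weights = clique("C", 4)
        extra = [("C0", "X"), ("X", "Y")]
        edges = edges + extra
        weights = {**weights, ("C0", "X"): 0.5, ("X", "Y"): 1.5}
        w = make_weighted(edges, weights)
        ls = detect_modules(w)
        mapping = {n: f"Z{ord(n[0])}{n[1:]}" for n in w.base.nodes}
        w2 = make_weighted(
            [(mapping[a], mapping[b]) for a, b in edges],
            {(mapping[a], mapping[b]): v for (a, b), v in weights.items()},
        )
        ls2 = detect_modules(w2)
        assert ls2.n_modules == ls.n_modules
        h1 = ls.height.rename(index=mapping).sort_index()
        assert np.allclose(h1.to_numpy(), ls2.height.sort_index().to_numpy())

    def test_strengthening_planted_module_does_not_reduce_membership(self):
        a_names, _, w = bridged_cliques(bridge_weight=0.5)
        ls = detect_modules(w)
        assign = discrete_assignment(ls)
        core_a = assign["A1"]
        base_strength = ls.assignment.loc[a_names].max(axis=1)
        boosted = {
            k: (v * 1.5 if k[0][0] == "A" and k[1][0] == "A" else v)
            for k, v in w.pair_weights.items()
        }
        w2 = make_weighted([(a, b) for a, b, _ in w.base.edges], boosted)
        ls2 = detect_modules(w2)
        strength = ls2.assignment.loc[a_names].max(axis=1)
        assert (strength.to_numpy() >= base_strength.to_numpy() - 1e-9).all()


class TestCentralityAndNaming:
    def test_star_center_strictly_dominates(self):
        edges = [("HUB", f"L{i}") for i in range(5)]
        ls = detect_modules(make_weighted(edges, {e: 1.0 for e in edges}))
        cent = community_centrality(ls)
        assert all(cent["HUB"] > cent[f"L{i}"] for i in range(5))

    def test_centrality_equals_incoming_zone_sum(self):
        edges = [("A", "B"), ("B", "C"), ("C", "D"), ("B", "D"), ("D", "E"), ("E", "F")]
        w = make_weighted(edges, {e: float(i + 1) for i, e in enumerate(edges)})
        ls = detect_modules(w)
        nodes = sorted(w.base.nodes)
        total = pd.Series(0.0, index=nodes)
        for seed in nodes:
            total += influence_zone(w, seed)
        assert np.allclose(ls.centrality.loc[nodes].to_numpy(), total.to_numpy(), atol=1e-9)

    def test_isolated_pairless_node_has_unit_centrality(self):
        edges = [("A", "B"), ("A", "C"), ("I", "I2")]
        w = make_weighted(edges, {("A", "B"): 1.0, ("A", "C"): 1.0, ("I", "I2"): 1e-12})
        # the I-I2 pair is near-isolated; influence on it from the triangle is 0
        ls = detect_modules(w)
        assert ls.centrality["I"] <= 2.0

    def test_module_named_after_top_centrality_member(self):
        a_names, b_names, w = bridged_cliques(bridge_weight=0.5)
        ls = detect_modules(w)
        names = name_modules(ls)
        assign = discrete_assignment(ls)
        cent = ls.centrality
        for mod, nm in names.items():
            members = [n for n, m in assign.items() if m == mod]
            assert nm in members
            assert cent[nm] == max(cent[m] for m in members)


class TestOverlapMetrics:
    def test_pure_and_uniform_rows(self):
        ls = ModuleLandscape(
            nodes=["A", "B"],
            module_cores=["M1", "M2"],
            assignment=pd.DataFrame(
                [[1.0, 0.0], [0.5, 0.5]], index=["A", "B"], columns=["M1", "M2"]
            ),
            centrality=pd.Series({"A": 1.0, "B": 1.0}),
            height=pd.Series({"A": 1.0, "B": 1.0}),
        )
        out = overlap_metrics(ls)
        assert out.loc["A", "modular_overlap"] == pytest.approx(1.0)
        assert out.loc["B", "modular_overlap"] == pytest.approx(2.0)

    def test_matches_entropy_oracle_and_weighted_degree(self, small_states):
        _, _, weighted = small_states
        w = weighted["normal"]
        ls = detect_modules(w)
        out = overlap_metrics(ls, w)
        a = ls.assignment.to_numpy()
        for i in range(0, len(ls.nodes), 7):
            row = a[i][a[i] > 0]
            expected = np.exp(-(row * np.log(row)).sum())
            assert out["modular_overlap"].iloc[i] == pytest.approx(expected)
        degrees = w.weighted_degree()
        assert np.allclose(
            out["effective_degree"].sort_index().to_numpy(),
            degrees.sort_index().to_numpy(),
        )


class TestMatchModules:
    def test_identical_landscapes_identity_mapping(self, small_states):
        _, _, weighted = small_states
        ls = detect_modules(weighted["normal"])
        match = match_modules(ls, ls)
        for pair in match.pairs:
            assert pair["from"] == pair["to"]
            assert pair["jaccard"] == pytest.approx(1.0)
            assert pair["annotation"] == ""

    def test_union_annotated_as_merge(self):
        def landscape(assign_map):
            nodes = sorted(assign_map)
            cores = sorted(set(assign_map.values()))
            a = pd.DataFrame(0.0, index=nodes, columns=cores)
            for n, m in assign_map.items():
                a.loc[n, m] = 1.0
            return ModuleLandscape(
                nodes=nodes,
                module_cores=cores,
                assignment=a,
                centrality=pd.Series(1.0, index=nodes),
                height=pd.Series(1.0, index=nodes),
            )

        a = landscape({"n1": "M1", "n2": "M1", "n3": "M2", "n4": "M2"})
        b = landscape({"n1": "U", "n2": "U", "n3": "U", "n4": "U"})
        match = match_modules(a, b)
        assert {p["annotation"] for p in match.pairs} == {"merge"}
        back = match_modules(b, a)
        assert back.pairs[0]["annotation"] == "split"

        disjoint = landscape({"x1": "M"})
        with pytest.raises(ValueError, match="share no nodes"):
            match_modules(a, disjoint)
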