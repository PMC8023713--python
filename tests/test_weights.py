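import itertools
import math

import numpy as np
import pytest
from scipy import stats

from oncosignal.io_formats import SignalingNetwork
from oncosignal.weights import (
    compute_link_weights,
    extreme_links,
    module_representation,
    paired_wilcoxon,
    summarize_weights,
)

from conftest import make_weighted, random_weighted


class TestComputeLinkWeights:
    def test_log10_of_product(self):
        net = SignalingNetwork.from_edges([("A", "B", "undirected")])
        w = compute_link_weights(net, {"A": 10.0, "B": 10.0})
        assert w.edge_weight("A", "B") == pytest.approx(2.0)
        w1 = compute_link_weights(net, {"A": 1.0, "B": 1.0})
        assert w1.edge_weight("A", "B") == pytest.approx(0.0)

    def test_matches_per_edge_oracle_on_random_network(self):
        rng = np.random.default_rng(5)
        w = random_weighted(rng, n_nodes=30, p=0.25)
        ab = {n: float(rng.uniform(0.5, 16)) for n in w.base.nodes}
        out = compute_link_weights(w.base, ab, log_base=10)
        for s, t, _ in w.base.edges:
            assert out.edge_weight(s, t) == pytest.approx(
                math.log10(ab[s] * ab[t]), abs=1e-12
            )

    def test_missing_abundance_names_gene(self):
        net = SignalingNetwork.from_edges([("A", "B", "undirected")])
        with pytest.raises(KeyError, match="B"):
            compute_link_weights(net, {"A": 2.0})

    def test_monotone_in_abundance(self):
        net = SignalingNetwork.from_edges(
            [("A", "B", "undirected"), ("B", "C", "activating")]
        )
        ab = {"A": 4.0, "B": 8.0, "C": 2.0}
        base = compute_link_weights(net, ab)
        raised = compute_link_weights(net, {**ab, "B": 9.0})
        for s, t, _ in net.edges:
            assert raised.edge_weight(s, t) >= base.edge_weight(s, t)

    def test_weight_multiset_invariant_under_relabeling(self):
        rng = np.random.default_rng(9)
        w = random_weighted(rng, n_nodes=15, p=0.3)
        ab = {n: float(rng.uniform(1, 16)) for n in w.base.nodes}
        out = compute_link_weights(w.base, ab)
        mapping = {n: f"X{n}" for n in w.base.nodes}
        renamed = SignalingNetwork.from_edges(
            [(mapping[s], mapping[t], k) for s, t, k in w.base.edges]
        )
        out2 = compute_link_weights(renamed, {mapping[n]: a for n, a in ab.items()})
        assert sorted(out.edge_weights()) == pytest.approx(sorted(out2.edge_weights()))


class TestSummarizeWeights:
    def test_basic_order_statistics(self):
        s = summarize_weights(np.array([1.0, 2.0, 3.0, 4.0]))
        assert (s.median, s.min, s.max) == (2.5, 1.0, 4.0)
        assert s.q1 <= s.median <= s.q3 and s.iqr == pytest.approx(s.q3 - s.q1)

    def test_degenerate_constant_weights(self):
        s = summarize_weights(np.full(6, 2.5))
        assert s.sd == 0 and s.iqr == 0
        assert s.bin_fractions == (0.0, 1.0, 0.0)

    def test_bin_fractions_closed_medium_interval(self):
        s = summarize_weights(np.array([1.9, 2.0, 2.5, 2.8]))
        assert s.bin_fractions == pytest.approx((0.25, 0.50, 0.25))
        assert sum(s.bin_fractions) == pytest.approx(1.0)

    def test_cumulative_curve_monotone_to_one(self):
        rng = np.random.default_rng(2)
        s = summarize_weights(rng.normal(2, 0.5, size=100))
        probs = [p for _, p in s.cumulative]
        values = [v for v, _ in s.cumulative]
        assert probs == sorted(probs) and probs[-1] == pytest.approx(1.0)
        assert values == sorted(values)

    def test_single_weight_rejected(self):
        with pytest.raises(ValueError):
            summarize_weights(np.array([1.0]))


def exact_p_by_enumeration(x, y):
    """Brute-force two-sided signed-rank p: all 2^n sign assignments."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    total = ranks.sum()
    stats_all = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(ranks))
    ]
    n_all = len(stats_all)
    p_le = sum(1 for w in stats_all if w <= observed + 1e-9) / n_all
    p_ge = sum(1 for w in stats_all if w >= observed - 1e-9) / n_all
    return min(1.0, 2 * min(p_le, p_ge))


class TestPairedWilcoxon:
    def test_toy_case_exact(self):
        w, p = paired_wilcoxon([1, 2, 3], [2, 3, 4])
        assert w == 0.0
        assert p == pytest.approx(0.25)

    def test_matches_enumeration_for_small_n(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(3, 13))
            x = rng.normal(size=n)
            y = x + rng.normal(scale=0.8, size=n)
            if np.all(x == y):
                continue
            _, p = paired_wilcoxon(x, y)
            assert p == pytest.approx(exact_p_by_enumeration(x, y), abs=1e-12)

    def test_handles_tied_ranks_exactly(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 4.0]  # |d| ties
        _, p = paired_wilcoxon(x, y)
        assert p == pytest.approx(exact_p_by_enumeration(x, y), abs=1e-12)

    def test_p_decreases_with_n_for_consistent_shift(self):
        ps = []
        for n in (6, 8, 10):
            x = np.arange(1, n + 1, dtype=float)
            ps.append(paired_wilcoxon(x, x + 0.5)[1])
        assert ps[0] > ps[1] > ps[2]

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_wilcoxon([1.0, 2.0], [1.0, 2.0])

    def test_exact_agrees_with_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=12)
        y = x + rng.normal(scale=0.5, size=12)
        _, p = paired_wilcoxon(x, y)
        ref = stats.wilcoxon(x, y, zero_method="wilcox", method="exact").pvalue
        assert p == pytest.approx(float(ref), abs=1e-12)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=60)
        y = x + rng.normal(scale=1.0, size=60) + 0.3
        _, p = paired_wilcoxon(x, y)
        ref = stats.wilcoxon(
            x, y, zero_method="wilcox", correction=False, method="approx"
        ).pvalue
        assert p == pytest.approx(float(ref), rel=1e-9)


class TestExtremeLinks:
    def ladder(self, n):
        names = [f"N{i:03d}" for i in range(n + 1)]
        edges = [(names[i], names[i + 1]) for i in range(n)]
        weights = {e: float(i + 1) for i, e in enumerate(edges)}
        return make_weighted(edges, weights)

    def test_ten_edges_top_and_bottom_singletons(self):
        w = self.ladder(10)
        rep = extreme_links(w, decile=0.1, percentile=0.01)
        assert len(rep.top_decile) == 1 and len(rep.bottom_decile) == 1
        (top,) = rep.top_decile
        (bottom,) = rep.bottom_decile
        assert w.edge_weight(top[0], top[1]) == 10.0
        assert w.edge_weight(bottom[0], bottom[1]) == 1.0

    def test_hundred_edges_forced_counts_and_subsets(self):
        rep = extreme_links(self.ladder(100))
        assert len(rep.top_decile) == 10 and len(rep.top_percentile) == 1
        assert rep.top_percentile <= rep.top_decile
        assert rep.bottom_percentile <= rep.bottom_decile
        assert not (rep.top_decile & rep.bottom_decile)

    def test_tie_break_matches_sort_oracle(self):
        rng = np.random.default_rng(4)
        w = random_weighted(rng, n_nodes=25, p=0.3)
        # quantize weights to force ties
        w.pair_weights = {k: round(v) * 1.0 for k, v in w.pair_weights.items()}
        rep = extreme_links(w, decile=0.2, percentile=0.04)
        edges = list(w.base.edges)
        by_weight = sorted(edges, key=lambda e: (w.edge_weight(e[0], e[1]), e))
        k = int(0.2 * len(edges))
        assert rep.bottom_decile == frozenset(by_weight[:k])
        by_weight_desc = sorted(edges, key=lambda e: (-w.edge_weight(e[0], e[1]), e))
        assert rep.top_decile == frozenset(by_weight_desc[:k])

    @pytest.mark.parametrize("bad", [0.5, 0.9, 0.0])
    def test_fraction_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            extreme_links(self.ladder(20), decile=bad)


class TestModuleRepresentation:
    def test_half_of_internal_edges_in_stratum(self):
        names = [f"M{i}" for i in range(5)]
        edges = [(names[i], names[j]) for i in range(5) for j in range(i + 1, 5)]
        weights = {e: float(k + 1) for k, e in enumerate(edges)}
        w = make_weighted(edges, weights)
        rep = extreme_links(w, decile=0.2, percentile=0.1)
        assign = {n: "M" for n in names}
        out = module_representation(rep, assign)
        assert out["M"]["top_decile"] == pytest.approx(2 / 10)

    def test_spanning_edges_count_for_neither(self):
        edges = [("A", "B"), ("B", "C"), ("C", "D")]
        w = make_weighted(edges, {e: float(i + 1) for i, e in enumerate(edges)})
        rep = extreme_links(w, decile=0.34, percentile=0.33)
        assign = {"A": "M1", "B": "M1", "C": "M2", "D": "M2"}
        out = module_representation(rep, assign)
        # each module has exactly one internal edge; B-C spans and counts nowhere
        assert out["M1"]["bottom_decile"] == 1.0  # A-B is the lightest edge
        assert out["M2"]["top_decile"] == 1.0  # C-D is the heaviest edge

    def test_matches_exhaustive_count_on_random_assignment(self):
        rng = np.random.default_rng(8)
        w = random_weighted(rng, n_nodes=30, p=0.25)
        rep = extreme_links(w, decile=0.2, percentile=0.05)
        mods = ["M1", "M2", "M3"]
        assign = {n: mods[int(rng.integers(0, 3))] for n in w.base.nodes}
        out = module_representation(rep, assign)
        for m in mods:
            internal = [
                e for e in w.base.edges if assign[e[0]] == assign[e[1]] == m
            ]
            for stratum in rep.STRATA:
                expected = (
                    sum(1 for e in internal if e in rep.stratum(stratum)) / len(internal)
                    if internal
                    else 0.0
                )
                assert out[m][stratum] == pytest.approx(expected)

    def test_uncovered_nodes_rejected(self):
        edges = [("A", "B"), ("B", "C")]
        w = make_weighted(edges, {e: 1.0 * i for i, e in enumerate(edges, 1)})
        rep = extreme_links(w, decile=0.4, percentile=0.3)
        with pytest.raises(ValueError, match="cover"):
            module_representation(rep, {"A": "M"})


class TestStateOrderings:
    def test_adenoma_dispersion_inflates_weight_sd(self, small_states):
        _, _, weighted = small_states
        sd = {s: summarize_weights(w).sd for s, w in weighted.items()}
        assert sd["adenoma"] > sd["normal"]
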