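"""Synthetic three-state study generator with ground truth.

Emulates the statistical structure the analysis assumes: a sparse typed
signaling network whose edge-type mix matches the curated human cancer
signaling topology (2403 activating / 741 inhibiting / 1915 undirected /
30 unknown out of 5089); log2-scale expression centered near 8 for three
states that share the topology; a planted connected module whose genes are
up-shifted in the "carcinoma" state; and gene-level dispersion inflation
in the "adenoma" state.  Every draw is driven by one integer seed, with
sorted iteration orders, so outputs are fully reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    INTERACTION_TYPES,
    ExpressionMatrix,
    GeneSetCollection,
    SignalingNetwork,
)

STATES = ("normal", "adenoma", "carcinoma")

#: Edge-type mix of the curated cancer signaling network (activating,
#: inhibiting, undirected, unknown out of 5089 links).
CANCER_SIGNALING_TYPE_MIX = (2403 / 5089, 741 / 5089, 1915 / 5089, 30 / 5089)


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults model a desk-scale version of the real study: a 300-node,
    1200-edge connected typed network; 50 samples per state of log2
    intensities centered at 8 (sd 1.5 across genes, 0.5 across samples);
    a planted connected module of 30 genes shifted up by ``delta`` = 1.0
    (log2) in carcinoma; and adenoma gene-level deviations inflated by
    ``kappa`` = 1.3.
    """

    n_nodes: int = 300
    n_edges: int = 1200
    type_proportions: tuple[float, float, float, float] = CANCER_SIGNALING_TYPE_MIX
    mixing: float = 0.1  # fraction of edges between topological groups
    n_samples: int = 50
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    planted_module_size: int = 30
    delta: float = 1.0  # carcinoma additive log2 shift on planted genes
    kappa: float = 1.3  # adenoma gene-level deviation inflation (>= 1)
    gamma: float = 0.15  # carcinoma compression of below-mean genes toward the mean
    sample_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.type_proportions) - 1.0) > 1e-9:
            raise ValueError("type_proportions must sum to 1")
        if self.n_nodes < 2 or self.n_edges < self.n_nodes - 1:
            raise ValueError("need n_edges >= n_nodes - 1 for a connected graph")
        if self.planted_module_size > self.n_nodes:
            raise ValueError("planted module larger than the network")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError("gamma must be in [0, 1)")
        if self.n_samples < 1 or self.sample_noise_sd <= 0:
            raise ValueError("invalid sampling parameters")


@dataclass
class GroundTruth:
    """What was planted: module members, true means, gene sets."""

    planted_members: list[str]
    true_means: pd.DataFrame  # genes x states
    gene_sets: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_members": self.planted_members,
            "true_means": {
                s: self.true_means[s].round(10).to_dict() for s in self.true_means
            },
            "gene_sets": self.gene_sets,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def largest_remainder(proportions: Sequence[float], total: int) -> list[int]:
    """Apportion ``total`` into integer counts by the largest-remainder rule.

    Each class receives floor(p * total); leftover units go to the classes
    with the largest fractional remainders (ties resolved by class order).
    """
    exact = [p * total for p in proportions]
    counts = [int(np.floor(e)) for e in exact]
    leftover = total - sum(counts)
    remainders = sorted(
        range(len(proportions)), key=lambda i: (-(exact[i] - counts[i]), i)
    )
    for i in remainders[:leftover]:
        counts[i] += 1
    return counts


def _gene_symbols(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def group_boundaries(n_nodes: int, group_size: int) -> list[tuple[int, int]]:
    """Contiguous near-equal node-index ranges defining the topological groups."""
    n_groups = max(1, n_nodes // group_size)
    bounds = np.linspace(0, n_nodes, n_groups + 1).astype(int)
    return [(int(bounds[k]), int(bounds[k + 1])) for k in range(n_groups)]


def generate_network(cfg: SyntheticConfig) -> SignalingNetwork:
    """Connected typed network with hub-centered modular structure.

    Signaling modules mainly represent protein complexes, i.e. cohesive
    subgraphs, so the generator builds a modular topology: nodes are split
    into contiguous groups of about ``planted_module_size``; each group
    grows a preferential-attachment tree (new members attach with
    probability proportional to degree + 1, giving each group a hub) and is
    densified with extra within-group edges whose endpoints are again
    degree-biased; a fraction ``mixing`` of all edges runs between groups
    (a spanning chain that keeps the whole graph connected plus
    cross-group pairs with sqrt(degree)-biased endpoints, so hubs mediate
    inter-module traffic without two group hubs sitting adjacent).  Edge
    types are apportioned by largest
    remainder over ``type_proportions`` and shuffled across edges.  No
    self-loops or duplicate pairs.
    """
    rng = np.random.default_rng(cfg.seed)
    n, n_edges = cfg.n_nodes, cfg.n_edges
    max_pairs = n * (n - 1) // 2
    if n_edges > max_pairs:
        raise ValueError("n_edges exceeds the number of distinct pairs")
    symbols = _gene_symbols(n)
    groups = [list(range(a, b)) for a, b in group_boundaries(n, cfg.planted_module_size)]
    n_groups = len(groups)
    degree = np.zeros(n, dtype=float)
    pairs: list[tuple[int, int]] = []
    pair_set: set[tuple[int, int]] = set()

    def add_pair(a: int, b: int) -> bool:
        a, b = (a, b) if a < b else (b, a)
        if a == b or (a, b) in pair_set:
            return False
        pairs.append((a, b))
        pair_set.add((a, b))
        degree[a] += 1
        degree[b] += 1
        return True

    # preferential-attachment tree within each group
    for g in groups:
        for i, new in enumerate(g[1:], start=1):
            weights = degree[g[:i]] + 1.0
            target = g[int(rng.choice(i, p=weights / weights.sum()))]
            add_pair(new, target)
    # spanning chain across groups keeps the graph connected; each group's
    # hub attaches to a uniform member of the previous group so that two
    # group hubs rarely sit adjacent (adjacency would erase one group's
    # landscape maximum)
    for k in range(1, n_groups):
        hub = groups[k][int(np.argmax(degree[groups[k]]))]
        add_pair(hub, int(rng.choice(groups[k - 1])))

    n_between_target = max(int(cfg.mixing * n_edges), n_groups - 1)
    n_within_target = n_edges - n_between_target
    # degree-biased within-group densification
    per_group = max(0, (n_within_target - (n - n_groups)) // n_groups)
    for g in groups:
        added, tries = 0, 0
        budget = min(per_group, len(g) * (len(g) - 1) // 2 - (len(g) - 1))
        while added < budget and tries < 50 * per_group + 100:
            tries += 1
            weights = degree[g] + 1.0
            i, j = rng.choice(len(g), size=2, replace=False, p=weights / weights.sum())
            if add_pair(g[int(i)], g[int(j)]):
                added += 1
    # cross-group edges up to the full budget; endpoints are degree-biased
    # (inter-module links in signaling networks preferentially join hubs)
    while len(pairs) < n_edges:
        if n_groups > 1:
            k1, k2 = (int(k) for k in rng.choice(n_groups, size=2, replace=False))
            # soft degree bias: hubs mediate inter-module traffic without
            # two group hubs becoming directly adjacent too often (which
            # would erase one group's landscape maximum)
            w1 = np.sqrt(degree[groups[k1]] + 1.0)
            w2 = np.sqrt(degree[groups[k2]] + 1.0)
            a = groups[k1][int(rng.choice(len(groups[k1]), p=w1 / w1.sum()))]
            b = groups[k2][int(rng.choice(len(groups[k2]), p=w2 / w2.sum()))]
        else:
            a, b = (int(x) for x in rng.integers(0, n, size=2))
        add_pair(a, b)

    counts = largest_remainder(cfg.type_proportions, n_edges)
    types = np.repeat(np.arange(4), counts)
    rng.shuffle(types)
    edges = []
    for (a, b), k in zip(sorted(pairs), types):
        s, t = symbols[a], symbols[b]
        kind = INTERACTION_TYPES[k]
        if kind in ("activating", "inhibiting") and rng.integers(0, 2):
            s, t = t, s  # random orientation for directed links
        edges.append((s, t, kind))
    return SignalingNetwork.from_edges(edges, name=f"synthetic-{cfg.seed}")


def _pick_planted(net: SignalingNetwork, cfg: SyntheticConfig) -> list[str]:
    """Planted module: the topological group containing the top-degree hub.

    Groups are the contiguous symbol ranges the generator densified, so the
    planted set is a connected, cohesive subgraph anchored at the network's
    strongest hub (ties to the smallest symbol).  Deterministic given the
    network and configuration.
    """
    g = net.to_undirected_graph()
    symbols = _gene_symbols(cfg.n_nodes)
    hub = min(g.nodes, key=lambda n: (-g.degree(n), n))
    hub_idx = symbols.index(hub)
    for a, b in group_boundaries(cfg.n_nodes, cfg.planted_module_size):
        if a <= hub_idx < b:
            members = [symbols[i] for i in range(a, b)]
            return sorted(members)[: cfg.planted_module_size]
    raise RuntimeError("hub outside all groups")  # unreachable


def generate_expression(
    net: SignalingNetwork, cfg: SyntheticConfig
) -> tuple[dict[str, ExpressionMatrix], GroundTruth]:
    """Three per-state expression matrices sharing topology, plus ground truth.

    Gene baselines b_g ~ Normal(baseline_mean, baseline_sd) truncated above
    0.5.  State means: normal = b_g; adenoma = baseline_mean +
    kappa * (b_g - baseline_mean) (gene-level deviations inflated, floored
    at 0.5); carcinoma = b_g + delta for planted members plus
    gamma * max(0, baseline_mean - b_g) for every gene (weakly expressed
    genes pulled toward the mean, so the weakest links strengthen and the
    carcinoma network becomes more compact).  Samples add
    Normal(0, sample_noise_sd) noise, floored at 0.01 to keep intensities
    positive.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    genes = sorted(net.nodes)
    n = len(genes)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)
    for _ in range(100):
        bad = baseline <= 0.5
        if not bad.any():
            break
        baseline[bad] = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=bad.sum())
    baseline = np.maximum(baseline, 0.5 + 1e-6)

    planted = _pick_planted(net, cfg)
    planted_mask = np.isin(genes, planted)

    means = {
        "normal": baseline,
        "adenoma": np.maximum(
            cfg.baseline_mean + cfg.kappa * (baseline - cfg.baseline_mean), 0.5
        ),
        # carcinoma: planted module up-shifted; weakly expressed genes
        # compressed toward the mean (the weakest links strengthen, making
        # the carcinoma weight distribution more compact)
        "carcinoma": baseline
        + cfg.delta * planted_mask
        + cfg.gamma * np.maximum(cfg.baseline_mean - baseline, 0.0),
    }
    matrices: dict[str, ExpressionMatrix] = {}
    for state in STATES:
        noise = rng.normal(0.0, cfg.sample_noise_sd, size=(n, cfg.n_samples))
        values = np.maximum(means[state][:, None] + noise, 0.01)
        df = pd.DataFrame(
            values,
            index=genes,
            columns=[f"{state[:3]}_{j + 1:03d}" for j in range(cfg.n_samples)],
        )
        matrices[state] = ExpressionMatrix(
            data=df, state_label=state, series_id=f"SYN-{state}-{cfg.seed}"
        )
    truth = GroundTruth(
        planted_members=list(planted),
        true_means=pd.DataFrame(means, index=genes),
    )
    return matrices, truth


def generate_genesets(
    net: SignalingNetwork,
    truth: GroundTruth,
    cfg: SyntheticConfig,
    n_decoys: int = 3,
) -> GeneSetCollection:
    """The planted module as one gene set plus size-matched random decoys."""
    rng = np.random.default_rng(cfg.seed + 2)
    nodes = sorted(net.nodes)
    sets = {"PLANTED": list(truth.planted_members)}
    descriptions = {"PLANTED": "planted carcinoma-strengthened module"}
    size = len(truth.planted_members)
    for k in range(1, n_decoys + 1):
        members = sorted(rng.choice(nodes, size=size, replace=False).tolist())
        sets[f"DECOY_{k}"] = members
        descriptions[f"DECOY_{k}"] = "random size-matched decoy set"
    gsc = GeneSetCollection(sets=sets, descriptions=descriptions)
    truth.gene_sets = {k: list(v) for k, v in sets.items()}
    return gsc


def simulate(cfg: SyntheticConfig) -> tuple[
    SignalingNetwork, dict[str, ExpressionMatrix], GeneSetCollection, GroundTruth
]:
    """Generate network, three-state expression and gene sets in one call."""
    net = generate_network(cfg)
    matrices, truth = generate_expression(net, cfg)
    gsc = generate_genesets(net, truth, cfg)
    return net, matrices, gsc, truth
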