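"""Overlapping module detection via an influence-function community landscape.

Every node seeds an *influence zone*: a unit of influence placed on the
seed spreads synchronously along links, each step passing a fraction
``lam`` of the current increment to neighbors in proportion to the incident
link weights, until the total increment falls below ``eps``.  Summing all
zones gives a *community landscape* height per node; local maxima of the
height are module cores, and each node's assignment strength to a core is
proportional to that core's influence on it (rows normalized to 1).  Cores
whose assignment profiles overlap proportionally more than ``theta`` are
merged, yielding extensively overlapping modules.

*Community centrality* of a node is the total influence its own zone
exerts over the network; the node with the largest community centrality
among a module's discrete members names the module (it is the module's
main organizer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .weights import WeightedStateNetwork

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA = 0.5
DEFAULT_EPS = 1e-6
DEFAULT_THETA = 0.9
#: Relative height tolerance of the core (hill-top) detector: a node is a
#: core when its landscape height is within this fraction of every
#: neighbor's.  The tolerance makes hill detection robust to near-ties
#: (one marginally higher neighbor would otherwise erase a genuine hill,
#: as in the h-maxima transform of watershed segmentation); surplus cores
#: inside one hill are merged away by the overlap criterion.
DEFAULT_CORE_TOL = 0.05


@dataclass
class ModuleLandscape:
    """Node x module assignment strengths plus per-node community centrality.

    Module ids are the symbols of their core nodes.  Assignment rows sum
    to 1; every retained module has at least one discrete member.
    """

    nodes: list[str]
    module_cores: list[str]
    assignment: pd.DataFrame  # index: nodes, columns: module core ids
    centrality: pd.Series  # node -> community centrality
    height: pd.Series  # node -> landscape height
    params: dict = field(default_factory=dict)

    @property
    def n_modules(self) -> int:
        return len(self.module_cores)

    def discrete_members(self, module: str) -> set[str]:
        assign = discrete_assignment(self)
        return {n for n, m in assign.items() if m == module}


@dataclass
class ModuleMatch:
    """Cross-state module correspondence by discrete-member transfer."""

    pairs: list[dict]  # {"from": id, "to": id, "jaccard": float, "annotation": str}

    def mapping(self) -> dict[str, str]:
        return {p["from"]: p["to"] for p in self.pairs}


# ---------------------------------------------------------------------------
# influence spreading
# ---------------------------------------------------------------------------

def _adjacency(w: WeightedStateNetwork) -> tuple[list[str], np.ndarray]:
    """Sorted nodes and symmetric weight matrix over unique endpoint pairs.

    Non-positive link weights cannot carry spreading influence and are
    clamped to 0 (with a warning); this does not arise on the usual
    log2-intensity scale.
    """
    nodes = sorted(w.base.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    mat = np.zeros((len(nodes), len(nodes)))
    clamped = 0
    for (a, b), wt in w.pair_weights.items():
        if wt <= 0:
            clamped += 1
            wt = 0.0
        mat[idx[a], idx[b]] = wt
        mat[idx[b], idx[a]] = wt
    if clamped:
        logger.warning("%d non-positive link weights clamped to 0 for spreading", clamped)
    return nodes, mat


def _transition(mat: np.ndarray) -> np.ndarray:
    """Row-stochastic spreading operator; rows without outgoing weight stay 0."""
    row_sums = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(row_sums > 0, mat / np.where(row_sums > 0, row_sums, 1.0), 0.0)
    return p

def _spread(
    init: np.ndarray, p: np.ndarray, lam: float, eps: float
) -> np.ndarray:
    """Accumulate synchronous decaying spreading from per-row initial increments.

    Rows evolve independently (``inc <- lam * inc @ P``); a row stops
    accumulating once its own total increment drops below ``eps``.
    """
    influence = init.copy()
    inc = init.copy()
    active = np.ones(init.shape[0], dtype=bool)
    while active.any():
        inc = inc.copy()
        inc[active] = lam * inc[active] @ p
        done = inc[active].sum(axis=1) < eps
        influence[active] += np.where(done[:, None], 0.0, inc[active])
        idx = np.flatnonzero(active)
        active[idx[done]] = False
    return influence


def influence_zone(
    w: WeightedStateNetwork,
    seed_node: str,
    lam: float = DEFAULT_LAMBDA,
    eps: float = DEFAULT_EPS,
) -> pd.Series:
    """Influence of ``seed_node`` on every node of the network.

    The seed starts with influence 1; each step passes ``lam`` times the
    current increment to neighbors proportionally to incident link weights,
    stopping when the total new increment falls below ``eps``.  The seed's
    own influence is maximal; an isolated seed keeps all influence.
    """
    if not (0.0 < lam < 1.0):
        raise ValueError("lam must be in (0, 1)")
    if eps <= 0:
        raise ValueError("eps must be > 0")
    nodes, mat = _adjacency(w)
    if seed_node not in w.base.nodes:
        raise KeyError(f"seed node {seed_node!r} not in network")
    p = _transition(mat)
    init = np.zeros((1, len(nodes)))
    init[0, nodes.index(seed_node)] = 1.0
    vec = _spread(init, p, lam, eps)[0]
    return pd.Series(vec, index=nodes)


def _influence_matrix(
    w: WeightedStateNetwork, lam: float, eps: float
) -> tuple[list[str], np.ndarray]:
    """Stacked influence zones: row s = influence of node s on every node."""
    nodes, mat = _adjacency(w)
    p = _transition(mat)
    init = np.eye(len(nodes))
    return nodes, _spread(init, p, lam, eps)


# ---------------------------------------------------------------------------
# landscape construction
# ---------------------------------------------------------------------------

def detect_modules(
    w: WeightedStateNetwork,
    lam: float = DEFAULT_LAMBDA,
    eps: float = DEFAULT_EPS,
    theta: float = DEFAULT_THETA,
    core_tol: float = DEFAULT_CORE_TOL,
) -> ModuleLandscape:
    """Build the community landscape and its overlapping modules.

    Heights are the column sums of the all-seeds influence matrix; cores
    are nodes whose height reaches every neighbor's up to the relative
    tolerance ``core_tol`` (tolerant local maxima); assignment strength of
    node n to core c is proportional to c's influence on n.  Cores whose
    hills overlap proportionally more than ``theta`` are merged
    iteratively (the higher core absorbs the lower); modules that end up
    with no discrete member are absorbed likewise.
    """
    if not (0.0 < theta <= 1.0):
        raise ValueError("theta must be in (0, 1]")
    if not (0.0 <= core_tol < 1.0):
        raise ValueError("core_tol must be in [0, 1)")
    nodes, infl = _influence_matrix(w, lam, eps)
    n = len(nodes)
    idx = {nm: i for i, nm in enumerate(nodes)}
    height = infl.sum(axis=0)

    neighbors: dict[str, set[str]] = {nm: set() for nm in nodes}
    for a, b in w.base.node_pairs():
        neighbors[a].add(b)
        neighbors[b].add(a)
    # absolute floor keeps exact plateaus (symmetric graphs) joint maxima
    # even when core_tol is 0
    tol = 1e-9 * max(1.0, float(np.max(np.abs(height))))
    cores = [
        nm for nm in nodes
        if all(
            height[idx[nm]] >= (1.0 - core_tol) * height[idx[nb]] - tol
            for nb in neighbors[nm]
        )
    ]

    # a module is the summed influence zones of its absorbed cores; the
    # core set is tracked so overlap can ignore the cores' own self-peaks
    mod_vecs: dict[str, np.ndarray] = {c: infl[idx[c]].copy() for c in cores}
    mod_cores: dict[str, set[str]] = {c: {c} for c in cores}
    mod_height: dict[str, float] = {c: float(height[idx[c]]) for c in cores}

    def assignment_matrix(mods: dict[str, np.ndarray]) -> pd.DataFrame:
        cols = sorted(mods)
        a = np.stack([mods[c] for c in cols], axis=1)  # n x k
        row_sums = a.sum(axis=1, keepdims=True)
        flat = row_sums[:, 0] == 0
        if flat.any():
            # nodes unreached by any core zone: uniform membership
            a[flat] = 1.0 / len(cols)
            row_sums = a.sum(axis=1, keepdims=True)
        return pd.DataFrame(a / row_sums, index=nodes, columns=cols)

    def proportional_overlap(c1: str, c2: str) -> float:
        """Overlap of two modules' hills, self-peaks excluded.

        The zones of two cores inside one cohesive region are identical
        except at the cores themselves (a zone is always largest at its own
        seed), so the comparison masks both modules' core entries; the
        remainder is sum-of-minima over the smaller hill.  Two hills whose
        support is entirely their own cores count as fully overlapping.
        """
        mask = np.ones(n, dtype=bool)
        for c in mod_cores[c1] | mod_cores[c2]:
            mask[idx[c]] = False
        v1, v2 = mod_vecs[c1][mask], mod_vecs[c2][mask]
        denom = min(v1.sum(), v2.sum())
        if denom <= 0:
            return 1.0
        return float(np.minimum(v1, v2).sum() / denom)

    def absorb(loser: str, winner: str) -> None:
        mod_vecs[winner] = mod_vecs[winner] + mod_vecs[loser]
        mod_cores[winner] |= mod_cores[loser]
        del mod_vecs[loser], mod_cores[loser], mod_height[loser]

    while True:
        assign = assignment_matrix(mod_vecs)
        if len(mod_vecs) > 1:
            best_pair, best_ov = None, theta
            cols = sorted(mod_vecs)
            for i, c1 in enumerate(cols):
                for c2 in cols[i + 1:]:
                    ov = proportional_overlap(c1, c2)
                    if ov > best_ov:
                        best_pair, best_ov = (c1, c2), ov
            if best_pair is not None:
                c1, c2 = best_pair
                h1, h2 = mod_height[c1], mod_height[c2]
                if abs(h1 - h2) <= tol:
                    winner, loser = min(c1, c2), max(c1, c2)
                elif h1 > h2:
                    winner, loser = c1, c2
                else:
                    winner, loser = c2, c1
                absorb(loser, winner)
                continue
        # modules that end with no discrete member are absorbed into their
        # most-overlapping neighbor module
        discrete = assign.to_numpy().argmax(axis=1)
        cols = list(assign.columns)
        member_counts = {c: 0 for c in cols}
        for i in range(n):
            member_counts[cols[discrete[i]]] += 1
        empty = [c for c in cols if member_counts[c] == 0 and len(mod_vecs) > 1]
        if empty:
            loser = empty[0]
            others = [c for c in cols if c != loser]
            winner = max(others, key=lambda c: (proportional_overlap(loser, c), c))
            logger.warning("module %r has no discrete member; merged into %r", loser, winner)
            absorb(loser, winner)
            continue
        break

    # community centrality: the whole network's influence on each node,
    # i.e. the landscape height itself (incoming influence; the outgoing
    # zone total is the same 1/(1-lam) for every non-isolated node and
    # carries no information)
    centrality = pd.Series(height, index=nodes)
    return ModuleLandscape(
        nodes=nodes,
        module_cores=sorted(mod_vecs),
        assignment=assign,
        centrality=centrality,
        height=pd.Series(height, index=nodes),
        params={"lam": lam, "eps": eps, "theta": theta},
    )


def community_centrality(
    landscape: ModuleLandscape, w: WeightedStateNetwork | None = None
) -> pd.Series:
    """Node -> summed influence of every node's zone on it (landscape height).

    This is the whole network's influence on the node; it ranks each
    module's main organizers.  (The outgoing total of a node's own zone is
    1/(1-lam) for every non-isolated node and therefore uninformative.)
    """
    return landscape.centrality.copy()


def discrete_assignment(landscape: ModuleLandscape) -> dict[str, str]:
    """Assign each node to the module of its largest strength.

    Ties go to the lexicographically smallest module core id.
    """
    a = landscape.assignment
    out: dict[str, str] = {}
    cols = np.array(a.columns)
    values = a.to_numpy()
    for i, node in enumerate(a.index):
        row = values[i]
        best = row.max()
        winners = cols[np.isclose(row, best, rtol=0, atol=1e-12)]
        out[str(node)] = str(min(winners))
    return out


def name_modules(landscape: ModuleLandscape) -> dict[str, str]:
    """Name each module after its discrete member with maximal community centrality.

    Ties break to the lexicographically smallest symbol; a module without
    discrete members is dropped with a warning (does not arise for
    landscapes built by :func:`detect_modules`).
    """
    assign = discrete_assignment(landscape)
    names: dict[str, str] = {}
    for mod in landscape.module_cores:
        members = sorted(n for n, m in assign.items() if m == mod)
        if not members:
            logger.warning("module %r has no discrete member; dropped from naming", mod)
            continue
        cent = landscape.centrality.loc[members]
        best = cent.max()
        names[mod] = min(g for g in members if cent[g] >= best - 1e-12)
    return names


def overlap_metrics(
    landscape: ModuleLandscape, w: WeightedStateNetwork | None = None
) -> pd.DataFrame:
    """Per-node modular overlap and effective degree.

    ``modular_overlap`` is the effective number of modules a node belongs
    to: exp of the Shannon entropy of its assignment row (1 for a node
    fully inside one module).  ``effective_degree`` is the node's weighted
    degree (sum of incident link weights); it requires ``w`` and is NaN
    otherwise.
    """
    a = landscape.assignment.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(a > 0, np.log(a), 0.0)
    entropy = -(a * logs).sum(axis=1)
    overlap = np.exp(entropy)
    out = pd.DataFrame({"modular_overlap": overlap}, index=landscape.assignment.index)
    if w is not None:
        out["effective_degree"] = w.weighted_degree().reindex(out.index)
    else:
        out["effective_degree"] = np.nan
    return out


def match_modules(a: ModuleLandscape, b: ModuleLandscape) -> ModuleMatch:
    """Match each module of ``a`` to the module of ``b`` receiving most of its members.

    The transfer is by discrete members; Jaccard similarity of the discrete
    member sets is reported per pair.  When two or more modules of ``a``
    map to one module of ``b`` each pair is annotated ``"merge"``; when a
    module of ``b`` would map onto several of ``a`` the reverse direction
    marks ``"split"``.
    """
    if not set(a.nodes) & set(b.nodes):
        raise ValueError("landscapes share no nodes")
    assign_a = discrete_assignment(a)
    assign_b = discrete_assignment(b)
    members_a = {m: {n for n, mm in assign_a.items() if mm == m} for m in a.module_cores}
    members_b = {m: {n for n, mm in assign_b.items() if mm == m} for m in b.module_cores}

    def jaccard(s1: set[str], s2: set[str]) -> float:
        union = s1 | s2
        return len(s1 & s2) / len(union) if union else 0.0

    forward: dict[str, str] = {}
    for ma in sorted(members_a):
        transfers = {
            mb: len(members_a[ma] & members_b[mb]) for mb in sorted(members_b)
        }
        # plurality of transferred members; ties to larger Jaccard then id
        best = max(
            sorted(transfers),
            key=lambda mb: (transfers[mb], jaccard(members_a[ma], members_b[mb]), mb),
        )
        forward[ma] = best
    reverse_counts: dict[str, int] = {}
    for mb in forward.values():
        reverse_counts[mb] = reverse_counts.get(mb, 0) + 1

    backward: dict[str, str] = {}
    for mb in sorted(members_b):
        transfers = {ma: len(members_b[mb] & members_a[ma]) for ma in sorted(members_a)}
        backward[mb] = max(
            sorted(transfers),
            key=lambda ma: (transfers[ma], jaccard(members_b[mb], members_a[ma]), ma),
        )
    split_targets: dict[str, int] = {}
    for ma in backward.values():
        split_targets[ma] = split_targets.get(ma, 0) + 1

    pairs = []
    for ma in sorted(forward):
        mb = forward[ma]
        annotation = ""
        if reverse_counts[mb] >= 2:
            annotation = "merge"
        elif split_targets.get(ma, 0) >= 2:
            annotation = "split"
        pairs.append(
            {
                "from": ma,
                "to": mb,
                "jaccard": jaccard(members_a[ma], members_b[mb]),
                "annotation": annotation,
            }
        )
    return ModuleMatch(pairs=pairs)
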