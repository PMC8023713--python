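"""Link weights, their distribution statistics, paired tests and extreme strata.

A link weight is LW(i, j) = log(a_i * a_j): the logarithm (base 10 by
default) of the product of the two endpoint abundances.  It is symmetric in
the endpoints and acts as a proxy for the probability of the interaction.
Distribution summaries use the field's conventional strength bins (weak
< 2, medium 2..2.7, strong > 2.7 on the log10 scale); cross-state
comparisons use the paired Wilcoxon signed-rank test with the edge as the
pairing unit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Edge, SignalingNetwork

logger = logging.getLogger(__name__)


@dataclass
class WeightedStateNetwork:
    """A filtered signaling network with one link weight per edge for one state.

    ``log_base`` records the base of the logarithm applied to the raw
    abundance products, so downstream transforms (the diameter's
    negative-log distance mapping) can reconstruct the probability-like
    raw weight ``base ** LW``.
    """

    base: SignalingNetwork
    state: str
    pair_weights: dict[tuple[str, str], float]  # key: sorted endpoint pair
    log_base: float = 10.0

    def __post_init__(self) -> None:
        for s, t, _ in self.base.edges:
            key = _pair(s, t)
            if key not in self.pair_weights:
                raise ValueError(f"edge {s}-{t} has no weight")
            if not math.isfinite(self.pair_weights[key]):
                raise ValueError(f"edge {s}-{t} has non-finite weight")

    def edge_weight(self, s: str, t: str) -> float:
        return self.pair_weights[_pair(s, t)]

    def edge_weights(self) -> np.ndarray:
        """Weight per edge (parallel edges of different type each counted)."""
        return np.array([self.edge_weight(s, t) for s, t, _ in self.base.edges])

    def weighted_degree(self) -> pd.Series:
        """Node -> sum of incident link weights (over unique endpoint pairs)."""
        acc: dict[str, float] = {n: 0.0 for n in self.base.nodes}
        for a, b in self.base.node_pairs():
            w = self.pair_weights[(a, b)]
            acc[a] += w
            acc[b] += w
        return pd.Series(acc).sort_index()

    @property
    def w_max(self) -> float:
        return max(self.pair_weights[_pair(s, t)] for s, t, _ in self.base.edges)


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def compute_link_weights(
    net: SignalingNetwork,
    ab: Mapping[str, float] | pd.Series,
    state: str = "",
    log_base: float = 10.0,
) -> WeightedStateNetwork:
    """LW(i, j) = log_base(a_i * a_j) for every edge of a filtered network.

    Every endpoint must have a positive abundance; a missing gene raises a
    ``KeyError`` naming it.
    """
    if isinstance(ab, pd.Series):
        ab = ab.to_dict()
    log_b = math.log(log_base)
    weights: dict[tuple[str, str], float] = {}
    for s, t, _ in net.edges:
        for g in (s, t):
            if g not in ab:
                raise KeyError(f"no abundance for gene {g!r}")
        key = _pair(s, t)
        if key not in weights:
            weights[key] = math.log(ab[s] * ab[t]) / log_b
    return WeightedStateNetwork(
        base=net, state=state, pair_weights=weights, log_base=log_base
    )


# ---------------------------------------------------------------------------
# distribution summaries
# ---------------------------------------------------------------------------

@dataclass
class WeightSummary:
    """Descriptive statistics of one state's edge-weight multiset."""

    median: float
    mean: float
    sd: float
    q1: float
    q3: float
    iqr: float
    min: float
    max: float
    bin_fractions: tuple[float, float, float]  # weak, medium, strong
    cumulative: list[tuple[float, float]]  # sorted (weight, cumulative probability)
    n_edges: int

    def as_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in ("median", "mean", "sd", "q1", "q3", "iqr", "min", "max", "n_edges")
        }
        d["bin_fractions"] = list(self.bin_fractions)
        return d


def summarize_weights(
    w: WeightedStateNetwork | np.ndarray,
    weak_max: float = 2.0,
    strong_min: float = 2.7,
) -> WeightSummary:
    """Summarize the edge-weight multiset of one state.

    Quartiles use linear interpolation between order statistics; the three
    strength bins are weak ``< weak_max``, medium ``[weak_max, strong_min]``
    (closed on both ends) and strong ``> strong_min``.
    """
    values = w.edge_weights() if isinstance(w, WeightedStateNetwork) else np.asarray(w, float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 edge weights to summarize")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    weak = float(np.mean(values < weak_max))
    strong = float(np.mean(values > strong_min))
    medium = float(np.mean((values >= weak_max) & (values <= strong_min)))
    order = np.sort(values)
    cumulative = [(float(v), (i + 1) / n) for i, v in enumerate(order)]
    return WeightSummary(
        median=float(med),
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        q1=float(q1),
        q3=float(q3),
        iqr=float(q3 - q1),
        min=float(values.min()),
        max=float(values.max()),
        bin_fractions=(weak, medium, strong),
        cumulative=cumulative,
        n_edges=n,
    )


# ---------------------------------------------------------------------------
# paired Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def paired_wilcoxon(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Pairs with zero difference are removed first.  For n <= 25 remaining
    pairs the null distribution of the positive-rank sum W+ is computed
    exactly by convolution over the observed (midrank-resolved) ranks, so
    ties are handled exactly, conditional on the observed rank pattern.
    Above 25 the normal approximation with tie correction is used.

    Returns
    -------
    (W, p)
        ``W`` is the positive-rank sum W+; ``p`` the two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("degenerate pairing: all differences are zero")
    ranks = stats.rankdata(np.abs(d), method="average")
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        p = float(
            stats.wilcoxon(
                d, zero_method="wilcox", correction=False, method="approx"
            ).pvalue
        )
    return w_plus, p


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for W+ given the observed rank multiset.

    Each rank independently joins W+ with probability 1/2 under the null;
    the distribution is built by convolving the factors ``(1/2 + 1/2 x^r)``.
    Midranks are doubled so all exponents are integers.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    probs = np.zeros(total + 1)
    probs[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(probs)
        shifted[r:] = probs[: total + 1 - r]
        probs = 0.5 * (probs + shifted)
    w2 = int(round(2 * w_plus))
    p_le = probs[: w2 + 1].sum()
    p_ge = probs[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


# ---------------------------------------------------------------------------
# extreme-link strata
# ---------------------------------------------------------------------------

@dataclass
class ExtremeLinkReport:
    """Top/bottom weight strata of one state's edges.

    ``top_percentile`` is a subset of ``top_decile`` (and likewise at the
    bottom); the top and bottom strata are disjoint.
    """

    network: SignalingNetwork
    state: str
    top_decile: frozenset[Edge]
    top_percentile: frozenset[Edge]
    bottom_decile: frozenset[Edge]
    bottom_percentile: frozenset[Edge]

    STRATA = ("top_decile", "top_percentile", "bottom_decile", "bottom_percentile")

    def stratum(self, name: str) -> frozenset[Edge]:
        if name not in self.STRATA:
            raise KeyError(name)
        return getattr(self, name)


def extreme_links(
    w: WeightedStateNetwork, decile: float = 0.10, percentile: float = 0.01
) -> ExtremeLinkReport:
    """Pick the highest/lowest ``decile`` of edges by weight, plus the
    ``percentile`` subcategory.

    Stratum sizes are ``floor(fraction * E)``.  Ties at stratum boundaries
    are broken deterministically by (weight, source, target, type)
    lexicographic order.
    """
    for f in (decile, percentile):
        if not (0.0 < f < 0.5):
            raise ValueError(f"stratum fraction must be in (0, 0.5), got {f}")
    if percentile > decile:
        raise ValueError("percentile stratum cannot exceed the decile stratum")
    edges = list(w.base.edges)
    n = len(edges)
    ascending = sorted(edges, key=lambda e: (w.edge_weight(e[0], e[1]), e))
    descending = sorted(edges, key=lambda e: (-w.edge_weight(e[0], e[1]), e))
    k_dec, k_pct = int(decile * n), int(percentile * n)
    return ExtremeLinkReport(
        network=w.base,
        state=w.state,
        top_decile=frozenset(descending[:k_dec]),
        top_percentile=frozenset(descending[:k_pct]),
        bottom_decile=frozenset(ascending[:k_dec]),
        bottom_percentile=frozenset(ascending[:k_pct]),
    )


def module_representation(
    report: ExtremeLinkReport, assignment: Mapping[str, str]
) -> dict[str, dict[str, float]]:
    """Fraction of each module's internal edges falling in each stratum.

    An edge belongs to a module only when *both* endpoints are discretely
    assigned to it; edges spanning two modules count for neither.  A module
    with no internal edge reports ratio 0 for every stratum (with a warning).
    """
    missing = report.network.nodes - set(assignment)
    if missing:
        raise ValueError(f"assignment does not cover nodes: {sorted(missing)[:5]}")
    modules = sorted(set(assignment.values()))
    internal: dict[str, list[Edge]] = {m: [] for m in modules}
    for e in report.network.edges:
        s, t, _ = e
        if assignment[s] == assignment[t]:
            internal[assignment[s]].append(e)
    out: dict[str, dict[str, float]] = {}
    for m in modules:
        edges = internal[m]
        if not edges:
            logger.warning("module %r has no internal edge; ratios set to 0", m)
            out[m] = {s: 0.0 for s in ExtremeLinkReport.STRATA}
            continue
        out[m] = {
            s: sum(1 for e in edges if e in report.stratum(s)) / len(edges)
            for s in ExtremeLinkReport.STRATA
        }
    return out
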