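"""Gene-set (pathway) level statistics across biological states.

For each gene set the members are first restricted to the network's nodes;
statistics are then per-state median abundances, pairwise paired Wilcoxon
tests between states (with a Shapiro-Wilk normality screen reported for
transparency), weighted-degree medians relative to the whole network, and
counts of member-incident links among the extreme strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import AbundanceTable
from .io_formats import GeneSetCollection, SignalingNetwork
from .weights import ExtremeLinkReport, WeightedStateNetwork, paired_wilcoxon

logger = logging.getLogger(__name__)

MIN_MEMBERS_FOR_TEST = 5


def pathway_medians(
    gene_set: Sequence[str], ab: AbundanceTable, net: SignalingNetwork
) -> dict:
    """Per-state median abundance over the gene set's in-network members."""
    members = [g for g in dict.fromkeys(gene_set)]
    in_network = sorted(set(members) & net.nodes & set(ab.genes))
    out: dict = {
        "n_in_geneset": len(members),
        "n_in_network": len(in_network),
        "medians": {},
    }
    if not in_network:
        return out
    for state in ab.states:
        out["medians"][state] = float(ab.data.loc[in_network, state].median())
    return out


def pathway_tests(
    gene_set: Sequence[str], ab: AbundanceTable, net: SignalingNetwork | None = None
) -> dict:
    """Pairwise paired Wilcoxon p-values between states over member genes.

    Pairing is per gene (the same gene's abundance in the two states).
    Requires at least 5 members with abundances (restricted to the network
    when one is given); otherwise, and when all paired differences are
    zero, the p-value is reported as None with a reason.  Shapiro-Wilk
    p-values per state are included as the normality screen motivating the
    nonparametric test.
    """
    members = set(gene_set) & set(ab.genes)
    if net is not None:
        members &= net.nodes
    members = sorted(members)
    out: dict = {"n_members_tested": len(members), "shapiro": {}, "wilcoxon": {}}
    if len(members) >= 3:
        for state in ab.states:
            vals = ab.data.loc[members, state].to_numpy()
            if np.ptp(vals) == 0:
                out["shapiro"][state] = None
            else:
                out["shapiro"][state] = float(stats.shapiro(vals).pvalue)
    states = ab.states
    for i, s1 in enumerate(states):
        for s2 in states[i + 1:]:
            key = f"{s1}-{s2}"
            if len(members) < MIN_MEMBERS_FOR_TEST:
                out["wilcoxon"][key] = {"p": None, "reason": "fewer than 5 members"}
                continue
            x = ab.data.loc[members, s1].to_numpy()
            y = ab.data.loc[members, s2].to_numpy()
            if np.all(x == y):
                out["wilcoxon"][key] = {"p": None, "reason": "all differences zero"}
                continue
            w, p = paired_wilcoxon(x, y)
            out["wilcoxon"][key] = {"W": w, "p": p}
    return out


def pathway_weighted_degree(
    gene_set: Sequence[str], w: WeightedStateNetwork
) -> dict:
    """Median weighted degree of in-network members vs the whole network.

    The ratio > 2 signals a pathway whose nodes carry far more link weight
    than typical nodes.
    """
    degrees = w.weighted_degree()
    members = sorted(set(gene_set) & set(degrees.index))
    if not members:
        raise ValueError("gene set has no member in the network")
    member_median = float(degrees.loc[members].median())
    network_median = float(degrees.median())
    return {
        "member_median": member_median,
        "network_median": network_median,
        "ratio": member_median / network_median if network_median else float("nan"),
        "n_members": len(members),
    }


def pathway_extreme_counts(
    gene_set: Sequence[str],
    report: ExtremeLinkReport,
    mode: str = "any-endpoint",
) -> tuple[int, int]:
    """Counts of pathway-associated links among the top and bottom deciles.

    A link is pathway-associated when at least one endpoint is a member
    (``mode="any-endpoint"``, default) or when both are
    (``mode="both-endpoints"``).
    """
    if mode not in ("any-endpoint", "both-endpoints"):
        raise ValueError(f"unknown mode {mode!r}")
    members = set(gene_set)

    def hit(edge) -> bool:
        s, t, _ = edge
        if mode == "any-endpoint":
            return s in members or t in members
        return s in members and t in members

    top = sum(1 for e in report.top_decile if hit(e))
    bottom = sum(1 for e in report.bottom_decile if hit(e))
    return top, bottom


def pathway_table(
    gsc: GeneSetCollection,
    ab: AbundanceTable,
    net: SignalingNetwork,
    weighted: Mapping[str, WeightedStateNetwork] | None = None,
    extremes: Mapping[str, ExtremeLinkReport] | None = None,
) -> pd.DataFrame:
    """One row per gene set: the consolidated pathway analysis table.

    Columns cover membership counts, per-state medians, pairwise Wilcoxon
    p-values and (when weighted networks / extreme reports are supplied)
    weighted-degree ratios and extreme-link counts per state.
    """
    rows = []
    for name in gsc:
        gs = gsc[name]
        med = pathway_medians(gs, ab, net)
        row: dict = {
            "pathway": name,
            "n_in_geneset": med["n_in_geneset"],
            "n_in_network": med["n_in_network"],
        }
        for state in ab.states:
            row[f"median_{state}"] = med["medians"].get(state, np.nan)
        if med["n_in_network"] > 0:
            tests = pathway_tests(gs, ab, net)
            for key, res in tests["wilcoxon"].items():
                row[f"p_{key}"] = res["p"] if res["p"] is not None else np.nan
        if weighted is not None and med["n_in_network"] > 0:
            for state, wsn in weighted.items():
                row[f"degree_ratio_{state}"] = pathway_weighted_degree(gs, wsn)["ratio"]
        if extremes is not None:
            for state, rep in extremes.items():
                top, bottom = pathway_extreme_counts(gs, rep)
                row[f"top10_{state}"] = top
                row[f"bottom10_{state}"] = bottom
        rows.append(row)
    return pd.DataFrame(rows).set_index("pathway")
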