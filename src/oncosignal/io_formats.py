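"""Readers, writers and filtering for the formats the pipeline touches.

The central object is a :class:`SignalingNetwork`: a typed, optionally
directed graph of gene-symbol nodes whose topology is shared by every
biological state.  Interaction types follow the vocabulary of curated
signaling resources: ``activating`` and ``inhibiting`` links are directed,
``undirected`` links are association- or interaction-based, and ``unknown``
links carry no usable type and are removed before analysis.

Expression matrices are plain TSV (genes in rows, samples in columns,
log2-scale intensities); gene sets use the standard GMT format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

ACTIVATING = "activating"
INHIBITING = "inhibiting"
UNDIRECTED = "undirected"
UNKNOWN = "unknown"

#: The four admissible interaction types, in canonical order.
INTERACTION_TYPES: tuple[str, ...] = (ACTIVATING, INHIBITING, UNDIRECTED, UNKNOWN)

#: Directed interaction types (the arc points source -> target).
DIRECTED_TYPES: frozenset[str] = frozenset({ACTIVATING, INHIBITING})

_INTERACTION_ALIASES: dict[str, str] = {
    "activating": ACTIVATING,
    "activate": ACTIVATING,
    "activates": ACTIVATING,
    "activation": ACTIVATING,
    "1": ACTIVATING,
    "inhibiting": INHIBITING,
    "inhibit": INHIBITING,
    "inhibits": INHIBITING,
    "inhibition": INHIBITING,
    "-1": INHIBITING,
    "undirected": UNDIRECTED,
    "pp": UNDIRECTED,
    "association": UNDIRECTED,
    "interaction": UNDIRECTED,
    "unknown": UNKNOWN,
}

#: An edge is a (source, target, interaction_type) triple of strings.
Edge = tuple[str, str, str]


class NetworkParseError(ValueError):
    """Raised when an edge-list file cannot be parsed."""


@dataclass
class SignalingNetwork:
    """Typed signaling network with a fixed topology.

    Parameters
    ----------
    nodes
        Gene symbols.  Every edge endpoint must be present.
    edges
        ``(source, target, interaction_type)`` triples.  Duplicate triples
        are not allowed; parallel edges of *different* types between the
        same pair are legitimate and retained.
    name
        Free-text label.
    """

    nodes: set[str]
    edges: list[Edge]
    name: str = ""

    def __post_init__(self) -> None:
        self.nodes = set(self.nodes)
        seen: set[Edge] = set()
        for e in self.edges:
            if len(e) != 3:
                raise ValueError(f"edge {e!r} is not a (source, target, type) triple")
            s, t, kind = e
            if kind not in INTERACTION_TYPES:
                raise ValueError(f"edge {e!r} has unknown interaction type {kind!r}")
            if s not in self.nodes or t not in self.nodes:
                raise ValueError(f"edge {e!r} has an endpoint outside the node set")
            if e in seen:
                raise ValueError(f"duplicate edge {e!r}")
            seen.add(e)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_edges(cls, edges: Iterable[Edge], name: str = "") -> "SignalingNetwork":
        """Build a network whose node set is exactly the edge endpoints."""
        edges = list(edges)
        nodes = {s for s, _, _ in edges} | {t for _, t, _ in edges}
        return cls(nodes=nodes, edges=edges, name=name)

    # -- views -------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_pairs(self) -> list[tuple[str, str]]:
        """Sorted unique unordered endpoint pairs (parallel edges collapsed)."""
        return sorted({_pair(s, t) for s, t, _ in self.edges})

    def type_counts(self) -> dict[str, int]:
        counts = {k: 0 for k in INTERACTION_TYPES}
        for _, _, kind in self.edges:
            counts[kind] += 1
        return counts

    def to_undirected_graph(self) -> nx.Graph:
        """Undirected skeleton; parallel edges collapse to a single edge."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((s, t) for s, t, _ in self.edges)
        return g


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# network I/O
# ---------------------------------------------------------------------------

def read_network(path: str | Path, name: str | None = None) -> SignalingNetwork:
    """Read a typed edge list in SIF or 3-column TSV dialect.

    The dialect is auto-detected: a header line containing both ``source``
    and ``target`` switches to the TSV dialect (columns source, target,
    interaction); otherwise rows are SIF (source, interaction, target, with
    additional columns read as extra targets).  Unknown interaction strings
    map to ``"unknown"`` with a logged warning; identical (source, target,
    type) triples are de-duplicated.
    """
    path = Path(path)
    raw = path.read_text().splitlines()
    lines = [(i + 1, ln) for i, ln in enumerate(raw) if ln.strip()]
    if not lines:
        raise NetworkParseError(f"{path}: empty network file")

    header_fields = [f.strip().lower() for f in lines[0][1].split("\t")]
    tsv_dialect = "source" in header_fields and "target" in header_fields
    if tsv_dialect:
        lines = lines[1:]
        if not lines:
            raise NetworkParseError(f"{path}: header but no edges")

    edges: list[Edge] = []
    seen: set[Edge] = set()
    for lineno, ln in lines:
        fields = ln.split("\t") if "\t" in ln else ln.split()
        fields = [f.strip() for f in fields if f.strip()]
        if len(fields) < 3:
            raise NetworkParseError(
                f"{path}:{lineno}: expected at least 3 columns, got {len(fields)}"
            )
        if tsv_dialect:
            rows = [(fields[0], fields[1], fields[2])]
        else:
            src, interaction = fields[0], fields[1]
            rows = [(src, tgt, interaction) for tgt in fields[2:]]
        for src, tgt, interaction in rows:
            kind = _INTERACTION_ALIASES.get(interaction.lower())
            if kind is None:
                logger.warning(
                    "%s:%d: unrecognized interaction %r mapped to 'unknown'",
                    path, lineno, interaction,
                )
                kind = UNKNOWN
            edge = (src, tgt, kind)
            if edge not in seen:
                seen.add(edge)
                edges.append(edge)
    return SignalingNetwork.from_edges(edges, name=name or path.stem)


def write_network(net: SignalingNetwork, path: str | Path, dialect: str = "sif") -> None:
    """Write a network as SIF (``source TAB interaction TAB target``) or TSV."""
    path = Path(path)
    lines = []
    if dialect == "sif":
        lines = [f"{s}\t{k}\t{t}" for s, t, k in net.edges]
    elif dialect == "tsv":
        lines = ["source\ttarget\tinteraction"]
        lines += [f"{s}\t{t}\t{k}" for s, t, k in net.edges]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n")


def filter_network(net: SignalingNetwork, measured_genes: Iterable[str]) -> SignalingNetwork:
    """Restrict a network to measured genes, known link types and the giant component.

    Keeps only edges whose endpoints were both measured and whose type is not
    ``unknown``, then restricts to the largest connected component of the
    undirected skeleton.  The operation is idempotent.
    """
    measured = set(measured_genes)
    if not measured:
        raise ValueError("measured_genes is empty")
    kept = [
        (s, t, k)
        for s, t, k in net.edges
        if k != UNKNOWN and s in measured and t in measured
    ]
    if not kept:
        raise ValueError("no edge survives filtering")
    skeleton = nx.Graph()
    skeleton.add_edges_from((s, t) for s, t, _ in kept)
    # among equally large components take the one containing the
    # lexicographically smallest node, for determinism
    giant = max(nx.connected_components(skeleton), key=lambda c: (len(c), min(c)))
    sizes = [len(c) for c in nx.connected_components(skeleton)]
    if sizes.count(max(sizes)) > 1:
        tied = [c for c in nx.connected_components(skeleton) if len(c) == max(sizes)]
        giant = min(tied, key=min)
    final = [(s, t, k) for s, t, k in kept if s in giant and t in giant]
    if not final:
        raise ValueError("no edge survives filtering")
    return SignalingNetwork.from_edges(final, name=net.name)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of positive log2-scale intensities for one state."""

    data: pd.DataFrame  # index: gene symbols, columns: sample ids
    state_label: str
    series_id: str = ""

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene symbols (collapse probes first)")
        values = self.data.to_numpy(dtype=float)
        import numpy as np

        if not np.isfinite(values).all():
            raise ValueError("non-finite expression values")
        if (values <= 0).any():
            raise ValueError("expression values must be > 0")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def read_expression(path: str | Path, state_label: str, series_id: str = "") -> ExpressionMatrix:
    """Read a genes-in-rows TSV; duplicate gene rows collapse by element-wise median."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.isna().any() or (df.index.astype(str).str.strip() == "").any():
        raise ValueError(f"{path}: empty gene symbol in first column")
    df.index = df.index.astype(str)
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            gene = df.index[converted.isna().to_numpy().argmax()]
            raise ValueError(f"{path}: non-numeric value at gene {gene!r}, sample {col!r}")
        numeric[col] = converted
    if (numeric.to_numpy() <= 0).any():
        bad = numeric[(numeric <= 0).any(axis=1)].index[0]
        raise ValueError(f"{path}: non-positive value at gene {bad!r}")
    if numeric.index.has_duplicates:
        numeric = numeric.groupby(level=0, sort=False).median()
    return ExpressionMatrix(
        data=numeric, state_label=state_label, series_id=series_id or path.stem
    )


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with one-line descriptions (GMT semantics)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for nm, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {nm!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB member...`` per line.

    Duplicate members within a line are dropped, first occurrence wins;
    duplicate set names are an error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, desc, raw_members = fields[0], fields[1], fields[2:]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
        members: list[str] = []
        seen: set[str] = set()
        for g in raw_members:
            g = g.strip()
            if g and g not in seen:
                seen.add(g)
                members.append(g)
        if not members:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
        sets[name] = members
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, gsc.descriptions.get(name, "")] + gsc.sets[name])
        for name in gsc.sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")
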