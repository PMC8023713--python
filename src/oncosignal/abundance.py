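"""Per-state gene abundances: normalization, median aggregation, noise.

An *abundance* is the per-gene median of normalized log2-scale expression
over all samples of one biological state; it is used downstream as a proxy
for protein abundance.  Robustness checks perturb every abundance
multiplicatively up or down by a fixed fraction (default 5%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class AbundanceTable:
    """Genes x states table of positive abundances (log2-intensity medians)."""

    data: pd.DataFrame  # index: genes, columns: state labels

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("abundance values must be finite")
        if (values <= 0).any():
            raise ValueError("abundance values must be > 0")

    @property
    def states(self) -> list[str]:
        return list(self.data.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    def state(self, label: str) -> pd.Series:
        """Gene -> abundance for one state."""
        return self.data[label]

    @classmethod
    def from_state_series(cls, per_state: Mapping[str, pd.Series]) -> "AbundanceTable":
        """Assemble from per-state gene->abundance maps, intersecting genes.

        Genes missing in any state are dropped from all states so that the
        gene universe is shared.
        """
        common: set[str] | None = None
        for s in per_state.values():
            common = set(s.index) if common is None else common & set(s.index)
        if not common:
            raise ValueError("empty gene intersection across states")
        genes = sorted(common)
        df = pd.DataFrame(
            {label: series.loc[genes].astype(float) for label, series in per_state.items()},
            index=genes,
        )
        return cls(data=df)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize a matrix so every sample shares one value distribution.

    Each column is replaced by the vector of row-rank means: the value at
    rank ``r`` becomes the mean over columns of each column's ``r``-th
    smallest value.  Tied values receive the mean of the normalized values
    at their tied ranks, so within-column rank order is preserved.

    A single-sample matrix is returned unchanged with a warning (there is
    nothing to normalize against).
    """
    values = m.data.to_numpy(dtype=float)
    n_genes, n_samples = values.shape
    if n_samples < 2:
        logger.warning(
            "quantile_normalize: matrix %s has a single sample; returned unchanged",
            m.series_id,
        )
        return ExpressionMatrix(data=m.data.copy(), state_label=m.state_label,
                                series_id=m.series_id)
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(1, n_genes + 1, dtype=float)
    for j in range(n_samples):
        ranks = rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, mean_sorted)
    df = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(data=df, state_label=m.state_label, series_id=m.series_id)


def median_aggregate(matrices: Sequence[ExpressionMatrix]) -> pd.Series:
    """Pool all samples of one state and take the per-gene median.

    Genes absent from any matrix are dropped (intersection); samples from
    every matrix of the state are pooled before the median, so the result
    is invariant to how samples are split across series.
    """
    if not matrices:
        raise ValueError("no matrices to aggregate")
    labels = {m.state_label for m in matrices}
    if len(labels) > 1:
        raise ValueError(f"matrices span multiple states: {sorted(labels)}")
    common: set[str] | None = None
    for m in matrices:
        common = set(m.genes) if common is None else common & set(m.genes)
    if not common:
        raise ValueError("empty gene intersection across matrices")
    genes = sorted(common)
    pooled = pd.concat([m.data.loc[genes] for m in matrices], axis=1)
    return pooled.median(axis=1)


def perturb_noise(t: AbundanceTable, fraction: float = 0.05, seed: int = 0) -> AbundanceTable:
    """Multiply every (gene, state) abundance by ``1 +/- fraction``, coin-flip each.

    The perturbation is multiplicative and exactly symmetric: each value is
    independently scaled by ``1 + fraction`` or ``1 - fraction`` with
    probability 1/2, driven by ``seed`` (equal seeds give identical output).
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"noise fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    # sorted gene x state grid so the draw order is well-defined
    df = t.data.sort_index(axis=0).sort_index(axis=1)
    signs = rng.integers(0, 2, size=df.shape) * 2 - 1
    factors = 1.0 + fraction * signs
    out = df * factors
    return AbundanceTable(data=out.loc[t.data.index, t.data.columns])
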