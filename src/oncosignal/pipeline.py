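"""End-to-end orchestration: data -> abundances -> weights -> diameters ->
modules -> extreme links -> pathways -> noise robustness.

``run_all`` executes every stage on either simulated or loaded data and
returns one consolidated report (a plain dict, JSON-serializable except
for the embedded DataFrames, which are written as TSV when an output
directory is given).  ``noise_robustness`` re-runs the weight-dependent
stages under repeated +/-5% abundance perturbations and reports how stable
the qualitative findings are.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import abundance as ab_mod
from . import diameter as diam_mod
from . import io_formats as io_mod
from . import modularization as mod_mod
from . import pathways as path_mod
from . import synthetic_data as syn_mod
from . import weights as w_mod

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31 - 1


def derive_seed(seed: int, offset: int) -> int:
    """Stage-specific sub-seed: deterministic, independent-looking, < 2^31."""
    return (seed * 1000003 + 7919 * offset + 17) % _SEED_MOD


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    In ``simulate`` mode the synthetic generator provides network,
    expression and gene sets; in ``load`` mode paths must point to a SIF/TSV
    network, per-state expression TSVs and (optionally) a GMT file.
    """

    mode: str = "simulate"  # "simulate" | "load"
    synthetic: syn_mod.SyntheticConfig = field(default_factory=syn_mod.SyntheticConfig)
    network_path: str | None = None
    expression_paths: dict[str, list[str]] = field(default_factory=dict)
    gmt_path: str | None = None
    log_base: float = 10.0
    distance_map: str = "neglog-maxnorm"
    lam: float = mod_mod.DEFAULT_LAMBDA
    eps: float = mod_mod.DEFAULT_EPS
    theta: float = mod_mod.DEFAULT_THETA
    decile: float = 0.10
    percentile: float = 0.01
    noise_fraction: float = 0.05
    noise_replicates: int = 0
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "load":
            if not self.network_path or not self.expression_paths:
                raise ValueError("load mode requires network_path and expression_paths")
            for p in [self.network_path, *(q for ps in self.expression_paths.values() for q in ps)]:
                if not Path(p).exists():
                    raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn:
            cfg.synthetic = syn_mod.SyntheticConfig(**syn)
        return cfg


def _load_inputs(cfg: RunConfig):
    if cfg.mode == "simulate":
        syn_cfg = dataclasses.replace(cfg.synthetic, seed=derive_seed(cfg.seed, 1))
        net, matrices_by_state, gsc, truth = syn_mod.simulate(syn_cfg)
        matrices = {s: [m] for s, m in matrices_by_state.items()}
        return net, matrices, gsc, truth
    net = io_mod.read_network(cfg.network_path)
    matrices = {
        state: [io_mod.read_expression(p, state_label=state) for p in paths]
        for state, paths in cfg.expression_paths.items()
    }
    gsc = io_mod.read_gmt(cfg.gmt_path) if cfg.gmt_path else None
    return net, matrices, gsc, None


def build_abundances(
    matrices: Mapping[str, list[io_mod.ExpressionMatrix]]
) -> ab_mod.AbundanceTable:
    """Quantile-normalize each series, pool per state, median-aggregate."""
    per_state = {}
    for state, mats in matrices.items():
        normalized = [ab_mod.quantile_normalize(m) for m in mats]
        per_state[state] = ab_mod.median_aggregate(normalized)
    return ab_mod.AbundanceTable.from_state_series(per_state)


def _weights_per_state(
    net: io_mod.SignalingNetwork, table: ab_mod.AbundanceTable, log_base: float
) -> dict[str, w_mod.WeightedStateNetwork]:
    return {
        state: w_mod.compute_link_weights(net, table.state(state), state=state, log_base=log_base)
        for state in table.states
    }


def _aligned_weight_vectors(
    weighted: Mapping[str, w_mod.WeightedStateNetwork]
) -> dict[str, np.ndarray]:
    states = list(weighted)
    edges = weighted[states[0]].base.edges
    return {
        s: np.array([weighted[s].edge_weight(e[0], e[1]) for e in edges])
        for s in states
    }


def _diameter_ordering(grid) -> dict[str, list[str]]:
    """Per convention: states sorted by increasing diameter."""
    out = {}
    states = list(grid)
    for conv in diam_mod.CONVENTIONS:
        out[conv] = sorted(states, key=lambda s: grid[s][conv].diameter)
    return out


def run_all(cfg: RunConfig) -> dict:
    """Run every analysis stage and return the consolidated report."""
    logger.info("stage: inputs (%s mode)", cfg.mode)
    net_raw, matrices, gsc, truth = _load_inputs(cfg)

    logger.info("stage: abundances")
    table = build_abundances(matrices)

    logger.info("stage: network filtering")
    net = io_mod.filter_network(net_raw, set(table.genes))
    table = ab_mod.AbundanceTable(data=table.data.loc[sorted(net.nodes)])

    logger.info("stage: link weights")
    weighted = _weights_per_state(net, table, cfg.log_base)
    summaries = {s: w_mod.summarize_weights(w) for s, w in weighted.items()}

    vectors = _aligned_weight_vectors(weighted)
    states = list(weighted)
    wilcoxon = {}
    for i, s1 in enumerate(states):
        for s2 in states[i + 1:]:
            W, p = w_mod.paired_wilcoxon(vectors[s1], vectors[s2])
            wilcoxon[f"{s1}-{s2}"] = {"W": W, "p": p}

    logger.info("stage: diameters")
    grid = diam_mod.diameter_grid(weighted, distance_map=cfg.distance_map)

    logger.info("stage: modules")
    landscapes = {
        s: mod_mod.detect_modules(w, lam=cfg.lam, eps=cfg.eps, theta=cfg.theta)
        for s, w in weighted.items()
    }
    module_tables = {}
    assignments = {}
    for s, ls in landscapes.items():
        names = mod_mod.name_modules(ls)
        assign = mod_mod.discrete_assignment(ls)
        assignments[s] = assign
        sizes = {m: sum(1 for v in assign.values() if v == m) for m in ls.module_cores}
        module_tables[s] = {
            "n_modules": ls.n_modules,
            "cores": list(ls.module_cores),
            "names": names,
            "sizes": sizes,
        }
    matches = {}
    for s1, s2 in zip(states, states[1:]):
        matches[f"{s1}->{s2}"] = mod_mod.match_modules(landscapes[s1], landscapes[s2]).pairs

    logger.info("stage: extreme links")
    extremes = {
        s: w_mod.extreme_links(w, decile=cfg.decile, percentile=cfg.percentile)
        for s, w in weighted.items()
    }
    extreme_report = {
        s: {
            "sizes": {name: len(rep.stratum(name)) for name in rep.STRATA},
            "module_representation": w_mod.module_representation(rep, assignments[s]),
        }
        for s, rep in extremes.items()
    }

    pathway_df = None
    if gsc is not None:
        logger.info("stage: pathways")
        pathway_df = path_mod.pathway_table(gsc, table, net, weighted, extremes)

    report: dict = {
        "params": {
            "mode": cfg.mode,
            "seed": cfg.seed,
            "log_base": cfg.log_base,
            "distance_map": cfg.distance_map,
            "module_params": {"lam": cfg.lam, "eps": cfg.eps, "theta": cfg.theta},
            "strata": {"decile": cfg.decile, "percentile": cfg.percentile},
            "n_nodes": net.n_nodes,
            "n_edges": net.n_edges,
        },
        "weights": {s: summaries[s].as_dict() for s in states},
        "wilcoxon": wilcoxon,
        "diameter": {
            s: {
                conv: {
                    "diameter": rep.diameter,
                    "average_path_length": rep.average_path_length,
                    "n_reachable_pairs": rep.n_reachable_pairs,
                    "n_nodes": rep.n_nodes,
                }
                for conv, rep in grid[s].items()
            }
            for s in states
        },
        "diameter_ordering": _diameter_ordering(grid),
        "modules": module_tables,
        "module_matches": matches,
        "extremes": extreme_report,
    }
    if truth is not None:
        recovery = {}
        planted = set(truth.planted_members)
        for s, ls in landscapes.items():
            best = 0.0
            best_mod = None
            for m in ls.module_cores:
                members = {n for n, mm in assignments[s].items() if mm == m}
                j = len(planted & members) / len(planted | members)
                if j > best:
                    best, best_mod = j, m
            recovery[s] = {"best_jaccard": best, "module": best_mod}
        report["ground_truth_recovery"] = recovery

    if cfg.noise_replicates >= 1:
        logger.info("stage: noise robustness (%d replicates)", cfg.noise_replicates)
        report["noise"] = noise_robustness(
            cfg, cfg.noise_replicates,
            _context=(net, table, grid, matches),
        )

    if cfg.outdir:
        _write_outputs(cfg, report, weighted, landscapes, pathway_df)
    if pathway_df is not None:
        report["pathways"] = pathway_df.to_dict(orient="index")
    return report


def noise_robustness(cfg: RunConfig, n_replicates: int, _context=None) -> dict:
    """Stability of the headline findings under repeated abundance noise.

    Each replicate multiplies every abundance by 1 +/- ``noise_fraction``
    (fair coin per value), recomputes weights, paired Wilcoxon p-values,
    the diameter grid and the cross-state module matches, and checks
    whether (i) the per-convention diameter ordering of states and
    (ii) each module-match target set are preserved relative to the
    unperturbed baseline.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if _context is None:
        base_cfg = dataclasses.replace(cfg, noise_replicates=0, outdir=None)
        net_raw, matrices, _, _ = _load_inputs(base_cfg)
        table = build_abundances(matrices)
        net = io_mod.filter_network(net_raw, set(table.genes))
        table = ab_mod.AbundanceTable(data=table.data.loc[sorted(net.nodes)])
        weighted = _weights_per_state(net, table, cfg.log_base)
        grid = diam_mod.diameter_grid(weighted, distance_map=cfg.distance_map)
        landscapes = {
            s: mod_mod.detect_modules(w, lam=cfg.lam, eps=cfg.eps, theta=cfg.theta)
            for s, w in weighted.items()
        }
        states = list(weighted)
        matches = {
            f"{s1}->{s2}": mod_mod.match_modules(landscapes[s1], landscapes[s2]).pairs
            for s1, s2 in zip(states, states[1:])
        }
    else:
        net, table, grid, matches = _context

    baseline_ordering = _diameter_ordering(grid)
    baseline_matches = {
        key: {(p["from"], p["to"]) for p in pairs} for key, pairs in matches.items()
    }
    states = table.states

    ordering_preserved = 0
    match_preserved = {key: 0 for key in baseline_matches}
    replicate_p: list[dict] = []
    replicate_grids: list[dict] = []
    for r in range(n_replicates):
        noisy = ab_mod.perturb_noise(
            table, fraction=cfg.noise_fraction, seed=derive_seed(cfg.seed, 100 + r)
        )
        weighted_r = _weights_per_state(net, noisy, cfg.log_base)
        vectors = _aligned_weight_vectors(weighted_r)
        pvals = {}
        for i, s1 in enumerate(states):
            for s2 in states[i + 1:]:
                _, p = w_mod.paired_wilcoxon(vectors[s1], vectors[s2])
                pvals[f"{s1}-{s2}"] = p
        replicate_p.append(pvals)
        grid_r = diam_mod.diameter_grid(weighted_r, distance_map=cfg.distance_map)
        replicate_grids.append(
            {
                s: {conv: rep.diameter for conv, rep in by_conv.items()}
                for s, by_conv in grid_r.items()
            }
        )
        if _diameter_ordering(grid_r) == baseline_ordering:
            ordering_preserved += 1
        landscapes_r = {
            s: mod_mod.detect_modules(w, lam=cfg.lam, eps=cfg.eps, theta=cfg.theta)
            for s, w in weighted_r.items()
        }
        for s1, s2 in zip(states, states[1:]):
            key = f"{s1}->{s2}"
            pairs_r = mod_mod.match_modules(landscapes_r[s1], landscapes_r[s2]).pairs
            if {(p["from"], p["to"]) for p in pairs_r} == baseline_matches[key]:
                match_preserved[key] += 1

    return {
        "n_replicates": n_replicates,
        "noise_fraction": cfg.noise_fraction,
        "baseline_diameter_grid": {
            s: {conv: rep.diameter for conv, rep in by_conv.items()}
            for s, by_conv in grid.items()
        },
        "diameter_grids_per_replicate": replicate_grids,
        "diameter_ordering_stability": ordering_preserved / n_replicates,
        "module_match_stability": {
            key: match_preserved[key] / n_replicates for key in match_preserved
        },
        "wilcoxon_p_per_replicate": replicate_p,
    }


def _write_outputs(cfg, report, weighted, landscapes, pathway_df) -> None:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=float) + "\n"
    )
    for s, w in weighted.items():
        rows = [
            {"source": e[0], "target": e[1], "interaction": e[2],
             "weight": w.edge_weight(e[0], e[1])}
            for e in w.base.edges
        ]
        pd.DataFrame(rows).to_csv(outdir / f"weights_{s}.tsv", sep="\t", index=False)
    for s, ls in landscapes.items():
        ls.assignment.to_csv(outdir / f"assignment_{s}.tsv", sep="\t", index_label="node")
    if pathway_df is not None:
        pathway_df.to_csv(outdir / "pathways.tsv", sep="\t")
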