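# oncosignal

Analysis of how a signaling network reorganizes across biological states —
for example normal colon tissue, colon adenoma and colon carcinoma — when
the network topology is fixed and only gene expression changes.

The package is aimed at systems-biology researchers who have (a) a typed
signaling network (activating / inhibiting / undirected links between gene
symbols) and (b) per-state gene-expression matrices, and who want to ask:
does the network become more or less compact in a disease state?  Which
functional modules merge, split or strengthen?  Which pathways carry the
change?  A synthetic-data generator with planted ground truth stands in
for real microarray data, so every analysis stage is testable end to end.

## The model

**Link weights.** Per state, each gene gets an abundance `a_i`: the median
of its quantile-normalized log2 expression over all samples of that state.
Each network link `(i, j)` gets a weight

```
LW(i, j) = log10(a_i · a_j)
```

a proxy for the probability of the interaction: high when both partners
are abundant.  The same topology under three different weight sets gives
three *state networks*.

**Weighted diameter.** Weights are converted to path lengths by a negative
logarithmic mapping on the raw weight `p = 10^LW`:

```
d(i, j) = ln(p_max / p(i, j)) = ln(10) · (LW_max − LW(i, j))
```

so the strongest link has length 0 and Dijkstra's shortest path is the
most likely signal-transition path.  The diameter (longest shortest path)
and average path length are computed under three directivity conventions:
*undirected* (every link bidirectional), *directed* (only
activating/inhibiting links, with direction), and *mixed* (directed links
keep direction; each undirected link becomes two opposite arcs).  When
states are compared, all share one normalizer `p_max` so differences come
only from the weights.

**Overlapping modules.** Every node seeds an influence zone: one unit of
influence spreads synchronously, each step passing a fraction λ of the
current increment to neighbors in proportion to link weights.  Summed
zones form a *community landscape*; its hills (tolerant local maxima of
the height) are module cores, each node's assignment strength to a core is
proportional to that core's influence on it, and hills that overlap more
than θ merge.  *Community centrality* — the whole network's influence on
a node — names each module after its top member and ranks module
organizers.  Nodes can belong to several modules at once; the
`modular_overlap` metric (exp of the assignment-row entropy) is the
effective number of modules per node.

**Statistics.** Cross-state comparisons use the paired Wilcoxon
signed-rank test (edge- or gene-paired; exact null distribution by rank
convolution for n ≤ 25, normal approximation with tie correction above).
Extreme-link strata (top/bottom 10% and 1% by weight) and gene-set
(pathway) summaries — per-state medians, Shapiro–Wilk screens, paired
tests, weighted-degree ratios, extreme-link counts — localize the changes.
Robustness is checked by re-running everything with every abundance
multiplied by 1 ± 5% at random.

## Worked example

```python
import oncosignal as osg

cfg = osg.SyntheticConfig(seed=42)          # 300 nodes, 1200 links, 3 states
net, matrices, gene_sets, truth = osg.simulate(cfg)

table    = osg.build_abundances({s: [m] for s, m in matrices.items()})
network  = osg.filter_network(net, set(table.genes))
weighted = {s: osg.compute_link_weights(network, table.state(s), state=s)
            for s in table.states}

for state, w in weighted.items():
    s = osg.summarize_weights(w)
    print(state, round(s.median, 3), round(s.sd, 3))
```

prints

```
normal 1.8 0.121
adenoma 1.796 0.164
carcinoma 1.82 0.114
```

— the adenoma state has the most dispersed weights (sd 0.164 vs 0.121)
and the carcinoma state the highest median: the weakest links strengthen
in carcinoma.  The diameter grid (`oncosignal.diameter.diameter_grid`)
shows the same reorganization geometrically:

```
             undirected   directed   mixed
normal          6.815      19.114    9.212
adenoma         7.314      19.488    9.789
carcinoma       6.439      17.799    8.733
```

The carcinoma network is the most compact and the adenoma network the
least, under every directivity convention.  Module detection
(`osg.detect_modules`) finds 11–13 overlapping modules per state and
recovers the planted module with Jaccard ≈ 0.9 (`examples/03`), and the
pathway table (`examples/04`) isolates the planted gene set as the only
one with a significant normal-vs-carcinoma shift (paired Wilcoxon
p < 1e-4, decoys flat).

The scripts in `examples/` run each capability end to end and print a
short interpretation with every number.

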