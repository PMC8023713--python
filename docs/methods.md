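# Methods

This note records the models, parameter choices and numerical conventions
behind `oncosignal`, and what the synthetic benchmark does and does not
establish about real data.

## From expression to link weights

Expression matrices (genes × samples, log2-scale intensities, all values
finite and positive) are quantile-normalized within each series: every
column is replaced by the vector of row-rank means, so all samples share
one value distribution while within-column rank order is preserved.  Ties
receive the mean of the normalized values at their tied ranks; a
single-sample matrix is returned unchanged with a warning.  Normalization
is per series and *before* pooling, the standard order when several
array series contribute samples to one biological state.  Samples of all
series of a state are then pooled and the per-gene median taken — the
state's *abundance* `a_i`.  Genes missing from any state are dropped from
all states so the gene universe is shared.  Probe-level duplicates are
collapsed by row-wise median at read time, consistent with the median
aggregation used everywhere else.

The network is filtered once, before any analysis: links whose type is
unknown or whose endpoints were not measured are removed, then everything
outside the largest connected component of the undirected skeleton.
Parallel links of different types between the same pair are kept as
distinct links (they carry distinct biology); same-type duplicates merge.
Gene symbols match exactly and case-sensitively; alias resolution is out
of scope.

Link weights are `LW(i,j) = log10(a_i · a_j)`.  The product form means a
link is strong only when both partners are abundant, as for mass-action
binding; the logarithm tames outlying intensities.  Abundances enter on
the normalized log2-intensity scale as stored — they are never
exponentiated back to linear intensities — so `LW` for typical
intensities near 8 sits around `log10(64) ≈ 1.8`.  The weight is
symmetric in the endpoints and identical for parallel links of a pair.

## Distance mapping and diameters

Treating weights as interaction probabilities, the most likely path
maximizes the product of raw weights `p = 10^LW`, i.e. minimizes
`−Σ ln p`.  Each link therefore gets the non-negative length

    d = ln(p_norm / p) = ln(10) · (LW_norm − LW),

with `p_norm` the maximum raw weight (`neglog-maxnorm`, default) or the
total raw weight (`neglog-sumnorm`, configurable).  Two properties follow
exactly under the default: the strongest link has length zero, and
multiplying every abundance by a common factor cancels from the ratio,
leaving all lengths unchanged.  An alternative form sometimes written
down — the logarithm of the ratio of the *log*-weights themselves — has
neither property and compresses the length scale by roughly an order of
magnitude; it is not used.

When several states are compared (`diameter_grid`), all states share one
`p_norm` (the study-wide maximum).  With per-state normalizers, a state
that strengthens any near-maximal link would see every *other* distance
stretched and could appear less compact precisely because part of it got
stronger — an artifact of the normalizer, not of the network.  A single
state analyzed alone (`build_view` without `norm`) uses its own maximum.

Three directivity conventions are computed per state: undirected (all
links bidirectional), directed (only activating/inhibiting links, with
their direction) and mixed (directed links keep direction; each
undirected link contributes two opposite arcs of equal length).  Arc sets
are nested (directed ⊆ mixed ⊆ undirected-as-bidirectional) and all
conventions share the state's normalizer, so for any pair reachable in
all three views the distances nest the same way.  Before the all-pairs
computation the view is restricted to its largest connected component
(undirected) or largest strongly connected component (directed/mixed) —
diameter over unreachable pairs is undefined, and the strongly connected
restriction is the conservative reading of "removing the isolated parts"
for directed graphs.  Diameter and mean shortest-path length are taken
over ordered reachable pairs (unordered for the undirected view, where
both give the same mean); Dijkstra supplies the paths, and ties in the
extremal pair resolve to the lexicographically smallest (source, target).
Parallel arcs keep the minimum length.

## The community landscape

Influence spreading is linear and synchronous: a unit increment at the
seed; at each step every node passes λ times its current increment to its
neighbors in proportion to the incident link weights (row-stochastic
operator); accumulation stops for a seed when its total new increment
falls below ε.  Defaults λ = 0.5 (each hop halves the transported mass,
an influence horizon of a few links — the scale of a signaling complex),
ε = 1e−6 (plateau of the geometric tail; with λ = 0.5 about 20
iterations).  Non-positive link weights cannot carry spreading influence
and are clamped to zero with a warning; they do not arise on the usual
log2-intensity scale.

The landscape height of a node is the summed influence of all seeds on
it.  Module cores are *tolerant local maxima* of the height: a node whose
height reaches at least `(1 − core_tol)` of every neighbor's, with
`core_tol = 0.05`.  The tolerance is the analogue of the h-maxima
transform in watershed segmentation: with a strict comparison, one
marginally higher neighbor (for instance a cross-module contact of a hub)
erases a genuine hill and its entire region is absorbed by a neighboring
module; with the tolerance the hill keeps a core and surplus cores inside
one hill are merged away.  Raising the tolerance much beyond 0.05
fragments hills faster than merging repairs them.

Assignment strength of node n to core c is proportional to c's influence
on n, normalized so each node's strengths sum to 1.  Nodes unreached by
any core's zone (possible only in disconnected inputs) get uniform
membership.  Hills merge when their *proportional overlap* exceeds
θ = 0.9: the overlap of modules A and B is the sum of elementwise minima
of their influence vectors divided by the smaller vector's total, with
both modules' core self-entries masked — a zone is always largest at its
own seed, and without the mask two cores of one clique would never look
similar enough to merge.  The higher core absorbs the lower (ties to the
lexicographically smaller id), vectors add, and overlaps are recomputed
until stable; modules left without a discrete member are absorbed into
their most-overlapping neighbor.

Community centrality is the landscape height itself: the whole network's
influence on a node.  (The outgoing total of a node's own zone is
`1/(1−λ)` for every non-isolated node under row-stochastic spreading and
carries no information.)  A module is named after the discrete member
with the largest community centrality, ties to the smallest symbol.
`modular_overlap` is the exponential of the Shannon entropy of a node's
assignment row — the effective number of modules it belongs to — and
`effective_degree` is the weighted degree, definitions chosen for
interpretability where several conventions exist.

Cross-state module matching transfers each module of state A to the
module of state B that receives the plurality of its discrete members
(ties to larger Jaccard, then id).  Two or more A-modules mapping to one
B-module are annotated "merge"; the converse direction marks "split".
Jaccard similarity of discrete member sets is reported per pair.

## Paired tests and extreme links

The paired Wilcoxon signed-rank test pairs observations by edge (weights)
or by gene (pathway abundances).  Zero differences are removed first.
For n ≤ 25 the exact two-sided p-value is computed by convolving the
factors `(1/2 + 1/2·x^r)` over the observed midranks (doubled to stay
integer), which handles ties exactly, conditional on the observed rank
pattern; above 25 the normal approximation with tie correction is used
(no continuity correction).  The function accepts any n ≥ 1 with at
least one nonzero difference; pathway-level tests additionally require
five members before reporting a p-value.

Extreme strata take the `floor(f·E)` highest and lowest edges by weight
at f = 10% and 1%, ties broken by (weight, source, target, type) so the
strata are reproducible.  The percentile stratum is a subset of the
decile stratum by construction.  An edge belongs to a module only when
both endpoints are discretely assigned to it; edges spanning modules
count for neither (the conservative attribution).  For pathway
association the default is the opposite, at-least-one-endpoint
(configurable to both-endpoints): pathway links include the pathway's
interface to the rest of the network.

Weight summaries use linear interpolation between order statistics for
quartiles, sample standard deviation (ddof = 1), and three strength bins
(weak < 2, medium 2–2.7 closed on both ends, strong > 2.7 on the log10
scale), with the bin boundaries exposed as arguments.

## Synthetic study design

The generator produces the statistical structure the analysis assumes,
with ground truth for recovery tests.  Topology: nodes are split into
contiguous groups of `planted_module_size` (default 30 of 300); each
group grows a preferential-attachment tree (attachment probability ∝
degree + 1, giving each group a hub) and is densified by degree-biased
within-group edges; a `mixing` fraction (default 0.1) of all edges runs
between groups — a spanning chain connecting each group's hub to a
uniform member of the previous group plus cross-group pairs with
√degree-biased endpoints — for a connected, modular, hub-centered graph
of 1200 edges.  Signaling modules represent protein complexes, i.e.
cohesive subgraphs, which is why the background is modular rather than
uniform-random: in a uniform-random graph no module — planted or
otherwise — exists to be recovered.  The √degree bias reflects that
inter-module links preferentially attach to hubs, while a full degree
bias would often place two group hubs adjacent, erasing one group's
landscape hill.  Edge types are apportioned by largest remainder over the
curated cancer-signaling mix (2403:741:1915:30 of 5089) and shuffled;
directed links get a random orientation.

Expression: gene baselines `b_g ~ Normal(8, 1.5)` (log2 scale, truncated
above 0.5).  State means — normal: `b_g`; adenoma: gene-level deviations
inflated, `8 + κ(b_g − 8)` with κ = 1.3 (dispersion grows, the weight
distribution spreads); carcinoma: the planted module (the group holding
the top-degree hub) shifted up by δ = 1.0 log2 units, plus a global
compression of weakly expressed genes toward the mean by γ = 0.15 of
their shortfall.  The compression models the strengthening of the
weakest links in the carcinoma state — the feature that makes the
carcinoma network geometrically more compact; a purely local planted
boost leaves the two states' diameters tied whenever the extremal path
misses the planted region.  Samples add `Normal(0, 0.5)` noise (a
realistic within-state log2 spread for array data), floored at 0.01 to
keep intensities positive; 50 samples per state by default.  All draws
run through one integer-seeded generator with sorted iteration orders,
so output is fully deterministic.

What the generator does not emulate: probe-level effects, batch and
series effects, correlated noise between genes, realistic dynamic range
of raw intensities (its log-weights span ≈ 1.2–2.2 rather than the wider
span of real studies), or biologically structured edge types.  Passing
the recovery and ordering tests therefore shows the pipeline detects the
planted effects under clean, favorable conditions; it does not show the
effects are detectable in any particular real data set.

## Pipeline, seeds and robustness

`run_all` chains the stages (simulate/load → normalize → aggregate →
filter → weights → tests → diameters → modules → matches → extremes →
pathways → noise) and writes a JSON report plus per-state TSVs; rerunning
with the same seed is byte-identical.  One global seed fans out to
stage-specific sub-seeds through a fixed affine map modulo 2³¹−1, so
stages are independently reproducible.  The noise check multiplies every
abundance by exactly 1 ± fraction (fair coin per value, default 5%) —
not uniform noise in an interval, keeping the perturbation magnitude
interpretable — and reports the fraction of replicates preserving the
per-convention diameter ordering of states and each cross-state
module-match set, together with the per-replicate diameter grids and
Wilcoxon p-values.  Both stability criteria are strict set/ordering
equalities, so they are conservative: a single swap of two nearly-tied
states counts as a loss.

## Known limitations

- The influence landscape is one member of the family of
  influence-function community methods; no exact correspondence with any
  particular plugin implementation is claimed, and module boundaries on
  graphs without clear community structure are sensitive to near-ties in
  the landscape height.
- Module recovery is benchmarked at a single scale (groups of ~30); the
  method has no hierarchical layers.
- Diameters on the directed view can be dominated by the strongly
  connected core, which may be much smaller than the full network; the
  reported `n_nodes`/`n_reachable_pairs` make this visible.
- Quantile normalization assumes comparable global distributions across
  samples; background correction and batch adjustment are out of scope.
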