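"""Simulate a three-state study and compare link-weight distributions.

Generates the default synthetic study (a 300-node signaling network with
normal / adenoma / carcinoma expression), maps per-state abundances onto
the shared topology as link weights LW = log10(a_i * a_j), and prints the
distribution statistics and paired Wilcoxon comparisons.
"""

import oncosignal as osg

cfg = osg.SyntheticConfig(seed=42)
net, matrices, gene_sets, truth = osg.simulate(cfg)

table = osg.build_abundances({state: [m] for state, m in matrices.items()})
network = osg.filter_network(net, set(table.genes))
weighted = {
    state: osg.compute_link_weights(network, table.state(state), state=state)
    for state in table.states
}

print(f"network: {network.n_nodes} nodes, {network.n_edges} typed links\n")
print(f"{'state':<10} {'median':>7} {'sd':>7} {'min':>7} {'max':>7}  weak/medium/strong")
for state, w in weighted.items():
    s = osg.summarize_weights(w)
    bins = "/".join(f"{b:.2f}" for b in s.bin_fractions)
    print(f"{state:<10} {s.median:7.3f} {s.sd:7.3f} {s.min:7.3f} {s.max:7.3f}  {bins}")

print("\npaired Wilcoxon signed-rank (edge-paired weights):")
edges = weighted["normal"].base.edges
for a, b in [("normal", "adenoma"), ("adenoma", "carcinoma"), ("normal", "carcinoma")]:
    x = [weighted[a].edge_weight(s, t) for s, t, _ in edges]
    y = [weighted[b].edge_weight(s, t) for s, t, _ in edges]
    w_stat, p = osg.paired_wilcoxon(x, y)
    print(f"  {a} vs {b}: W+ = {w_stat:.0f}, p = {p:.3g}")

print(
    "\nThe adenoma state spreads the weight distribution (larger sd), the "
    "carcinoma state\nshifts weights up (larger median); the paired tests "
    "show all three states differ."
)
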