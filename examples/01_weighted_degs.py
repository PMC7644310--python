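"""Weighted DEGs: rank genes by regulatory influence, intersect with DEGs.

Builds a toy regulator->target network, computes the damped fixed-point
weights, and intersects the top-ranked genes with a DEG list.
"""

import goegcn as G

# A regulates B and C; B regulates C and D; E is isolated.
net = G.RegulatoryNetwork.from_edges(
    [("A", "B"), ("A", "C"), ("B", "C"), ("B", "D")],
    genes=["A", "B", "C", "D", "E"])

weights = G.compute_weights(net, d=0.85)
print("gene weights (restart value is (1-d)/N = 0.03):")
for gene in G.rank_top_m(weights, 5):
    print(f"  {gene}: {weights[gene]:.6f}")

degs = {"B", "C", "E"}
top2 = G.rank_top_m(weights, 2)
print(f"\nDEGs {sorted(degs)} ∩ top-2 weighted {top2} "
      f"-> weighted DEGs {G.weighted_degs(degs, top2)}")
print("A regulator's weight exceeds the restart value exactly when it has "
      "targets; here A and B accumulate weight from the genes they regulate.")
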