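"""Group-average network and communicability assortativity.

Generates a small synthetic cohort, builds the 75%-presence average
network, and summarizes how communicability concentrates among high-degree
nodes (positive assortative communicability) and how densely the
top-communicability nodes are interconnected.
"""

import numpy as np

import commlesion as cl

cohort = cl.generate_cohort(
    cl.CohortSpec(n_subjects=10, n_nodes=60), seed=42
)
avg = cl.build_average_network(cohort, presence_threshold=0.75)
pairs = avg.n_nodes * (avg.n_nodes - 1) / 2
print(f"average network: {avg.n_nodes} nodes, {avg.n_edges()} edges "
      f"(density {avg.n_edges() / pairs:.3f})")

_, blocks, _ = cl.communicability_assortativity(avg, weighted=False, k=15)
print("mean communicability within the 15 lowest-degree nodes :",
      round(blocks["bottom"], 4))
print("mean communicability within the 15 highest-degree nodes:",
      round(blocks["top"], 4))
print("mean communicability across the two blocks             :",
      round(blocks["cross"], 4))

deg, sw = cl.degree_strength(avg)
cm = cl.node_communicability(cl.communicability_binary(avg))
for name, vec in [("Deg", deg), ("Sw", sw), ("Cm", cm)]:
    dens = cl.top_node_density(avg, vec, k=10)
    print(f"density among the 10 top-{name} nodes: {dens:.3f}")
print()
print("top-block communicability exceeding the bottom block is the")
print("positive assortativity signature; the top-Cm subgraph is at least")
print("as dense as the top-degree one.")
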