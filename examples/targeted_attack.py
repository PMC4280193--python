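"""Targeted attacks: single-choice versus frozen hub order.

Removes 20 nodes from one synthetic connectome under the degree and the
communicability-centrality criteria, with the criterion either recomputed
after every removal (single-choice) or frozen on the intact network (hubs
order), and prints the global-efficiency decay.
"""

import numpy as np

import commlesion as cl

cohort = cl.generate_cohort(cl.CohortSpec(n_subjects=1, n_nodes=60), seed=3)
net = cohort.subjects[0][1]
print(f"intact efficiency: Eff = {cl.global_efficiency(net):.3f}, "
      f"Eff^w = {cl.global_efficiency(net, weighted=True):.3f}")

for criterion in ("Deg", "CBC"):
    for method in ("single_choice", "hubs_order"):
        trace = cl.targeted_attack(net, criterion, method, n_attacks=20)
        eff = trace.eff_binary
        print(f"{criterion:4s} {method:13s} Eff after 5/10/20 removals: "
              f"{eff[5]:.3f} / {eff[10]:.3f} / {eff[20]:.3f}")
print()
print("single-choice curves sit at or below the frozen-order curves: "
      "re-ranking after each removal finds the currently most central node.")
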