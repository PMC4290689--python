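"""Predict one temporal response network on a synthetic benchmark.

Builds a 60-gene instance with 4 planted temporal paths over a noisy
background, runs the minimum-cost-flow method at (gamma1, gamma2) = (1, 1)
and prints the predicted sub-network. SRC/INT/SNK nodes are members of the
early/intermediate/late input groups; NOD nodes are predicted transient
regulators with no measured expression change. Flow is the importance score:
higher flow, more central to the predicted response.
"""

import tempoflow as tf

spec = tf.SyntheticSpec(n_genes=60, n_paths=4, path_len=2,
                        background_edges=150, seed=11)
net, part, truth = tf.generate_planted_network(spec)
print(f"input: {len(net)} ordered interactions over {len(net.genes)} genes; "
      f"groups: {len(part.early)} early / {len(part.intermediate)} "
      f"intermediate / {len(part.late)} late")

result = tf.run_on_data(net, part, tf.LPParameters(gamma1=1.0, gamma2=1.0))
rn = result.response
print(f"objective {result.solution.objective:.4f}; predicted network: "
      f"{len(rn.nodes)} genes, {len(rn.edges)} interactions")

by_type = {}
for n in rn.nodes:
    by_type.setdefault(n.node_type, []).append(n)
for t in ("SRC", "INT", "SNK", "NOD"):
    members = sorted(by_type.get(t, []), key=lambda n: -n.flow)
    shown = ", ".join(f"{n.gene}({n.flow:.3f})" for n in members[:4])
    print(f"  {t}: {len(members)} genes, top flows: {shown}")

m = tf.evaluate_recovery(rn, truth)
print(f"against the planted ground truth: edge recall {m.edge_recall:.2f}, "
      f"precision {m.edge_precision:.2f}, transient-regulator (NOD) recall "
      f"{m.nod_recall:.2f}")
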