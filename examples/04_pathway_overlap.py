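"""Score a prediction by its longest consecutive overlap with a reference
pathway.

A predicted network is more credible when it reproduces long unbroken runs
of directed edges from an independently curated pathway. This example plants
paths, predicts the network, and reports the longest directed path shared
with the (here: ground-truth) reference edge set.
"""

import tempoflow as tf

spec = tf.SyntheticSpec(n_genes=60, n_paths=4, path_len=2,
                        background_edges=150, seed=11)
net, part, truth = tf.generate_planted_network(spec)
result = tf.run_on_data(net, part, tf.LPParameters(gamma1=1.0, gamma2=1.0))

overlap = tf.max_consecutive_overlap(result.response, truth.planted_edges)
print(f"longest consecutive directed overlap with the reference pathway: "
      f"{overlap} edges")
print(f"(planted paths are {spec.path_len + 2} edges long: start -> "
      f"interior -> regulator -> interior -> end)")
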