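"""Independent oracles used by the test suite.

`random_integer_instance` builds small flow graphs with integer capacities;
`enumerate_min_objective` finds the true minimum objective by exhaustively
enumerating every integral flow (node-arc incidence matrices are totally
unimodular, so an integral optimum exists for integral capacities). These
routines never call the LP path they are used to check.
"""

from __future__ import annotations

import itertools
from dataclasses import replace

import numpy as np

import tempoflow as tf
from tempoflow.model import ArcKind


def random_integer_instance(seed: int, max_edges: int = 3):
    """A random small validated instance with integer arc capacities <= 2.

    Genes: one early, one late, 1-2 intermediates, 0-1 untyped way-point.
    Edges are sampled until the flow graph is buildable (early gene has an
    out-edge, late gene an in-edge).
    """
    rng = np.random.default_rng(seed)
    while True:
        n_mid = int(rng.integers(1, 3))
        n_extra = int(rng.integers(0, 2))
        genes = ["E", "L"] + [f"M{i}" for i in range(n_mid)] + \
                [f"X{i}" for i in range(n_extra)]
        pairs = [(u, v) for u in genes for v in genes if u != v]
        n_edges = int(rng.integers(2, max_edges + 1))
        picks = rng.choice(len(pairs), size=n_edges, replace=False)
        net = tf.InteractionNetwork()
        for k in picks:
            u, v = pairs[int(k)]
            w = float(rng.uniform(0.3, 1.0))
            net.add(tf.Interaction(u, v, tf.Directionality.UNIDIRECTIONAL, w))
        present = net.genes
        mids = {f"M{i}": 1.0 for i in range(n_mid) if f"M{i}" in present}
        if "E" not in present or "L" not in present or not mids:
            continue
        try:
            part = tf.GeneGroupPartition(
                early={"E": 1.0},
                intermediate=mids,
                late={"L": 1.0},
            )
            params = tf.LPParameters(
                gamma1=float(rng.uniform(0.2, 3.0)),
                gamma2=float(rng.uniform(0.2, 3.0)),
            )
            graph = tf.build_flow_graph(net, part, params)
        except tf.InputError:
            continue
        # override every finite capacity with a random integer in {1, 2}
        arcs = [
            a if a.kind is ArcKind.RETURN_ARC
            else replace(a, capacity=float(rng.integers(1, 3)))
            for a in graph.arcs
        ]
        graph = tf.FlowGraph(nodes=graph.nodes, arcs=arcs,
                             partition=graph.partition, params=graph.params,
                             network=graph.network)
        return graph


def enumerate_min_objective(problem) -> float:
    """True minimum objective over all integral feasible flows.

    The return arc's flow is not enumerated: conservation at the source pins
    it to the total source-arc flow.
    """
    arcs = problem.graph.arcs
    ret = next(j for j, a in enumerate(arcs) if a.kind is ArcKind.RETURN_ARC)
    src = [j for j, a in enumerate(arcs) if a.kind is ArcKind.SOURCE_ARC]
    free = [j for j in range(len(arcs)) if j != ret]
    caps = [int(arcs[j].capacity) for j in free]
    assert all(c <= 2 for c in caps), "oracle assumes capacities <= 2"

    combos = np.array(
        list(itertools.product(*[range(c + 1) for c in caps])), dtype=float
    )
    flows = np.zeros((combos.shape[0], len(arcs)))
    flows[:, free] = combos
    src_cols = [free.index(j) for j in src]
    flows[:, ret] = combos[:, src_cols].sum(axis=1)

    a = problem.a_eq.toarray()
    resid = np.abs(a @ flows.T).max(axis=0)
    feasible = flows[resid < 1e-9]
    assert feasible.size, "zero flow is always feasible"
    return float((feasible @ problem.c).min())
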