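"""Independent oracles shared by the unit and acceptance suites.

These deliberately avoid the package's pruning code path: the
likelihood oracle sums over every internal-node state assignment.
"""

import itertools
import math

import numpy as np
from scipy.linalg import expm

from sexlinkage.phylo import TipStateMatrix

TREES = [
    "(A:1.2,B:0.7);",
    "((A:0.5,B:1.1):0.6,C:2.0);",
    "((A:0.3,B:0.4):0.8,(C:0.9,D:1.0):0.2);",
    "(((A:0.2,B:0.3):0.4,C:0.5):0.6,D:1.5);",
    "((((A:0.1,B:0.2):0.3,C:0.4):0.5,D:0.6):0.7,E:2.1);",
    "((A:0.5,B:0.5,C:0.5):0.5,D:1.0);",  # polytomy
]


def enum_loglik(tree, tips, model):
    """Exhaustive sum over all internal-node state assignments."""
    K = model.K
    nodes = list(tree.preorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    P = {n: expm(model.Q * (n.edge.length or 0.0)) for n in nodes if n.parent_node is not None}
    total = 0.0
    for assign in itertools.product(range(K), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        prob = model.root_prior[amap[tree.seed_node]]
        for n in nodes:
            if n.parent_node is None:
                continue
            ps = amap[n.parent_node]
            if n.is_leaf():
                row = tips.row_for(n.taxon.label)
                row = row / row.max()
                prob *= float(sum(P[n][ps, k] * row[k] for k in range(K)))
            else:
                prob *= float(P[n][ps, amap[n]])
        total += prob
    return math.log(total)


def random_tips(labels, K, rng):
    """Random mix of certain, two-state ambiguous and unknown tips."""
    choices = {}
    for lab in labels:
        r = rng.random()
        if r < 0.2:
            choices[lab] = None
        elif r < 0.4 and K >= 2:
            choices[lab] = sorted(rng.choice(K, size=2, replace=False).tolist())
        else:
            choices[lab] = int(rng.integers(K))
    return TipStateMatrix.from_states(choices, tuple(f"s{k}" for k in range(K)))
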