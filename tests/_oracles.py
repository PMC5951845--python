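"""Independent oracles used by the test suite.

These deliberately avoid the package's pruning/propagator code paths:
likelihoods are computed by exhaustive enumeration over internal-node
state assignments with scipy's dense matrix exponential.
"""

import itertools

import numpy as np
from scipy.linalg import expm

from nestevo.trees import TreeArrays


def brute_force_loglik(arrays: TreeArrays, state_sets, Q, root_prior) -> float:
    """Sum over every internal-node state assignment (and every allowed
    state of polymorphic/missing tips) of the product of exp(Qt) entries."""
    k = Q.shape[0]
    P = [expm(Q * t) for t in arrays.edge_len]
    tip_of_node = {int(n): j for j, n in enumerate(arrays.tip_node)}
    internals = [i for i in range(arrays.n_nodes) if arrays.child_count[i] > 0]
    root = arrays.n_nodes - 1
    allowed = {}
    for i in range(arrays.n_nodes):
        if arrays.child_count[i] == 0:
            ss = state_sets[arrays.taxon_labels[tip_of_node[i]]]
            allowed[i] = list(range(k)) if not ss else sorted(ss)
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        st = dict(zip(internals, assign))
        branch_prob = root_prior[st[root]]
        for i in range(arrays.n_nodes - 1):
            par = st[arrays.parent[i]]
            if arrays.child_count[i] == 0:
                branch_prob *= sum(P[i][par, s] for s in allowed[i])
            else:
                branch_prob *= P[i][par, st[i]]
        total += branch_prob
    return float(np.log(total))


def random_state_sets(rng, labels, k, poly_prob=0.2, missing_prob=0.1):
    out = {}
    for lbl in labels:
        u = rng.random()
        if u < missing_prob:
            out[lbl] = None
        elif u < missing_prob + poly_prob:
            out[lbl] = set(rng.choice(k, size=2, replace=False).tolist())
        else:
            out[lbl] = {int(rng.integers(k))}
    return out
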