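"""Numerical core: transition matrices and Felsenstein pruning kernels.

The kernels are compiled with numba and operate on the flat postorder
encoding from :mod:`nestevo.trees`.  Per-node rescaling keeps partial
likelihoods in range on large trees; the accumulated log-scalers are added
back to the root total.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.linalg import expm


@njit(cache=False)
def _pruning_loglik(child_list, child_start, child_count, P, partials, root_prior):
    n, k = partials.shape
    logscale = 0.0
    work = np.empty(k)
    for i in range(n):
        cc = child_count[i]
        if cc == 0:
            continue
        for a in range(k):
            work[a] = 1.0
        for ci in range(child_start[i], child_start[i] + cc):
            c = child_list[ci]
            for a in range(k):
                s = 0.0
                for b in range(k):
                    s += P[c, a, b] * partials[c, b]
                work[a] *= s
        m = 0.0
        for a in range(k):
            if work[a] > m:
                m = work[a]
        if m <= 0.0:
            return -np.inf
        for a in range(k):
            partials[i, a] = work[a] / m
        logscale += np.log(m)
    root = n - 1
    tot = 0.0
    for a in range(k):
        tot += root_prior[a] * partials[root, a]
    if tot <= 0.0:
        return -np.inf
    return np.log(tot) + logscale


@njit(cache=False)
def _node_marginals(child_list, child_start, child_count, parent, P, partials, root_prior):
    """Marginal posterior state probabilities at every node (up-down pass).

    ``partials`` must already hold the (rescaled) up-pass partials, i.e.
    `_pruning_loglik` has been run on the same buffer.
    """
    n, k = partials.shape
    down = np.zeros((n, k))
    root = n - 1
    for a in range(k):
        down[root, a] = root_prior[a]
    # S[c] = P[c] @ partials[c], the contribution of child c to its parent
    S = np.empty((n, k))
    for c in range(n - 1):
        for a in range(k):
            s = 0.0
            for b in range(k):
                s += P[c, a, b] * partials[c, b]
            S[c, a] = s
    for i in range(n - 1, -1, -1):  # preorder
        cc = child_count[i]
        if cc == 0:
            continue
        for ci in range(child_start[i], child_start[i] + cc):
            c = child_list[ci]
            # message from above: down[i] times siblings' contributions
            tot = 0.0
            for b in range(k):
                acc = 0.0
                for a in range(k):
                    up = down[i, a]
                    for cj in range(child_start[i], child_start[i] + cc):
                        s = child_list[cj]
                        if s != c:
                            up *= S[s, a]
                    acc += P[c, a, b] * up
                down[c, b] = acc
                tot += acc
            if tot > 0.0:
                for b in range(k):
                    down[c, b] /= tot
    marg = np.empty((n, k))
    for i in range(n):
        tot = 0.0
        for a in range(k):
            marg[i, a] = down[i, a] * partials[i, a]
            tot += marg[i, a]
        if tot > 0.0:
            for a in range(k):
                marg[i, a] /= tot
    return marg


@njit(cache=False)
def _simulate_states(child_list, child_start, child_count, P, root_state, n_rep, seed):
    """Simulate discrete states down the tree; returns (n_rep, n_nodes)."""
    np.random.seed(seed)
    n = child_count.shape[0]
    k = P.shape[1]
    out = np.empty((n_rep, n), dtype=np.int64)
    root = n - 1
    for r in range(n_rep):
        out[r, root] = root_state
        for i in range(n - 1, -1, -1):
            cc = child_count[i]
            if cc == 0:
                continue
            a = out[r, i]
            for ci in range(child_start[i], child_start[i] + cc):
                c = child_list[ci]
                u = np.random.random()
                acc = 0.0
                b = k - 1
                for j in range(k):
                    acc += P[c, a, j]
                    if u < acc:
                        b = j
                        break
                out[r, c] = b
    return out


# -- transition-probability builders --------------------------------------


def er_transition_matrices(k: int, q: float, t: np.ndarray) -> np.ndarray:
    """Closed-form equal-rates transition matrices for branch lengths ``t``.

    P_same(t) = 1/k + (k-1)/k * exp(-k q t); P_diff(t) = 1/k - 1/k * exp(-k q t).
    """
    t = np.asarray(t, dtype=np.float64)
    e = np.exp(-k * q * t)
    off = (1.0 - e) / k
    P = np.repeat(off, k * k).reshape(t.shape + (k, k))
    diag = off + e
    idx = np.arange(k)
    P[..., idx, idx] = diag[..., None]
    return P


class QEigenPropagator:
    """Transition matrices exp(Q t) for a general rate matrix via
    eigendecomposition, with a dense-expm fallback for defective Q."""

    def __init__(self, Q: np.ndarray):
        self.Q = np.asarray(Q, dtype=np.float64)
        self.k = self.Q.shape[0]
        self._ok = False
        try:
            lam, V = np.linalg.eig(self.Q)
            Vinv = np.linalg.inv(V)
            if np.linalg.cond(V) < 1e8:
                self._lam, self._V, self._Vinv = lam, V, Vinv
                self._ok = True
        except np.linalg.LinAlgError:
            pass

    def matrices(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        if self._ok:
            E = np.exp(np.multiply.outer(t, self._lam))  # (..., k)
            P = np.einsum("ij,...j,jl->...il", self._V, E, self._Vinv)
            P = np.ascontiguousarray(P.real)
        else:
            flat = t.reshape(-1)
            P = np.stack([expm(self.Q * ti) for ti in flat]).reshape(t.shape + (self.k, self.k))
        np.clip(P, 0.0, None, out=P)
        return P


def tip_partials_template(arrays, state_sets, k: int) -> np.ndarray:
    """(n_nodes, k) buffer with tip rows set to state-set indicators.

    Polymorphic tips get 1 on every observed state; missing tips (``None``
    or empty set) get an all-ones row.  Internal rows are scratch space for
    the kernels.
    """
    partials = np.zeros((arrays.n_nodes, k))
    for j, label in enumerate(arrays.taxon_labels):
        row = np.zeros(k)
        states = state_sets[j]
        if states is None or len(states) == 0:
            row[:] = 1.0
        else:
            for s in states:
                if not 0 <= int(s) < k:
                    raise ValueError(f"state {s} out of range for k={k}")
                row[int(s)] = 1.0
        partials[arrays.tip_node[j]] = row
    return partials
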