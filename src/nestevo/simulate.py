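"""Synthetic trees and discrete traits for testing the analysis pipeline.

Emulates the statistical structure of the real inputs: a family-level
time-calibrated phylogeny (Yule trees, ~200 tips), topological and
branch-length uncertainty across a tree set (random NNI moves plus
multiplicative log-normal branch-length noise), discrete traits evolved
under a Markov process, polymorphic and missing tips, and pairs of binary
traits evolved under a contingent-rates (dependent) process.

All randomness flows through explicit ``numpy`` generators seeded from the
caller; identical configuration and seed reproduce identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from ._pruning import QEigenPropagator, er_transition_matrices
from .errors import InputError, InvalidParameterError
from .mk import MkModel
from .trees import TreeArrays

__all__ = [
    "SimulationConfig",
    "simulate_yule_tree",
    "perturb_tree_set",
    "simulate_discrete_trait",
    "simulate_polymorphic_tipset",
    "simulate_correlated_binary_pair",
]


@dataclass
class SimulationConfig:
    """Bundle of generator settings for a full synthetic dataset.

    Defaults emulate the real study inputs: a 242-family tree set with
    mild topological/branch-length uncertainty, and characters in which a
    noticeable minority of families are polymorphic and a few percent are
    missing.
    """

    n_tips: int = 242
    birth_rate: float = 1.0
    n_trees: int = 100
    perturb_strength: int = 2
    bl_jitter: float = 0.1
    poly_prob: float = 0.15
    missing_prob: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 3:
            raise InvalidParameterError("n_tips must be >= 3")
        if self.n_trees < 1:
            raise InvalidParameterError("n_trees must be >= 1")
        for name in ("poly_prob", "missing_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise InvalidParameterError(f"{name} must lie in [0, 1]")
        if self.perturb_strength < 0 or self.bl_jitter < 0:
            raise InvalidParameterError("perturb_strength and bl_jitter must be >= 0")


def simulate_yule_tree(n_tips: int, birth_rate: float, seed) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree with ``n_tips`` labelled tips.

    The root splits at time zero; thereafter each lineage bifurcates at
    rate ``birth_rate``.  After the (n-1)-th split the tree is extended by
    one further exponential waiting time so the expected height equals
    sum_{m=2..n} 1/(birth_rate * m).
    """
    if n_tips < 2:
        raise InvalidParameterError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise InvalidParameterError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    root = tree.seed_node
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node, born = active.pop(i)
        node.edge.length = t - born
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    for j, (node, born) in enumerate(active):
        node.edge.length = t - born
        node.taxon = taxa[j]
    return tree


def _nni_candidates(tree: dendropy.Tree) -> list[dendropy.Node]:
    """Internal nodes eligible for a rooted NNI (non-root, >= 2 children,
    with at least one sibling)."""
    out = []
    for nd in tree.preorder_internal_node_iter():
        p = nd.parent_node
        if p is not None and len(nd.child_nodes()) >= 2 and len(p.child_nodes()) >= 2:
            out.append(nd)
    return out


def _apply_nni(tree: dendropy.Tree, rng: np.random.Generator) -> None:
    cands = _nni_candidates(tree)
    if not cands:
        return
    nd = cands[int(rng.integers(len(cands)))]
    p = nd.parent_node
    siblings = [c for c in p.child_nodes() if c is not nd]
    s = siblings[int(rng.integers(len(siblings)))]
    kids = nd.child_nodes()
    a = kids[int(rng.integers(len(kids)))]
    p.remove_child(s)
    nd.remove_child(a)
    p.add_child(a)
    nd.add_child(s)


def perturb_tree_set(
    base_tree: dendropy.Tree,
    n_trees: int,
    perturb_strength: int,
    bl_jitter: float,
    seed,
) -> dendropy.TreeList:
    """Tree set emulating topological and branch-length uncertainty.

    Each tree is a clone of ``base_tree`` after ``perturb_strength`` random
    NNI moves and multiplicative log-normal branch-length noise with
    coefficient of variation ``bl_jitter`` (mean 1, so lengths are unbiased
    and stay positive).
    """
    if n_trees < 1:
        raise InvalidParameterError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    base_tips = {leaf.taxon.label for leaf in base_tree.leaf_node_iter()}
    sigma = np.sqrt(np.log1p(bl_jitter**2)) if bl_jitter > 0 else 0.0
    out = dendropy.TreeList(taxon_namespace=base_tree.taxon_namespace)
    for _ in range(n_trees):
        t = base_tree.clone(depth=1)
        for _ in range(perturb_strength):
            _apply_nni(t, rng)
        if sigma > 0:
            for edge in t.preorder_edge_iter():
                if edge.length is not None:
                    edge.length = float(edge.length * rng.lognormal(-0.5 * sigma**2, sigma))
        tips = {leaf.taxon.label for leaf in t.leaf_node_iter()}
        if tips != base_tips:
            raise InputError("tip set changed during perturbation")
        out.append(t)
    return out


def _edge_matrices(arrays: TreeArrays, model: MkModel) -> np.ndarray:
    if model.rate_model == "ER":
        return er_transition_matrices(model.k, float(model.rates[0]), arrays.edge_len)
    return QEigenPropagator(model.rate_matrix()).matrices(arrays.edge_len)


def _simulate_node_states(arrays: TreeArrays, P: np.ndarray, root_state: int, rng) -> np.ndarray:
    k = P.shape[1]
    states = np.empty(arrays.n_nodes, dtype=np.int64)
    states[arrays.root] = root_state
    for i in range(arrays.n_nodes - 2, -1, -1):  # preorder below root
        row = P[i, states[arrays.parent[i]]]
        states[i] = rng.choice(k, p=row / row.sum())
    return states


def simulate_discrete_trait(tree, model: MkModel, root_state: int, seed) -> dict[str, int]:
    """One realisation of a discrete trait on ``tree`` under ``model``.

    States change along each branch according to the model's
    transition-probability matrices, starting from ``root_state`` at the
    root; returns a tip-label -> state map.
    """
    if not 0 <= root_state < model.k:
        raise InvalidParameterError(f"root_state {root_state} out of range for k={model.k}")
    arrays = tree if isinstance(tree, TreeArrays) else TreeArrays.from_tree(tree)
    rng = np.random.default_rng(seed)
    P = _edge_matrices(arrays, model)
    states = _simulate_node_states(arrays, P, root_state, rng)
    return {label: int(states[arrays.tip_node[j]]) for j, label in enumerate(arrays.taxon_labels)}


def simulate_polymorphic_tipset(
    tip_states: dict[str, int],
    model: MkModel,
    poly_prob: float,
    missing_prob: float,
    seed,
) -> dict[str, frozenset[int] | None]:
    """Inject polymorphism and missing data into single-state tips.

    Each tip is independently flagged missing with probability
    ``missing_prob``; otherwise, with probability ``poly_prob``, a second
    distinct state (uniform over the remaining k-1) is appended.
    """
    if poly_prob + missing_prob > 1:
        raise InvalidParameterError("poly_prob + missing_prob must be <= 1")
    rng = np.random.default_rng(seed)
    out: dict[str, frozenset[int] | None] = {}
    for label in sorted(tip_states):
        s = tip_states[label]
        u = rng.random()
        if u < missing_prob:
            out[label] = None
        elif u < missing_prob + poly_prob:
            extra = int(rng.integers(model.k - 1))
            if extra >= s:
                extra += 1
            out[label] = frozenset({s, extra})
        else:
            out[label] = frozenset({s})
    return out


#: order of the 8 contingent rates over joint states 00,01,10,11 of a
#: binary trait pair (A, B); double transitions have rate 0.
DEPENDENT_RATE_NAMES = [
    "b_gain_a0",  # 00 -> 01
    "a_gain_b0",  # 00 -> 10
    "b_loss_a0",  # 01 -> 00
    "a_gain_b1",  # 01 -> 11
    "a_loss_b0",  # 10 -> 00
    "b_gain_a1",  # 10 -> 11
    "a_loss_b1",  # 11 -> 01
    "b_loss_a1",  # 11 -> 10
]


#: reference study conditions for the dependent-pair generator.  "Strong
#: dependence": trait B can gain its derived state only while A is derived
#: (contingent gain 1.0 vs 0), with A toggling at a moderate rate so both
#: contexts are visited.  The context-free condition uses the same
#: magnitudes with no contingency.
STRONG_DEPENDENCE_RATES = np.array([0.0, 0.3, 0.1, 0.3, 0.3, 1.0, 0.3, 0.1])
CONTEXT_FREE_RATES = np.array([0.2, 0.3, 0.1, 0.3, 0.3, 0.2, 0.3, 0.1])


def dependent_rate_matrix(rates) -> np.ndarray:
    """4x4 generator over joint states (00, 01, 10, 11) from the 8
    contingent rates in ``DEPENDENT_RATE_NAMES`` order."""
    r = np.asarray(rates, dtype=np.float64)
    if r.shape != (8,):
        raise InvalidParameterError("dependent model needs exactly 8 rates")
    if np.any(r < 0):
        raise InvalidParameterError("rates must be non-negative")
    Q = np.zeros((4, 4))
    Q[0, 1], Q[0, 2] = r[0], r[1]
    Q[1, 0], Q[1, 3] = r[2], r[3]
    Q[2, 0], Q[2, 3] = r[4], r[5]
    Q[3, 1], Q[3, 2] = r[6], r[7]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def simulate_correlated_binary_pair(
    tree, dependent_rates, root_pair: tuple[int, int], seed
) -> dict[str, tuple[int, int]]:
    """Simulate two binary traits jointly under a contingent-rates model.

    The joint state evolves as a 4-state Markov chain over (A,B) in
    {00,01,10,11}; simultaneous double transitions are impossible.  Returns
    a tip-label -> (a, b) map.
    """
    Q = dependent_rate_matrix(dependent_rates)
    arrays = tree if isinstance(tree, TreeArrays) else TreeArrays.from_tree(tree)
    rng = np.random.default_rng(seed)
    P = QEigenPropagator(Q).matrices(arrays.edge_len)
    root_state = 2 * root_pair[0] + root_pair[1]
    if not 0 <= root_state < 4 or root_pair[0] not in (0, 1) or root_pair[1] not in (0, 1):
        raise InvalidParameterError("root_pair must be a pair of 0/1 states")
    states = _simulate_node_states(arrays, P, root_state, rng)
    return {
        label: (int(states[arrays.tip_node[j]]) // 2, int(states[arrays.tip_node[j]]) % 2)
        for j, label in enumerate(arrays.taxon_labels)
    }
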