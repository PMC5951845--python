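"""Phylogenetic signal tests for set-valued characters.

Two Mantel-type tests of the association between phylogenetic distance and
trait dissimilarity:

* the conventional Mantel test, whose null is built by jointly permuting
  the rows/columns of the trait dissimilarity matrix (taxon-label
  shuffling), and
* the evolutionary-model-based (EM-)Mantel test, whose null is built by
  repeatedly re-simulating the character under a fitted neutral Markov
  model on the same tree, so the null already carries the correlation
  expected from shared ancestry alone.

Trait dissimilarity between two families is the Bray-Curtis dissimilarity
of their state sets, 1 - 2|A n B| / (|A| + |B|), which reduces to the 0/1
mismatch metric on single-state families.  p-values are two-sided (double
the smaller tail) with add-one correction, so both significantly positive
(conserved) and significantly negative deviations can be detected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._pruning import _simulate_states, er_transition_matrices
from .errors import (
    DroppedReplicateWarning,
    InputError,
    InvalidParameterError,
    UndefinedStatisticError,
)
from .mk import MkModel
from .trees import TreeArrays

__all__ = [
    "MantelResult",
    "patristic_distances",
    "bray_curtis_dissimilarity",
    "bray_curtis_matrix",
    "mantel_statistic",
    "conventional_mantel",
    "em_mantel",
    "signal_report",
]


def patristic_distances(tree, taxon_order=None) -> tuple[list[str], np.ndarray]:
    """Labels and the matrix of path-length distances between all tip pairs."""
    arrays = tree if isinstance(tree, TreeArrays) else TreeArrays.from_tree(tree, taxon_order=taxon_order)
    return list(arrays.taxon_labels), arrays.patristic_matrix()


def bray_curtis_dissimilarity(set_a, set_b) -> float:
    """1 - 2|A n B| / (|A| + |B|) on presence/absence state sets."""
    a, b = frozenset(set_a), frozenset(set_b)
    if not a or not b:
        raise InputError("Bray-Curtis undefined for empty state sets; drop missing families first")
    return 1.0 - 2.0 * len(a & b) / (len(a) + len(b))


def bray_curtis_matrix(labels, state_sets: dict) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity over families, in ``labels`` order."""
    states = sorted({s for lbl in labels for s in state_sets[lbl]})
    index = {s: i for i, s in enumerate(states)}
    X = np.zeros((len(labels), len(index)))
    for i, lbl in enumerate(labels):
        ss = state_sets[lbl]
        if not ss:
            raise InputError(f"family {lbl!r} has no states; drop missing families first")
        for s in ss:
            X[i, index[s]] = 1.0
    inter = X @ X.T
    sizes = X.sum(axis=1)
    d = 1.0 - 2.0 * inter / (sizes[:, None] + sizes[None, :])
    np.fill_diagonal(d, 0.0)
    return d


def _upper(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], 1)
    return d[iu]


def _standardize(v: np.ndarray) -> np.ndarray:
    s = v.std()
    if s == 0:
        raise UndefinedStatisticError("distance matrix has zero variance off-diagonal")
    return (v - v.mean()) / s


def mantel_statistic(d1: np.ndarray, d2: np.ndarray) -> float:
    """Pearson correlation between the strictly-upper-triangle entries."""
    d1, d2 = np.asarray(d1, float), np.asarray(d2, float)
    if d1.shape != d2.shape or d1.ndim != 2 or d1.shape[0] != d1.shape[1]:
        raise InputError("matrices must be square and of equal shape")
    if d1.shape[0] < 4:
        raise InvalidParameterError("Mantel statistic needs >= 4 taxa")
    v1, v2 = _standardize(_upper(d1)), _standardize(_upper(d2))
    return float(v1 @ v2 / v1.size)


def _two_sided_p(r_emp: float, null: np.ndarray) -> tuple[float, float, float]:
    n = null.size
    p_pos = (np.sum(null >= r_emp) + 1) / (n + 1)
    p_neg = (np.sum(null <= r_emp) + 1) / (n + 1)
    return min(1.0, 2.0 * min(p_pos, p_neg)), p_pos, p_neg


@dataclass
class MantelResult:
    """Empirical Mantel r with its permutation and/or evolutionary-model
    null distributions and two-sided p-values."""

    r: float
    n_taxa: int
    seed: int | None = None
    perm_null: np.ndarray | None = None
    p_perm: float | None = None
    em_null: np.ndarray | None = None
    p_em: float | None = None
    n_dropped: int = 0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"r": self.r, "n_taxa": self.n_taxa, "seed": self.seed}
        if self.perm_null is not None:
            out.update(
                p_perm=self.p_perm,
                n_perm=int(self.perm_null.size),
                perm_null_mean=float(self.perm_null.mean()),
                perm_null_sd=float(self.perm_null.std()),
            )
        if self.em_null is not None:
            out.update(
                p_em=self.p_em,
                n_sim=int(self.em_null.size),
                em_null_mean=float(self.em_null.mean()),
                em_null_sd=float(self.em_null.std()),
                n_dropped=self.n_dropped,
            )
        out.update(self.extra)
        return out


def conventional_mantel(d_phylo, d_trait, n_perm: int = 9_999, seed=0) -> MantelResult:
    """Mantel test with a label-permutation null.

    Taxon labels of the trait matrix are jointly permuted over rows and
    columns ``n_perm`` times; the two-sided p-value doubles the smaller of
    the add-one-corrected tail probabilities.
    """
    if n_perm < 99:
        raise InvalidParameterError("n_perm must be >= 99")
    d_phylo, d_trait = np.asarray(d_phylo, float), np.asarray(d_trait, float)
    r_emp = mantel_statistic(d_phylo, d_trait)
    n = d_phylo.shape[0]
    rng = np.random.default_rng(seed)
    z1 = _standardize(_upper(d_phylo))
    null = np.empty(n_perm)
    for i in range(n_perm):
        p = rng.permutation(n)
        null[i] = z1 @ _standardize(_upper(d_trait[np.ix_(p, p)])) / z1.size
    p_two, p_pos, p_neg = _two_sided_p(r_emp, null)
    return MantelResult(
        r=r_emp,
        n_taxa=n,
        seed=seed,
        perm_null=null,
        p_perm=p_two,
        extra={"p_perm_pos": p_pos, "p_perm_neg": p_neg},
    )


def em_mantel(
    tree,
    tip_state_sets: dict,
    fitted_model: MkModel,
    root_state: int,
    n_sim: int = 9_999,
    seed=0,
    d_phylo: np.ndarray | None = None,
) -> MantelResult:
    """Mantel test against a neutral-evolution null.

    Each replicate simulates the character on ``tree`` under
    ``fitted_model`` (typically posterior-mean rates and the MAP root state
    from the Bayesian analysis), converts tips to singleton state sets and
    recomputes the Mantel correlation with the phylogenetic distances.
    Zero-variance simulated trait matrices (all tips identical) are dropped
    with a warning.
    """
    if n_sim < 1:
        raise InvalidParameterError("n_sim must be >= 1")
    if fitted_model.rate_model != "ER":
        raise InvalidParameterError("EM-Mantel null simulation supports the ER model")
    if not 0 <= root_state < fitted_model.k:
        raise InvalidParameterError(f"root_state {root_state} out of range")
    arrays = tree if isinstance(tree, TreeArrays) else TreeArrays.from_tree(tree)
    labels = arrays.taxon_labels
    observed = {lbl for lbl, ss in tip_state_sets.items() if ss}
    if observed != set(labels):
        raise InputError("tip_state_sets must cover exactly the tree's tips (drop missing first)")
    if d_phylo is None:
        d_phylo = arrays.patristic_matrix()
    d_trait = bray_curtis_matrix(labels, tip_state_sets)
    r_emp = mantel_statistic(d_phylo, d_trait)

    seed = int(np.random.SeedSequence(seed).generate_state(1)[0] >> 1)
    P = er_transition_matrices(fitted_model.k, float(fitted_model.rates[0]), arrays.edge_len)
    sims = _simulate_states(
        arrays.child_list, arrays.child_start, arrays.child_count, P, root_state, n_sim, seed
    )
    tip_states = sims[:, arrays.tip_node]  # (n_sim, n_tips)
    iu = np.triu_indices(len(labels), 1)
    z1 = _standardize(_upper(np.asarray(d_phylo, float)))
    mism = (tip_states[:, iu[0]] != tip_states[:, iu[1]]).astype(np.float64)
    sd = mism.std(axis=1)
    keep = sd > 0
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped}/{n_sim} zero-variance simulated replicates",
            DroppedReplicateWarning,
        )
    mism = mism[keep]
    null = ((mism - mism.mean(axis=1, keepdims=True)) / mism.std(axis=1, keepdims=True)) @ z1 / z1.size
    if null.size == 0:
        raise UndefinedStatisticError("all simulated replicates had zero variance")
    p_two, p_pos, p_neg = _two_sided_p(r_emp, null)
    return MantelResult(
        r=r_emp,
        n_taxa=len(labels),
        seed=seed,
        em_null=null,
        p_em=p_two,
        n_dropped=n_dropped,
        extra={"p_em_pos": p_pos, "p_em_neg": p_neg},
    )


def signal_report(results: dict[tuple[str, str], MantelResult]) -> pd.DataFrame:
    """One row per (character, subset) with r, p-values and null summaries."""
    if not results:
        raise InvalidParameterError("no Mantel results to report")
    rows = []
    for (character, subset), res in results.items():
        row = {"character": character, "subset": subset, "r": res.r, "n_taxa": res.n_taxa}
        if res.perm_null is not None:
            row["p_perm"] = res.p_perm
            row["perm_null_mean"] = float(res.perm_null.mean())
        if res.em_null is not None:
            row["p_em"] = res.p_em
            row["em_null_mean"] = float(res.em_null.mean())
        rows.append(row)
    return pd.DataFrame(rows)


def plot_null_histogram(result: MantelResult, path, title: str = "") -> None:
    """Histogram(s) of the null Mantel coefficients with the empirical r."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    if result.perm_null is not None:
        ax.hist(result.perm_null, bins=40, alpha=0.6, color="tab:red", label="permutation null")
    if result.em_null is not None:
        ax.hist(result.em_null, bins=40, alpha=0.6, color="tab:blue", label="evolutionary-model null")
    ax.axvline(result.r, color="black", lw=2, label=f"empirical r = {result.r:.3f}")
    ax.set_xlabel("Mantel r")
    ax.set_ylabel("count")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
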