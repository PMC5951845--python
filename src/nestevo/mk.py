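"""k-state Markov (Mk) model machinery for discrete characters on trees.

Covers the Bayesian workflow used for nest-character evolution: the
equal-rates (ER) / all-rates-different (ARD) continuous-time Markov model,
Felsenstein-pruning likelihoods with polymorphic and missing tips,
Metropolis-Hastings sampling of rates jointly with a tree index drawn from
a tree set, effective-sample-size and split R-hat diagnostics, marginal
ancestral-state reconstruction, and majority-rule consensus trees with
least-squares branch lengths.

Rates are expected transitions per unit branch length.  The prior on every
rate is exponential; tree uncertainty is integrated over by proposing, at
each iteration, a tree drawn uniformly from the supplied tree set and
accepting it by the Metropolis-Hastings ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from ._pruning import (
    QEigenPropagator,
    _node_marginals,
    _pruning_loglik,
    er_transition_matrices,
    tip_partials_template,
)
from .errors import (
    AbsentCladeError,
    InputError,
    InsufficientChainsError,
    InvalidParameterError,
    MissingTaxonError,
    TuningWarning,
    UndefinedStatisticError,
)
from .trees import TreeArrays, common_taxon_order

__all__ = [
    "MkModel",
    "MCMCConfig",
    "MCMCTrace",
    "AncestralReconstruction",
    "transition_probability",
    "tree_log_likelihood",
    "mcmc_sample",
    "effective_sample_size",
    "split_rhat",
    "convergence_diagnostic",
    "reconstruct_ancestral_states",
    "consensus_tree",
]


@dataclass
class MkModel:
    """k-state Markov model with an equal-rates or all-rates-different
    parameterisation and a root-state prior (uniform by default)."""

    k: int
    rate_model: str = "ER"
    rates: np.ndarray | float = 0.1
    root_prior: np.ndarray | None = None

    def __post_init__(self):
        if self.k < 2:
            raise InvalidParameterError("k must be >= 2")
        if self.rate_model not in ("ER", "ARD"):
            raise InvalidParameterError("rate_model must be 'ER' or 'ARD'")
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=np.float64))
        n_expected = 1 if self.rate_model == "ER" else self.k * (self.k - 1)
        if self.rates.size != n_expected:
            raise InvalidParameterError(
                f"{self.rate_model} model with k={self.k} needs {n_expected} rate(s)"
            )
        if np.any(self.rates < 0):
            raise InvalidParameterError("rates must be non-negative")
        if self.root_prior is None:
            self.root_prior = np.full(self.k, 1.0 / self.k)
        else:
            self.root_prior = np.asarray(self.root_prior, dtype=np.float64)
            if self.root_prior.size != self.k or not np.isclose(self.root_prior.sum(), 1.0):
                raise InvalidParameterError("root_prior must be a length-k probability vector")

    def rate_matrix(self) -> np.ndarray:
        """The k x k generator Q (off-diagonal rates, rows sum to zero)."""
        Q = np.zeros((self.k, self.k))
        if self.rate_model == "ER":
            Q[:] = self.rates[0]
        else:
            idx = 0
            for i in range(self.k):
                for j in range(self.k):
                    if i != j:
                        Q[i, j] = self.rates[idx]
                        idx += 1
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q


def transition_probability(model: MkModel, t: float) -> np.ndarray:
    """Stochastic matrix P(t) = exp(Q t).

    The ER case uses the closed form
    ``P_same = 1/k + (k-1)/k * exp(-k q t)``; ARD uses the matrix
    exponential via eigendecomposition.
    """
    if t < 0:
        raise InvalidParameterError("branch length t must be >= 0")
    if model.rate_model == "ER":
        return er_transition_matrices(model.k, float(model.rates[0]), np.array([t]))[0]
    return QEigenPropagator(model.rate_matrix()).matrices(np.array([t]))[0]


# --------------------------------------------------------------------------
# Likelihood over a tree set
# --------------------------------------------------------------------------


def _align_state_sets(taxon_order, tip_state_sets) -> list:
    out = []
    for label in taxon_order:
        if label not in tip_state_sets:
            raise MissingTaxonError(f"tip {label!r} has no record in the character data")
        out.append(tip_state_sets[label])
    return out


class TreeSetLikelihood:
    """Pruning log-likelihood evaluator over a fixed set of trees.

    ``q_builder`` maps a rate vector to a generator matrix; when it is None
    the equal-rates closed form is used and the rate vector has length 1.
    """

    def __init__(self, tree_set, tip_state_sets, k, q_builder=None, root_prior=None):
        if isinstance(tree_set, (dendropy.Tree, TreeArrays)):
            tree_set = [tree_set]
        if isinstance(tree_set[0], TreeArrays):
            self.arrays = list(tree_set)
            order = self.arrays[0].taxon_labels
            for a in self.arrays[1:]:
                if a.taxon_labels != order:
                    raise InputError("tree set taxon orders differ")
        else:
            order = common_taxon_order(tree_set)
            self.arrays = [TreeArrays.from_tree(t, taxon_order=order) for t in tree_set]
        self.taxon_order = order
        self.k = k
        self.q_builder = q_builder
        self.root_prior = (
            np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior, float)
        )
        states = _align_state_sets(order, tip_state_sets)
        self.partials = [tip_partials_template(a, states, k) for a in self.arrays]
        self._prop_cache: tuple[bytes, QEigenPropagator] | None = None

    @property
    def n_trees(self) -> int:
        return len(self.arrays)

    def _propagator(self, rates: np.ndarray) -> QEigenPropagator:
        key = rates.tobytes()
        if self._prop_cache is None or self._prop_cache[0] != key:
            self._prop_cache = (key, QEigenPropagator(self.q_builder(rates)))
        return self._prop_cache[1]

    def transition_matrices(self, rates: np.ndarray, tree_idx: int) -> np.ndarray:
        a = self.arrays[tree_idx]
        if self.q_builder is None:
            return er_transition_matrices(self.k, float(rates[0]), a.edge_len)
        return self._propagator(rates).matrices(a.edge_len)

    def loglik(self, rates: np.ndarray, tree_idx: int) -> float:
        a = self.arrays[tree_idx]
        P = self.transition_matrices(rates, tree_idx)
        return float(
            _pruning_loglik(
                a.child_list, a.child_start, a.child_count, P, self.partials[tree_idx], self.root_prior
            )
        )

    def node_marginals(self, rates: np.ndarray, tree_idx: int) -> np.ndarray:
        a = self.arrays[tree_idx]
        P = self.transition_matrices(rates, tree_idx)
        buf = self.partials[tree_idx]
        _pruning_loglik(a.child_list, a.child_start, a.child_count, P, buf, self.root_prior)
        return _node_marginals(
            a.child_list, a.child_start, a.child_count, a.parent, P, buf, self.root_prior
        )


def tree_log_likelihood(tree, tip_state_sets, model: MkModel) -> float:
    """Pruning log-likelihood of set-valued tip data under ``model``.

    Polymorphic tips enter as indicator vectors with 1 on each observed
    state; missing tips (None or empty set) as all-ones vectors.
    """
    q_builder = None if model.rate_model == "ER" else (lambda r, m=model: replace(m, rates=r).rate_matrix())
    ev = TreeSetLikelihood(tree, tip_state_sets, model.k, q_builder=q_builder, root_prior=model.root_prior)
    return ev.loglik(model.rates, 0)


# --------------------------------------------------------------------------
# MCMC
# --------------------------------------------------------------------------


@dataclass
class MCMCConfig:
    """Sampler configuration.

    Desk-scale defaults keep a single analysis in the seconds-to-minutes
    range; ``published_profile`` returns the published run lengths (20M
    iterations, 2M burn-in, thinning 10,000).
    """

    n_iter: int = 50_000
    burn_in: int = 10_000
    thin: int = 20
    prior_mean: float = 0.1
    target_accept_low: float = 0.2
    target_accept_high: float = 0.4
    n_chains: int = 3
    seed: int = 0
    tune_interval: int = 100

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise InvalidParameterError("require 0 <= burn_in < n_iter")
        if not 0 < self.target_accept_low < self.target_accept_high < 1:
            raise InvalidParameterError("acceptance band must satisfy 0 < low < high < 1")
        if self.prior_mean <= 0:
            raise InvalidParameterError("prior_mean must be > 0")

    @classmethod
    def published_profile(cls, **kw) -> "MCMCConfig":
        base = dict(n_iter=20_000_000, burn_in=2_000_000, thin=10_000, n_chains=3)
        base.update(kw)
        return cls(**base)


@dataclass
class MCMCTrace:
    """Retained posterior samples plus sampler bookkeeping."""

    rates: np.ndarray  # (n_samples, n_rates)
    loglik: np.ndarray
    tree_index: np.ndarray
    chain_id: np.ndarray
    rate_names: list[str]
    acceptance: list[dict]  # per chain: post-burn-in acceptance fractions
    tuning_history: list[list[tuple[int, float, float]]]  # (iter, window, accept)
    config: MCMCConfig
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.loglik)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rates, columns=self.rate_names)
        df.insert(0, "chain", self.chain_id)
        df["loglik"] = self.loglik
        df["tree_index"] = self.tree_index
        return df

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def rates_by_chain(self, name: str) -> list[np.ndarray]:
        j = self.rate_names.index(name)
        return [self.rates[self.chain_id == c, j] for c in np.unique(self.chain_id)]

    def posterior_mean(self) -> dict[str, float]:
        """Posterior mean of every rate, averaged across chains."""
        return {n: float(self.rates[:, j].mean()) for j, n in enumerate(self.rate_names)}

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        j = self.rate_names.index(name)
        lo = (1 - level) / 2
        return tuple(np.quantile(self.rates[:, j], [lo, 1 - lo]))


def _run_chains(evaluator, n_rates, rate_names, config, init_rates=None, meta=None, beta=1.0) -> MCMCTrace:
    """Shared Metropolis-Hastings driver: sliding-window proposals on
    log-rates (tuned to the target acceptance band during burn-in, frozen
    afterwards) plus a uniform tree-index proposal each iteration.

    ``beta`` tempers the likelihood (power posterior L^beta * prior); the
    recorded ``loglik`` column is always the untempered likelihood."""
    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.n_chains)
    n_keep = (config.n_iter - config.burn_in) // config.thin
    all_rates, all_ll, all_tree, all_chain = [], [], [], []
    acceptance, tuning_all = [], []
    m = config.prior_mean
    for chain, cs in enumerate(chain_seeds):
        rng = np.random.default_rng(cs)
        if init_rates is None:
            logq = np.log(rng.exponential(m, size=n_rates))
        else:
            logq = np.log(np.maximum(np.asarray(init_rates, float), 1e-12))
        tree_idx = int(rng.integers(evaluator.n_trees))
        ll = evaluator.loglik(np.exp(logq), tree_idx)
        w = 1.0
        tune_acc = tune_tot = 0
        post_acc = post_tot = 0
        tree_acc = tree_tot = 0
        tuning: list[tuple[int, float, float]] = []
        keep_r = np.empty((n_keep, n_rates))
        keep_ll = np.empty(n_keep)
        keep_t = np.empty(n_keep, dtype=np.int64)
        kept = 0
        for it in range(config.n_iter):
            j = int(rng.integers(n_rates)) if n_rates > 1 else 0
            step = rng.uniform(-w, w)
            prop = logq.copy()
            prop[j] += step
            ll_new = evaluator.loglik(np.exp(prop), tree_idx)
            # exponential prior on q plus the log-transform Jacobian q
            log_alpha = beta * (ll_new - ll) + (-(np.exp(prop[j]) - np.exp(logq[j])) / m) + step
            accept = np.log(rng.random()) < log_alpha
            if accept:
                logq, ll = prop, ll_new
            if it < config.burn_in:
                tune_acc += accept
                tune_tot += 1
                if (it + 1) % config.tune_interval == 0:
                    frac = tune_acc / tune_tot
                    if frac > config.target_accept_high:
                        w *= 1.25
                    elif frac < config.target_accept_low:
                        w /= 1.25
                    tuning.append((it + 1, w, frac))
                    tune_acc = tune_tot = 0
            else:
                post_acc += accept
                post_tot += 1
            if evaluator.n_trees > 1:
                t_prop = int(rng.integers(evaluator.n_trees))
                if t_prop != tree_idx:
                    ll_new = evaluator.loglik(np.exp(logq), t_prop)
                    if np.log(rng.random()) < beta * (ll_new - ll):
                        tree_idx, ll = t_prop, ll_new
                        if it >= config.burn_in:
                            tree_acc += 1
                    if it >= config.burn_in:
                        tree_tot += 1
            if it >= config.burn_in and (it - config.burn_in) % config.thin == config.thin - 1:
                keep_r[kept] = np.exp(logq)
                keep_ll[kept] = ll
                keep_t[kept] = tree_idx
                kept += 1
        rate_frac = post_acc / max(post_tot, 1)
        if not config.target_accept_low <= rate_frac <= config.target_accept_high:
            warnings.warn(
                f"chain {chain}: post-burn-in acceptance {rate_frac:.3f} outside "
                f"[{config.target_accept_low}, {config.target_accept_high}]",
                TuningWarning,
            )
        acceptance.append(
            {"rate": rate_frac, "tree": tree_acc / max(tree_tot, 1), "window": w}
        )
        tuning_all.append(tuning)
        all_rates.append(keep_r[:kept])
        all_ll.append(keep_ll[:kept])
        all_tree.append(keep_t[:kept])
        all_chain.append(np.full(kept, chain, dtype=np.int64))
    return MCMCTrace(
        rates=np.concatenate(all_rates),
        loglik=np.concatenate(all_ll),
        tree_index=np.concatenate(all_tree),
        chain_id=np.concatenate(all_chain),
        rate_names=list(rate_names),
        acceptance=acceptance,
        tuning_history=tuning_all,
        config=config,
        meta=meta or {},
    )


def mcmc_sample(tree_set, tip_state_sets, model_spec: MkModel, config: MCMCConfig | None = None) -> MCMCTrace:
    """Posterior sample of Mk transition rates over a tree set.

    ``tip_state_sets`` maps each tip label to a set of state indices (a
    singleton for monomorphic tips, several states for polymorphic families,
    None/empty for missing data).  The tree index is a sampled parameter:
    each iteration proposes replacing the current tree with one drawn
    uniformly from ``tree_set``.
    """
    config = config or MCMCConfig()
    if model_spec.rate_model == "ER":
        ev = TreeSetLikelihood(tree_set, tip_state_sets, model_spec.k, root_prior=model_spec.root_prior)
        names = ["q"]
    else:
        def q_builder(r, m=model_spec):
            return replace(m, rates=r).rate_matrix()

        ev = TreeSetLikelihood(
            tree_set, tip_state_sets, model_spec.k, q_builder=q_builder, root_prior=model_spec.root_prior
        )
        names = [f"q{i}{j}" for i in range(model_spec.k) for j in range(model_spec.k) if i != j]
    meta = {
        "k": model_spec.k,
        "rate_model": model_spec.rate_model,
        "root_prior": np.asarray(model_spec.root_prior).tolist(),
    }
    return _run_chains(ev, len(names), names, config, meta=meta)


# --------------------------------------------------------------------------
# Diagnostics
# --------------------------------------------------------------------------


def effective_sample_size(series) -> float:
    """ESS by Geyer's initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(series, dtype=np.float64)
    n = x.size
    if n < 10:
        raise InvalidParameterError("series too short for an ESS estimate (need >= 10)")
    if np.var(x) == 0:
        raise UndefinedStatisticError("ESS undefined for a zero-variance series")
    xc = x - x.mean()
    nf = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nf)
    acov = np.fft.irfft(f * np.conj(f), nf)[:n].real / n
    rho = acov / acov[0]
    tau = 0.0
    prev = np.inf
    mth = 0
    while 2 * mth + 1 < n:
        g = rho[2 * mth] + rho[2 * mth + 1]
        if g <= 0:
            break
        g = min(g, prev)  # enforce monotonicity of the pair sums
        tau += g
        prev = g
        mth += 1
    ess = n / max(2.0 * tau - 1.0, 1.0)
    return float(min(ess, n))


def split_rhat(chains) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    ``chains``: sequence of >= 2 same-length 1-D sample arrays.
    """
    chains = [np.asarray(c, dtype=np.float64) for c in chains]
    if len(chains) < 2:
        raise InsufficientChainsError("split R-hat needs at least two chains")
    n = min(len(c) for c in chains)
    halves = []
    for c in chains:
        c = c[:n]
        halves.append(c[: n // 2])
        halves.append(c[n // 2 : 2 * (n // 2)])
    m = len(halves)
    n2 = len(halves[0])
    means = np.array([h.mean() for h in halves])
    variances = np.array([h.var(ddof=1) for h in halves])
    W = variances.mean()
    if W == 0:
        raise UndefinedStatisticError("R-hat undefined: zero within-chain variance")
    B = n2 * means.var(ddof=1)
    var_hat = (n2 - 1) / n2 * W + B / n2
    return float(np.sqrt(var_hat / W))


def convergence_diagnostic(trace: MCMCTrace) -> dict[str, float]:
    """Split R-hat for every sampled rate, computed across chains."""
    if len(np.unique(trace.chain_id)) < 2:
        raise InsufficientChainsError("convergence diagnostic needs >= 2 chains")
    return {name: split_rhat(trace.rates_by_chain(name)) for name in trace.rate_names}


# --------------------------------------------------------------------------
# Ancestral-state reconstruction
# --------------------------------------------------------------------------


@dataclass
class AncestralReconstruction:
    """Posterior state probabilities per monitored clade.

    A clade is identified by its tip-label set; ``support`` is the fraction
    of posterior samples whose tree contains that clade, and the posterior
    vector is averaged over exactly those samples.
    """

    clades: list[frozenset[str]]
    support: np.ndarray
    posterior: np.ndarray  # (n_clades, k)
    state_labels: list[str] | None = None

    def map_state(self, clade: frozenset[str]) -> int:
        i = self.clades.index(frozenset(clade))
        return int(np.argmax(self.posterior[i]))

    def root_posterior(self) -> np.ndarray:
        sizes = [len(c) for c in self.clades]
        return self.posterior[int(np.argmax(sizes))]

    def to_dataframe(self) -> pd.DataFrame:
        k = self.posterior.shape[1]
        cols = self.state_labels or [f"state_{i}" for i in range(k)]
        df = pd.DataFrame(self.posterior, columns=[f"p_{c}" for c in cols])
        df.insert(0, "support", self.support)
        df.insert(0, "n_tips", [len(c) for c in self.clades])
        df.insert(0, "clade", ["|".join(sorted(c)) for c in self.clades])
        return df

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def reconstruct_ancestral_states(
    trace: MCMCTrace,
    tree_set,
    tip_state_sets,
    clades: list[frozenset[str]] | None = None,
    state_labels: list[str] | None = None,
) -> AncestralReconstruction:
    """Marginal ancestral states at monitored clades, averaged over the
    posterior sample.

    For each retained sample the marginal state probabilities are computed
    (up-down pass) at the MRCA of every monitored tip set on that sample's
    tree; a clade contributes only when it is monophyletic there.  Default
    monitored clades are those of the majority-rule consensus of
    ``tree_set``.
    """
    k = trace.meta.get("k")
    if k is None:
        raise InputError("trace lacks model metadata; was it produced by mcmc_sample?")
    if trace.meta.get("rate_model") == "ER":
        ev = TreeSetLikelihood(tree_set, tip_state_sets, k, root_prior=np.asarray(trace.meta["root_prior"]))
    else:
        model = MkModel(k=k, rate_model="ARD", rates=np.ones(k * (k - 1)))

        def q_builder(r, m=model):
            return replace(m, rates=r).rate_matrix()

        ev = TreeSetLikelihood(
            tree_set, tip_state_sets, k, q_builder=q_builder, root_prior=np.asarray(trace.meta["root_prior"])
        )
    order = ev.taxon_order
    tix = {label: i for i, label in enumerate(order)}
    if clades is None:
        cons = consensus_tree(tree_set)
        ca = TreeArrays.from_tree(cons, taxon_order=order)
        clades = [
            frozenset(order[i] for i in cl) for cl in ca.clusters() if len(cl) >= 2
        ]
    clade_idx = [frozenset(tix[t] for t in c) for c in clades]
    cluster_maps = [a.clusters() for a in ev.arrays]
    n_clades = len(clades)
    acc = np.zeros((n_clades, k))
    counts = np.zeros(n_clades)
    for s in range(trace.n_samples):
        ti = int(trace.tree_index[s])
        marg = ev.node_marginals(trace.rates[s], ti)
        cm = cluster_maps[ti]
        for ci, cl in enumerate(clade_idx):
            node = cm.get(cl)
            if node is not None:
                acc[ci] += marg[node]
                counts[ci] += 1
    absent = counts == 0
    if np.any(absent):
        bad = [sorted(clades[i]) for i in np.nonzero(absent)[0]]
        raise AbsentCladeError(f"clades never present in any sampled tree: {bad[:3]}")
    posterior = acc / counts[:, None]
    return AncestralReconstruction(
        clades=list(clades),
        support=counts / trace.n_samples,
        posterior=posterior,
        state_labels=state_labels,
    )


# --------------------------------------------------------------------------
# Consensus tree
# --------------------------------------------------------------------------


def consensus_tree(tree_set, min_freq: float = 0.5) -> dendropy.Tree:
    """Majority-rule consensus with least-squares branch lengths.

    Clades present in strictly more than ``min_freq`` of the trees are
    retained; branch lengths are fit by unweighted least squares to the mean
    patristic distance matrix of the set, constrained non-negative.  Clade
    frequencies are stored as internal-node ``support`` annotations.
    """
    trees = list(tree_set)
    if len(trees) == 0:
        raise InputError("empty tree set")
    order = common_taxon_order(trees) if not isinstance(trees[0], TreeArrays) else trees[0].taxon_labels
    arrays = [
        t if isinstance(t, TreeArrays) else TreeArrays.from_tree(t, taxon_order=order) for t in trees
    ]
    n = len(order)
    counts: dict[frozenset[int], int] = {}
    for a in arrays:
        for cl in a.clusters():
            counts[cl] = counts.get(cl, 0) + 1
    total = len(arrays)
    kept = {cl: c / total for cl, c in counts.items() if c / total > min_freq}
    full = frozenset(range(n))
    for i in range(n):
        kept.setdefault(frozenset({i}), 1.0)
    kept.setdefault(full, 1.0)

    # nest compatible majority clades, largest first
    ordered = sorted(kept, key=len, reverse=True)
    taxa = dendropy.TaxonNamespace(order)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    node_of: dict[frozenset[int], dendropy.Node] = {full: tree.seed_node}
    tree.seed_node.support = kept[full]
    for cl in ordered:
        if cl == full:
            continue
        parent = min(
            (p for p in node_of if cl < p), key=len
        )  # smallest strict superset already placed
        nd = dendropy.Node()
        nd.support = kept[cl]
        if len(cl) == 1:
            nd.taxon = taxa.get_taxon(order[next(iter(cl))])
        else:
            nd.label = f"{kept[cl]:.3f}"
        node_of[parent].add_child(nd)
        node_of[cl] = nd

    # least-squares branch lengths against the mean patristic matrix
    mean_d = np.mean([a.patristic_matrix() for a in arrays], axis=0)
    iu = np.triu_indices(n, 1)
    edges = [cl for cl in node_of if cl != full]
    member = np.zeros((len(edges), n), dtype=bool)
    for e, cl in enumerate(edges):
        member[e, list(cl)] = True
    A = (member[:, iu[0]] ^ member[:, iu[1]]).T.astype(np.float64)
    target = mean_d[iu]
    x, *_ = np.linalg.lstsq(A, target, rcond=None)
    if np.any(x < -1e-9):
        res = lsq_linear(A, target, bounds=(0.0, np.inf), method="bvls" if A.shape[1] <= 200 else "trf")
        x = res.x
    x = np.clip(x, 0.0, None)
    for e, cl in enumerate(edges):
        node_of[cl].edge.length = float(x[e])
    tree.seed_node.edge.length = None
    return tree
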