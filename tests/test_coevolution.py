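import numpy as np
import pytest

from nestevo.coevolution import (
    BayesFactorResult,
    INDEPENDENT_RATE_NAMES,
    bayes_factor,
    compare_models,
    fit_pagel_model,
    independent_rate_matrix,
    joint_state_sets,
    log_marginal_by_chain,
    log_marginal_harmonic_mean,
    log_marginal_stepping_stone,
    transition_asymmetry,
)
from nestevo.errors import (
    DegenerateTraitWarning,
    InsufficientSamplesError,
    NestevoError,
    WrongModelError,
)
from nestevo.mk import MCMCConfig, MkModel, TreeSetLikelihood, tree_log_likelihood
from nestevo.simulate import (
    STRONG_DEPENDENCE_RATES,
    simulate_correlated_binary_pair,
    simulate_yule_tree,
)
from nestevo.trees import TreeArrays

from conftest import random_tree


class TestJointLikelihood:
    @pytest.mark.parametrize("seed", range(6))
    def test_context_free_joint_equals_product_of_binary_likelihoods(self, seed):
        # with no contingency the 4-state pruning likelihood factorises
        # into the two single-trait binary (ARD) likelihoods
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, int(rng.integers(4, 7)))
        arrays = TreeArrays.from_tree(tree)
        a_gain, a_loss, b_gain, b_loss = rng.uniform(0.05, 0.8, size=4)
        tips_a = {t: int(rng.integers(2)) for t in arrays.taxon_labels}
        tips_b = {t: int(rng.integers(2)) for t in arrays.taxon_labels}
        joint = {t: frozenset({2 * tips_a[t] + tips_b[t]}) for t in arrays.taxon_labels}
        ev = TreeSetLikelihood(tree, joint, 4, q_builder=independent_rate_matrix)
        ll_joint = ev.loglik(np.array([a_gain, a_loss, b_gain, b_loss]), 0)
        ll_a = tree_log_likelihood(
            tree, {t: {v} for t, v in tips_a.items()}, MkModel(k=2, rate_model="ARD", rates=[a_gain, a_loss])
        )
        ll_b = tree_log_likelihood(
            tree, {t: {v} for t, v in tips_b.items()}, MkModel(k=2, rate_model="ARD", rates=[b_gain, b_loss])
        )
        assert ll_joint == pytest.approx(ll_a + ll_b, abs=1e-8)

    def test_joint_state_sets_handles_partial_missingness(self):
        a = {"x": "d", "y": None, "z": "a"}
        b = {"x": "a", "y": "d", "z": None}
        with pytest.warns(DegenerateTraitWarning):
            # trait a in {d, a} is fine; use a degenerate second trait to
            # check both the encoding and the warning
            joint = joint_state_sets(a, {"x": "d", "y": "d", "z": "d"}, "d", "d")
        assert joint["x"] == frozenset({3})
        joint = joint_state_sets(a, b, "d", "d")
        assert joint["y"] == frozenset({1, 3})  # A unknown, B derived
        assert joint["z"] == frozenset({0, 1})  # A ancestral, B unknown

    def test_fully_missing_tip_is_none(self):
        joint = joint_state_sets({"x": None, "y": "d"}, {"x": None, "y": "a"}, "d", "a")
        assert joint["x"] is None


class TestHarmonicMean:
    def test_constant_trace_returns_the_constant(self):
        assert log_marginal_harmonic_mean(np.full(200, -12.5)) == pytest.approx(-12.5)

    def test_two_point_hand_computation(self):
        # harmonic mean of {1, 1/3} is 2/(1+3) = 1/2
        ll = np.concatenate([np.zeros(100), np.full(100, np.log(1 / 3))])
        assert log_marginal_harmonic_mean(ll) == pytest.approx(np.log(0.5))

    def test_log_translation_equivariance(self):
        rng = np.random.default_rng(0)
        ll = rng.normal(-50, 3, size=500)
        assert log_marginal_harmonic_mean(ll - 10_000) == pytest.approx(
            log_marginal_harmonic_mean(ll) - 10_000, abs=1e-8
        )

    def test_bounded_by_max_sampled_loglik(self):
        rng = np.random.default_rng(1)
        ll = rng.normal(-30, 2, size=1000)
        assert log_marginal_harmonic_mean(ll) <= ll.max()

    def test_insufficient_samples_rejected(self):
        with pytest.raises(InsufficientSamplesError):
            log_marginal_harmonic_mean(np.zeros(10))


class TestBayesFactor:
    def test_equal_marginals_not_strong(self):
        res = bayes_factor(-100.0, -100.0)
        assert res.bf == 0 and res.support_call == "none"

    def test_three_log_units_is_strong(self):
        res = bayes_factor(-100.0, -103.0)
        assert res.bf == pytest.approx(6.0) and res.support_call == "strong"

    def test_antisymmetry_under_model_swap(self):
        a, b = -120.3, -117.9
        assert bayes_factor(a, b).bf == pytest.approx(-bayes_factor(b, a).bf)

    def test_non_finite_rejected(self):
        with pytest.raises(NestevoError):
            bayes_factor(float("nan"), -1.0)


@pytest.fixture(scope="module")
def dependent_fit():
    """Dependent-model fit on data where B gains only while A is derived."""
    tree = simulate_yule_tree(150, 1.0, 901)
    pair = simulate_correlated_binary_pair(tree, STRONG_DEPENDENCE_RATES, (0, 0), 902)
    joint = joint_state_sets(
        {t: "d" if v[0] else "a" for t, v in pair.items()},
        {t: "d" if v[1] else "a" for t, v in pair.items()},
        "d",
        "d",
    )
    cfg = MCMCConfig(n_iter=8_000, burn_in=3_000, thin=5, n_chains=2, seed=903)
    return tree, joint, fit_pagel_model([tree], joint, "dependent", cfg)


class TestPagelFit:
    def test_acceptance_in_band(self, dependent_fit):
        _, _, trace = dependent_fit
        for chain in trace.acceptance:
            assert 0.20 <= chain["rate"] <= 0.40

    def test_planted_asymmetry_recovered(self, dependent_fit):
        _, _, trace = dependent_fit
        asym = transition_asymmetry(trace)
        assert asym["orderings"]["p_b_gain_faster_when_a_derived"] > 0.9
        assert all(v["mean"] >= 0 for v in asym["rates"].values())

    def test_wrong_model_trace_rejected(self, dependent_fit):
        tree, joint, _ = dependent_fit
        cfg = MCMCConfig(n_iter=2_000, burn_in=500, thin=5, n_chains=1, seed=904)
        indep = fit_pagel_model([tree], joint, "independent", cfg)
        assert indep.rate_names == INDEPENDENT_RATE_NAMES
        with pytest.raises(WrongModelError):
            transition_asymmetry(indep)

    def test_degenerate_trait_warns(self, yule50):
        labels = [f"t{i+1}" for i in range(50)]
        a = {t: "d" for t in labels}
        b = {t: ("d" if i % 2 else "a") for i, t in enumerate(labels)}
        with pytest.warns(DegenerateTraitWarning):
            joint_state_sets(a, b, "d", "d")

    def test_strong_dependence_supported_over_independence(self, dependent_fit):
        tree, joint, _ = dependent_fit
        cfg = MCMCConfig(n_iter=8_000, burn_in=3_000, thin=5, n_chains=2, seed=905)
        res, dep, indep = compare_models([tree], joint, cfg)
        assert res.bf > 0
        assert len(log_marginal_by_chain(dep)) == 2

    def test_stepping_stone_exact_on_flat_likelihood(self, dependent_fit):
        # with every tip missing the likelihood is identically 1, so the
        # marginal likelihood is exactly 1 regardless of the prior
        tree, _, _ = dependent_fit
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        empty = {t: None for t in labels}
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            cfg = MCMCConfig(n_iter=1_500, burn_in=500, thin=5, n_chains=1, seed=906)
            ss = log_marginal_stepping_stone([tree], empty, "dependent", cfg, n_steps=3)
        assert ss == pytest.approx(0.0, abs=1e-12)

    def test_stepping_stone_bounded_by_max_likelihood(self, dependent_fit):
        tree, joint, trace = dependent_fit
        cfg = MCMCConfig(n_iter=2_000, burn_in=800, thin=5, n_chains=1, seed=907)
        ss = log_marginal_stepping_stone([tree], joint, "dependent", cfg, n_steps=4)
        assert np.isfinite(ss)
        assert ss < trace.loglik.max()
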