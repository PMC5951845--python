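import numpy as np
import pytest
from dendropy.calculate import treecompare
from scipy.linalg import expm
from scipy.stats import chisquare

from nestevo.errors import InvalidParameterError
from nestevo.mk import MkModel
from nestevo.simulate import (
    SimulationConfig,
    dependent_rate_matrix,
    perturb_tree_set,
    simulate_correlated_binary_pair,
    simulate_discrete_trait,
    simulate_polymorphic_tipset,
    simulate_yule_tree,
)
from nestevo.trees import TreeArrays

from conftest import tree_from_newick


class TestYule:
    def test_two_tip_cherry_is_ultrametric(self):
        t = simulate_yule_tree(2, 1.0, 1)
        lengths = [leaf.edge.length for leaf in t.leaf_node_iter()]
        assert len(lengths) == 2 and lengths[0] == pytest.approx(lengths[1])

    def test_ultrametric_and_labelled(self):
        a = TreeArrays.from_tree(simulate_yule_tree(50, 1.0, 2))
        depths = a.tip_depths()
        assert np.ptp(depths) < 1e-9
        assert len(set(a.taxon_labels)) == 50
        assert np.all(a.edge_len[:-1] > 0)

    def test_mean_height_matches_yule_expectation(self):
        heights = [
            TreeArrays.from_tree(simulate_yule_tree(50, 1.0, s)).tip_depths()[0]
            for s in range(500)
        ]
        expected = sum(1.0 / m for m in range(2, 51))
        se = np.std(heights) / np.sqrt(len(heights))
        assert abs(np.mean(heights) - expected) < 3 * se

    @pytest.mark.parametrize("n_tips,rate", [(1, 1.0), (5, 0.0), (5, -1.0)])
    def test_invalid_parameters(self, n_tips, rate):
        with pytest.raises(InvalidParameterError):
            simulate_yule_tree(n_tips, rate, 0)

    def test_determinism(self):
        a = simulate_yule_tree(20, 1.0, 9).as_string(schema="newick")
        b = simulate_yule_tree(20, 1.0, 9).as_string(schema="newick")
        assert a == b


class TestPerturbation:
    def test_identity_perturbation(self, yule50):
        trees = perturb_tree_set(yule50, 10, 0, 0.0, 3)
        base = yule50.as_string(schema="newick")
        assert len(trees) == 10
        assert all(t.as_string(schema="newick") == base for t in trees)

    def test_tip_labels_conserved_and_topology_moves(self, yule50):
        trees = perturb_tree_set(yule50, 30, 3, 0.1, 4)
        base_tips = {l.taxon.label for l in yule50.leaf_node_iter()}
        rfs = []
        for t in trees:
            assert {l.taxon.label for l in t.leaf_node_iter()} == base_tips
            clone = yule50.clone(depth=1)
            clone.migrate_taxon_namespace(t.taxon_namespace)
            rfs.append(treecompare.symmetric_difference(clone, t))
        assert np.mean(rfs) > 0

    def test_jitter_preserves_positivity(self, yule50):
        trees = perturb_tree_set(yule50, 5, 0, 0.5, 5)
        for t in trees:
            assert all(e.length > 0 for e in t.preorder_edge_iter() if e.length is not None)


class TestDiscreteTrait:
    def test_zero_rate_freezes_root_state(self, yule50):
        tips = simulate_discrete_trait(yule50, MkModel(k=3, rates=0.0), 2, 6)
        assert set(tips.values()) == {2}

    def test_root_state_out_of_range(self, yule50):
        with pytest.raises(InvalidParameterError):
            simulate_discrete_trait(yule50, MkModel(k=3, rates=0.1), 3, 0)

    def test_stationary_distribution_on_long_star(self):
        n, k = 1000, 4
        nwk = "(" + ",".join(f"t{i}:50.0" for i in range(n)) + ");"
        tips = simulate_discrete_trait(tree_from_newick(nwk), MkModel(k=k, rates=1.0), 0, 7)
        counts = np.bincount(list(tips.values()), minlength=k)
        assert chisquare(counts).pvalue > 0.01

    def test_cherry_matches_closed_form_transition_probability(self):
        # P(tip == root) on a branch of length t under ER:
        # 1/k + (k-1)/k * exp(-k q t), cross-checked against expm
        k, q, t = 4, 0.1, 1.3
        closed = 1 / k + (k - 1) / k * np.exp(-k * q * t)
        model = MkModel(k=k, rates=q)
        assert closed == pytest.approx(expm(model.rate_matrix() * t)[0, 0], abs=1e-12)
        cherry = TreeArrays.from_tree(tree_from_newick(f"(A:{t},B:{t});"))
        hits = n_rep = 0
        for seed in range(10_000):
            tips = simulate_discrete_trait(cherry, model, 0, seed)
            hits += tips["A"] == 0
            n_rep += 1
        se = np.sqrt(closed * (1 - closed) / n_rep)
        assert abs(hits / n_rep - closed) < 3 * se


class TestPolymorphicTipset:
    @pytest.fixture(scope="class")
    def base_states(self, yule50):
        return simulate_discrete_trait(yule50, MkModel(k=4, rates=0.3), 0, 8)

    def test_identity(self, base_states):
        out = simulate_polymorphic_tipset(base_states, MkModel(k=4, rates=0.3), 0.0, 0.0, 1)
        assert all(out[t] == frozenset({s}) for t, s in base_states.items())

    def test_forced_polymorphism(self, base_states):
        out = simulate_polymorphic_tipset(base_states, MkModel(k=4, rates=0.3), 1.0, 0.0, 1)
        assert all(len(ss) == 2 for ss in out.values())
        assert all(base_states[t] in ss for t, ss in out.items())

    def test_polymorphic_fraction_binomial(self):
        states = {f"t{i}": 0 for i in range(1000)}
        out = simulate_polymorphic_tipset(states, MkModel(k=4, rates=0.3), 0.2, 0.05, 2)
        frac_poly = np.mean([ss is not None and len(ss) == 2 for ss in out.values()])
        frac_miss = np.mean([ss is None for ss in out.values()])
        assert abs(frac_poly - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 1000)
        assert abs(frac_miss - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 1000)

    def test_probability_overflow_rejected(self, base_states):
        with pytest.raises(InvalidParameterError):
            simulate_polymorphic_tipset(base_states, MkModel(k=4, rates=0.3), 0.7, 0.5, 1)


class TestCorrelatedPair:
    def test_all_zero_rates_freeze_root_pair(self, yule50):
        out = simulate_correlated_binary_pair(yule50, np.zeros(8), (1, 0), 1)
        assert set(out.values()) == {(1, 0)}

    def test_negative_rate_rejected(self, yule50):
        rates = np.zeros(8)
        rates[3] = -0.1
        with pytest.raises(InvalidParameterError):
            simulate_correlated_binary_pair(yule50, rates, (0, 0), 1)

    def test_context_free_rates_match_independent_product(self):
        # with no contingency the joint chain factorises into two binary
        # chains; compare pooled joint tip counts against two independent
        # binary simulations with the matched gain/loss rates
        a_gain, a_loss, b_gain, b_loss = 0.3, 0.2, 0.4, 0.1
        rates = np.array([b_gain, a_gain, b_loss, a_gain, a_loss, b_gain, a_loss, b_loss])
        tree = TreeArrays.from_tree(simulate_yule_tree(12, 1.0, 11))
        joint = np.zeros(4)
        indep = np.zeros(4)
        for rep in range(400):
            pair = simulate_correlated_binary_pair(tree, rates, (0, 0), 100 + rep)
            for a, b in pair.values():
                joint[2 * a + b] += 1
            ta = simulate_discrete_trait(tree, MkModel(k=2, rate_model="ARD", rates=[a_gain, a_loss]), 0, 5000 + rep)
            tb = simulate_discrete_trait(tree, MkModel(k=2, rate_model="ARD", rates=[b_gain, b_loss]), 0, 9000 + rep)
            for t in ta:
                indep[2 * ta[t] + tb[t]] += 1
        # chi-square homogeneity between the two simulated joint distributions
        from scipy.stats import chi2_contingency

        stat = chi2_contingency(np.array([joint, indep]))
        assert stat.pvalue > 0.01

    def test_planted_contingency_gives_positive_association(self):
        # B gains only when A is derived -> positive odds ratio at the tips
        rates = np.array([0.0, 0.3, 0.1, 0.3, 0.3, 1.0, 0.3, 0.1])
        tree = simulate_yule_tree(500, 1.0, 13)
        pair = simulate_correlated_binary_pair(tree, rates, (0, 0), 14)
        tab = np.zeros((2, 2))
        for a, b in pair.values():
            tab[a, b] += 1
        odds = (tab[0, 0] * tab[1, 1]) / max(tab[0, 1] * tab[1, 0], 1.0)
        assert odds > 1

    def test_dependent_rate_matrix_structure(self):
        Q = dependent_rate_matrix(np.arange(1, 9, dtype=float))
        assert Q[0, 3] == Q[3, 0] == Q[1, 2] == Q[2, 1] == 0  # no double transitions
        assert np.allclose(Q.sum(axis=1), 0)


def test_simulation_config_validation():
    with pytest.raises(InvalidParameterError):
        SimulationConfig(n_tips=2)
    with pytest.raises(InvalidParameterError):
        SimulationConfig(poly_prob=1.4)
    cfg = SimulationConfig()
    assert cfg.n_tips == 242
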