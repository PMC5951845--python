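import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nestevo.errors import (
    DroppedReplicateWarning,
    InputError,
    InvalidParameterError,
    UndefinedStatisticError,
)
from nestevo.mk import MkModel
from nestevo.signal import (
    MantelResult,
    bray_curtis_dissimilarity,
    bray_curtis_matrix,
    conventional_mantel,
    em_mantel,
    mantel_statistic,
    patristic_distances,
    signal_report,
)
from nestevo.simulate import simulate_discrete_trait, simulate_yule_tree
from nestevo.trees import TreeArrays

from conftest import tree_from_newick


class TestPatristic:
    def test_cherry(self):
        labels, d = patristic_distances(tree_from_newick("(A:1,B:1);"))
        assert d[labels.index("A"), labels.index("B")] == pytest.approx(2.0)

    def test_three_taxon_hand_values(self):
        labels, d = patristic_distances(tree_from_newick("((A:1,B:1):1,C:2);"))
        i = {l: j for j, l in enumerate(labels)}
        assert d[i["A"], i["B"]] == pytest.approx(2.0)
        assert d[i["A"], i["C"]] == pytest.approx(4.0)
        assert d[i["B"], i["C"]] == pytest.approx(4.0)

    def test_matches_dendropy_on_random_tree(self, yule50):
        labels, d = patristic_distances(yule50)
        pdm = yule50.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in yule50.taxon_namespace}
        for a, b in [("t1", "t2"), ("t5", "t40"), ("t17", "t33")]:
            assert d[labels.index(a), labels.index(b)] == pytest.approx(
                pdm.patristic_distance(taxa[a], taxa[b])
            )

    def test_ultrametric_max_distance_is_twice_height(self, yule50):
        arrays = TreeArrays.from_tree(yule50)
        _, d = patristic_distances(yule50)
        assert d.max() == pytest.approx(2 * arrays.tip_depths()[0], abs=1e-9)


class TestBrayCurtis:
    def test_identical_sets(self):
        assert bray_curtis_dissimilarity({"cup"}, {"cup"}) == 0.0

    def test_disjoint_sets(self):
        assert bray_curtis_dissimilarity({"cup"}, {"platform"}) == 1.0

    def test_partial_overlap(self):
        assert bray_curtis_dissimilarity({"cup"}, {"cup", "simple dome"}) == pytest.approx(1 - 2 / 3)

    def test_empty_set_rejected(self):
        with pytest.raises(InputError):
            bray_curtis_dissimilarity(set(), {"cup"})

    @given(
        a=st.sets(st.integers(0, 6), min_size=1, max_size=4),
        b=st.sets(st.integers(0, 6), min_size=1, max_size=4),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_symmetry(self, a, b):
        d = bray_curtis_dissimilarity(a, b)
        assert 0 <= d <= 1
        assert d == bray_curtis_dissimilarity(b, a)
        if a == b:
            assert d == 0

    def test_singletons_reduce_to_mismatch_metric(self):
        labels = ["x", "y", "z"]
        sets = {"x": {0}, "y": {0}, "z": {1}}
        d = bray_curtis_matrix(labels, sets)
        assert d[0, 1] == 0 and d[0, 2] == 1 and d[1, 2] == 1


class TestMantelStatistic:
    def test_perfect_linear_relation(self):
        rng = np.random.default_rng(0)
        d = np.abs(rng.normal(size=(6, 6)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        assert mantel_statistic(d, 2 * d) == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        d = np.ones((5, 5)) - np.eye(5)
        rng = np.random.default_rng(1)
        other = np.abs(rng.normal(size=(5, 5)))
        other = (other + other.T) / 2
        np.fill_diagonal(other, 0)
        with pytest.raises(UndefinedStatisticError):
            mantel_statistic(d, d * 1.0)
        # sanity: non-constant matrices fine
        assert np.isfinite(mantel_statistic(other, other))

    def test_four_taxon_hand_computation(self):
        d1 = np.zeros((4, 4))
        d2 = np.zeros((4, 4))
        v1 = [1, 2, 3, 4, 5, 6]
        v2 = [2, 1, 4, 3, 6, 5]
        iu = np.triu_indices(4, 1)
        d1[iu] = v1
        d2[iu] = v2
        d1 += d1.T
        d2 += d2.T
        assert mantel_statistic(d1, d2) == pytest.approx(np.corrcoef(v1, v2)[0, 1])

    def test_matches_scikit_bio(self, yule50):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        _, d_phy = patristic_distances(yule50)
        trait = simulate_discrete_trait(yule50, MkModel(k=4, rates=0.2), 0, 1)
        labels = sorted(trait)
        d_trait = bray_curtis_matrix(labels, {t: {v} for t, v in trait.items()})
        r_skbio, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(d_phy, ids=labels),
            skbio_distance.DistanceMatrix(d_trait, ids=labels),
            permutations=0,
        )
        assert mantel_statistic(d_phy, d_trait) == pytest.approx(r_skbio, abs=1e-12)

    def test_joint_relabelling_invariance(self, yule50):
        _, d_phy = patristic_distances(yule50)
        rng = np.random.default_rng(2)
        d_trait = rng.random((50, 50))
        d_trait = (d_trait + d_trait.T) / 2
        np.fill_diagonal(d_trait, 0)
        r = mantel_statistic(d_phy, d_trait)
        p = rng.permutation(50)
        assert mantel_statistic(d_phy[np.ix_(p, p)], d_trait[np.ix_(p, p)]) == pytest.approx(r)


class TestConventionalMantel:
    def test_maximal_signal(self, yule50):
        _, d = patristic_distances(yule50)
        res = conventional_mantel(d, d.copy(), n_perm=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_perm <= 0.01

    def test_p_value_never_zero_and_reproducible(self, yule50):
        _, d = patristic_distances(yule50)
        rng = np.random.default_rng(3)
        noise = rng.random((50, 50))
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        a = conventional_mantel(d, noise, n_perm=199, seed=9)
        b = conventional_mantel(d, noise, n_perm=199, seed=9)
        assert a.p_perm > 0
        assert np.array_equal(a.perm_null, b.perm_null)

    def test_too_few_permutations_rejected(self, yule50):
        _, d = patristic_distances(yule50)
        with pytest.raises(InvalidParameterError):
            conventional_mantel(d, d, n_perm=10)


class TestEMMantel:
    def test_zero_replicates_rejected(self, yule50):
        trait = simulate_discrete_trait(yule50, MkModel(k=4, rates=0.2), 0, 4)
        states = {t: frozenset({v}) for t, v in trait.items()}
        with pytest.raises(InvalidParameterError):
            em_mantel(yule50, states, MkModel(k=4, rates=0.2), 0, n_sim=0)

    def test_invalid_root_state_rejected(self, yule50):
        trait = simulate_discrete_trait(yule50, MkModel(k=4, rates=0.2), 0, 4)
        states = {t: frozenset({v}) for t, v in trait.items()}
        with pytest.raises(InvalidParameterError):
            em_mantel(yule50, states, MkModel(k=4, rates=0.2), 7, n_sim=99)

    def test_zero_variance_replicates_dropped_with_warning(self):
        tree = simulate_yule_tree(20, 1.0, 5)
        trait = simulate_discrete_trait(tree, MkModel(k=3, rates=0.2), 0, 6)
        states = {t: frozenset({v}) for t, v in trait.items()}
        # tiny rate: most simulated traits are monomorphic
        with pytest.warns(DroppedReplicateWarning):
            res = em_mantel(tree, states, MkModel(k=3, rates=0.005), 0, n_sim=199, seed=7)
        assert res.n_dropped > 0
        assert res.em_null.size == 199 - res.n_dropped

    def test_null_agrees_with_permutation_when_rate_saturates(self, yule50):
        # at very high rates simulated tips are label-exchangeable, so the
        # EM null and the permutation null coincide in distribution
        from scipy.stats import ks_2samp

        trait = simulate_discrete_trait(yule50, MkModel(k=4, rates=5.0), 0, 8)
        states = {t: frozenset({v}) for t, v in trait.items()}
        labels, d_phy = patristic_distances(yule50)
        d_trait = bray_curtis_matrix(labels, states)
        conv = conventional_mantel(d_phy, d_trait, n_perm=999, seed=10)
        emr = em_mantel(yule50, states, MkModel(k=4, rates=5.0), 0, n_sim=999, seed=11)
        assert ks_2samp(conv.perm_null, emr.em_null).pvalue > 0.01


class TestSignalReport:
    def test_single_result_row(self):
        res = MantelResult(r=0.3, n_taxa=30, perm_null=np.zeros(9), p_perm=0.5)
        df = signal_report({("structure", "all"): res})
        assert len(df) == 1 and df.loc[0, "character"] == "structure"

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            signal_report({})
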