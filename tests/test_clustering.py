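"""UPGMA construction, Newick export, threshold cuts, cophenetic agreement.

scipy.cluster.hierarchy (average linkage + cophenet) serves as the
independent reference implementation throughout.
"""

import numpy as np
import pytest
from scipy.cluster.hierarchy import average as scipy_average, cophenet
from scipy.spatial.distance import squareform

from trapdiv import (
    DistanceMatrix,
    ValidationError,
    cophenetic_correlation,
    cut_at_similarity,
    cut_into_k,
    default_paper_config,
    simulate_matrix,
    similarity_matrix,
    to_distance,
    to_newick,
    upgma,
)


def _dm(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [chr(65 + i) for i in range(values.shape[0])]
    return DistanceMatrix(labels, values)


def _random_dm(rng, n):
    cond = rng.uniform(0.05, 1.0, size=n * (n - 1) // 2)
    return _dm(squareform(cond))


def _random_ultrametric(rng, n):
    """Random ultrametric via a random UPGMA tree's cophenetic distances."""
    t = upgma(_random_dm(rng, n))
    return _dm(t.cophenetic_matrix())


class TestUpgma:
    def test_two_leaves_single_merge(self):
        t = upgma(_dm([[0, 0.2], [0.2, 0]]))
        assert t.merges == [(0, 1, 0.2)]
        assert t.root_height == 0.2

    def test_three_leaf_hand_computation(self):
        d = _dm([[0, 0.1, 0.4], [0.1, 0, 0.4], [0.4, 0.4, 0]])
        t = upgma(d)
        assert [h for _, _, h in t.merges] == pytest.approx([0.1, 0.4])
        members = t.node_members()
        assert members[3] == frozenset({0, 1})

    def test_proportional_averaging_three_leaves(self):
        # after merging A,B the distance to C is (0.3 + 0.5) / 2 = 0.4
        d = _dm([[0, 0.1, 0.3], [0.1, 0, 0.5], [0.3, 0.5, 0]])
        t = upgma(d)
        assert t.merges[1][2] == pytest.approx(0.4)

    def test_asymmetric_or_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(["A", "B"], np.array([[0.0, 0.3], [0.1, 0.0]]))
        d = _dm([[0, 0.2], [0.2, 0]])
        d.values[0, 1] = -0.2  # tamper after construction
        d.values[1, 0] = -0.2
        with pytest.raises(ValidationError):
            upgma(d)

    def test_heights_non_decreasing_on_random_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            t = upgma(_random_dm(rng, 8))
            heights = [h for _, _, h in t.merges]
            assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_ultrametric_input_reproduced_exactly(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            d = _random_ultrametric(rng, 6)
            t = upgma(d)
            assert np.allclose(t.cophenetic_matrix(), d.values, atol=1e-9)

    def test_cophenetic_matches_scipy_reference(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            d = _random_dm(rng, 7)
            mine = upgma(d).cophenetic_matrix()
            theirs = squareform(cophenet(scipy_average(squareform(d.values))))
            assert np.allclose(mine, theirs, atol=1e-9)

    def test_leaf_permutation_only_permutes(self):
        rng = np.random.default_rng(23)
        d = _random_dm(rng, 6)
        perm = rng.permutation(6)
        permuted = _dm(
            d.values[np.ix_(perm, perm)], [d.strain_ids[i] for i in perm]
        )
        coph_a = upgma(d).cophenetic_matrix()
        coph_b = upgma(permuted).cophenetic_matrix()
        assert np.allclose(coph_a[np.ix_(perm, perm)], coph_b, atol=1e-12)

    def test_tie_break_is_lexicographic(self):
        # A-B and C-D are both at the minimum 0.1; A-B must merge first
        vals = squareform([0.1, 0.9, 0.9, 0.9, 0.9, 0.1])
        t = upgma(_dm(vals))
        assert t.merges[0][:2] == (0, 1)
        assert t.merges[1][:2] == (2, 3)


class TestNewick:
    def test_two_leaf_half_height_branches(self):
        t = upgma(_dm([[0, 0.2], [0.2, 0]]))
        assert to_newick(t) == "(A:0.1,B:0.1);"

    def test_labels_with_spaces_are_quoted(self):
        t = upgma(_dm([[0, 0.2], [0.2, 0]], ["strain one", "strain;two"]))
        nwk = to_newick(t)
        assert "'strain one'" in nwk and "'strain;two'" in nwk

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_preserves_topology_and_heights(self, seed):
        import dendropy

        rng = np.random.default_rng(seed)
        d = _random_dm(rng, 8)
        t = upgma(d)
        tree = dendropy.Tree.get(data=to_newick(t), schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in tree.taxon_namespace}
        coph = t.cophenetic_matrix()
        for i, a in enumerate(t.leaves):
            for j, b in enumerate(t.leaves):
                if i < j:
                    # path length between leaves equals the cophenetic distance
                    assert pdm.patristic_distance(
                        taxa[a], taxa[b]
                    ) == pytest.approx(coph[i, j], abs=1e-8)


class TestCuts:
    def test_extreme_thresholds(self, default_sim):
        matrix, _ = default_sim
        t = upgma(to_distance(similarity_matrix(matrix)))
        assert cut_at_similarity(t, 0.0).k == 1
        assert cut_at_similarity(t, 1.0).k == matrix.n_strains

    def test_cluster_count_monotone_in_threshold(self, default_sim):
        matrix, _ = default_sim
        t = upgma(to_distance(similarity_matrix(matrix)))
        ks = [cut_at_similarity(t, s).k for s in np.linspace(1, 0, 21)]
        assert all(b <= a for a, b in zip(ks, ks[1:]))

    def test_cut_just_below_final_merge_recovers_planted_clusters(
        self, default_sim
    ):
        matrix, truth = default_sim
        t = upgma(to_distance(similarity_matrix(matrix)))
        s = 1.0 - (t.root_height - 1e-9)
        a = cut_at_similarity(t, s)
        assert a.k == 2
        grouping = {}
        for strain, cid in a.labels.items():
            grouping.setdefault(cid, set()).add(truth.cluster_labels[strain])
        assert all(len(v) == 1 for v in grouping.values())

    def test_cut_into_k_matches_threshold_cut(self, default_sim):
        matrix, _ = default_sim
        t = upgma(to_distance(similarity_matrix(matrix)))
        a2 = cut_into_k(t, 2)
        assert a2.k == 2
        assert cut_at_similarity(t, a2.threshold_similarity).labels == a2.labels

    def test_invalid_threshold_rejected(self, default_sim):
        matrix, _ = default_sim
        t = upgma(to_distance(similarity_matrix(matrix)))
        with pytest.raises(ValidationError):
            cut_at_similarity(t, 1.5)


class TestCophenetic:
    def test_ultrametric_input_gives_r_one(self):
        rng = np.random.default_rng(31)
        d = _random_ultrametric(rng, 6)
        assert cophenetic_correlation(upgma(d), d) == pytest.approx(1.0)

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            d = _random_dm(rng, 6)
            t = upgma(d)
            iu = np.triu_indices(6, 1)
            x, y = d.values[iu], t.cophenetic_matrix()[iu]
            expected = (
                ((x - x.mean()) * (y - y.mean())).sum()
                / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
            )
            assert cophenetic_correlation(t, d) == pytest.approx(expected)

    def test_pair_only_input_rejected(self):
        d = _dm([[0, 0.2], [0.2, 0]])
        with pytest.raises(ValidationError):
            cophenetic_correlation(upgma(d), d)
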