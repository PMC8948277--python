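import itertools

import numpy as np
import pytest

from connfp import (
    edge_overlap_test,
    make_parcellation,
    network_cell_proportions,
    network_matrix_correlation,
    node_degree,
    predictive_mask,
    rewire_preserving_degree,
    spin_test,
)
from connfp.connectome import Parcellation, edge_node_pairs, n_edges
from connfp.fingerprint import EdgeMask
from connfp.overlap import _edge_index_of_pair, _uniform_rotation


def mask_from_pairs(pairs, n):
    bits = np.zeros(n_edges(n), dtype=bool)
    for i, j in pairs:
        bits[_edge_index_of_pair(np.array([i]), np.array([j]), n)[0]] = True
    return EdgeMask(bits=bits)


def degrees_of(bits, n):
    ii, jj = edge_node_pairs(n)
    return np.bincount(ii[bits], minlength=n) + np.bincount(jj[bits], minlength=n)


class TestPredictiveMask:
    def test_empty_when_nothing_selected(self):
        assert predictive_mask(np.zeros(10)).n_selected == 0

    def test_boundary_is_inclusive(self):
        m = predictive_mask(np.array([0.79, 0.80, 1.0]), min_frac=0.8)
        assert m.n_selected == 2
        assert not m.bits[0]

    def test_exact_fold_count_fraction(self):
        # a frequency arising as 800 of 1000 folds compares equal to 0.8
        freq = np.array([800 / 1000, 799 / 1000])
        assert np.array_equal(predictive_mask(freq, 0.8).bits, [True, False])


class TestRewire:
    def test_star_graph_is_rigid(self):
        star = mask_from_pairs([(0, 1), (0, 2), (0, 3), (0, 4)], 5)
        out = rewire_preserving_degree(star, seed=1)
        assert np.array_equal(out.bits, star.bits)

    def test_four_cycle_stays_degree_two_everywhere(self):
        cycle = mask_from_pairs([(0, 1), (1, 2), (2, 3), (0, 3)], 4)
        # enumerate all 2-regular simple graphs on 4 labelled nodes: the
        # three perfect pairings of the 4-cycle's edge structure
        valid = []
        all_pairs = list(itertools.combinations(range(4), 2))
        for combo in itertools.combinations(all_pairs, 4):
            deg = np.zeros(4, int)
            for i, j in combo:
                deg[i] += 1
                deg[j] += 1
            if np.all(deg == 2):
                valid.append(frozenset(combo))
        assert len(valid) == 3
        for seed in range(10):
            out = rewire_preserving_degree(cycle, seed=seed)
            ii, jj = edge_node_pairs(4)
            got = frozenset(
                (int(a), int(b)) for a, b in zip(ii[out.bits], jj[out.bits])
            )
            assert got in valid

    def test_degree_sequence_preserved_on_random_graphs(self, rng):
        # the defining invariant, checked on 100 random graphs
        for trial in range(100):
            n = int(rng.integers(6, 25))
            E = n_edges(n)
            m = int(rng.integers(2, max(3, E // 3)))
            bits = np.zeros(E, dtype=bool)
            bits[rng.choice(E, size=m, replace=False)] = True
            out = rewire_preserving_degree(bits, seed=trial)
            assert np.array_equal(
                np.sort(degrees_of(bits, n)), np.sort(degrees_of(out.bits, n))
            )
            assert out.n_selected == m

    def test_tiny_mask_returned_unchanged_with_warning(self):
        bits = np.zeros(n_edges(5), dtype=bool)
        bits[0] = True
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = rewire_preserving_degree(bits, seed=0)
        assert np.array_equal(out.bits, bits)

    def test_rewiring_actually_moves_edges(self, rng):
        bits = np.zeros(n_edges(30), dtype=bool)
        bits[rng.choice(n_edges(30), size=60, replace=False)] = True
        out = rewire_preserving_degree(bits, seed=5)
        assert not np.array_equal(out.bits, bits)


class TestEdgeOverlapTest:
    def test_empty_mask_overlaps_nothing(self, rng):
        E = n_edges(10)
        maskB = np.zeros(E, dtype=bool)
        maskB[rng.choice(E, 8, replace=False)] = True
        res = edge_overlap_test(np.zeros(E, dtype=bool), maskB, n_perm=50, seed=0)
        assert res.observed == 0
        assert res.p_value == 1.0

    def test_self_overlap_is_extreme(self, rng):
        # identical masks dense in a small subgraph: observed at the maximum
        # half the possible edges among 8 of 15 nodes (dense but not rigid:
        # a complete subgraph would be the unique graph with its degrees)
        bits = np.zeros(n_edges(15), dtype=bool)
        ii, jj = edge_node_pairs(15)
        sub = np.flatnonzero((ii < 8) & (jj < 8))
        bits[np.random.default_rng(0).choice(sub, size=14, replace=False)] = True
        res = edge_overlap_test(bits, bits, n_perm=200, seed=1)
        assert res.observed == bits.sum()
        assert res.p_value < 0.05

    def test_null_mean_matches_exhaustive_enumeration(self):
        # 5-node fixture: brute-force every degree-preserving configuration
        # of maskB and average the overlap with maskA
        n = 5
        maskA = mask_from_pairs([(0, 1), (2, 3), (1, 4)], n)
        maskB = mask_from_pairs([(0, 2), (1, 3), (2, 4)], n)
        degB = np.sort(degrees_of(maskB.bits, n))
        all_pairs = list(itertools.combinations(range(n), 2))
        overlaps = []
        for combo in itertools.combinations(all_pairs, 3):
            deg = np.zeros(n, int)
            for i, j in combo:
                deg[i] += 1
                deg[j] += 1
            if np.array_equal(np.sort(deg), degB):
                m = mask_from_pairs(combo, n)
                overlaps.append(int(np.sum(m.bits & maskA.bits)))
        exact_mean = np.mean(overlaps)
        res = edge_overlap_test(maskA, maskB, n_perm=2000, seed=3)
        se = np.std(overlaps) / np.sqrt(2000)
        # degree-sequence-preserving null vs exact enumeration over the same
        # degree sequence; allow 3 MC standard errors plus mixing slack
        assert res.null_mean == pytest.approx(exact_mean, abs=max(3 * se, 0.15))

    def test_add_one_p_convention(self, rng):
        E = n_edges(8)
        bits = np.zeros(E, dtype=bool)
        bits[rng.choice(E, 6, replace=False)] = True
        res = edge_overlap_test(bits, bits, n_perm=99, seed=2)
        assert res.p_value >= 1 / 100  # can never be zero


class TestNetworkMatrix:
    @pytest.fixture
    def two_net_parc(self):
        # 6 nodes, nets A = {0,1,2}, B = {3,4,5}
        return Parcellation(
            node_ids=[f"n{i}" for i in range(6)],
            networks=np.array(["A", "A", "A", "B", "B", "B"]),
            centroids=np.tile([0.0, 0.0, 1.0], (6, 1)),
        )

    def test_hand_counted_proportions(self, two_net_parc):
        # select edges (0,1) within A and (0,3), (2,5) between A and B
        mask = mask_from_pairs([(0, 1), (0, 3), (2, 5)], 6)
        nm = network_cell_proportions(mask, two_net_parc)
        a = nm.labels.index("A")
        b = nm.labels.index("B")
        assert nm.cells[a, a] == pytest.approx(100 * 1 / 3)
        assert nm.cells[a, b] == pytest.approx(100 * 2 / 9)
        assert nm.cells[b, b] == pytest.approx(0.0)

    def test_full_mask_saturates_all_cells(self, two_net_parc):
        mask = EdgeMask(bits=np.ones(n_edges(6), dtype=bool))
        nm = network_cell_proportions(mask, two_net_parc)
        assert np.allclose(nm.cells, 100.0)

    def test_partition_property(self, rng):
        parc = make_parcellation(30, 4, seed=2)
        bits = np.zeros(n_edges(30), dtype=bool)
        bits[rng.choice(n_edges(30), 50, replace=False)] = True
        nm = network_cell_proportions(EdgeMask(bits=bits), parc)
        iu = np.triu_indices(len(nm.labels))
        assert nm.selected[iu].sum() == 50
        assert nm.total[iu].sum() == n_edges(30)

    def test_eight_networks_have_36_cells(self):
        parc = make_parcellation(80, 8, seed=4)
        nm = network_cell_proportions(
            EdgeMask(bits=np.zeros(n_edges(80), dtype=bool)), parc
        )
        iu = np.triu_indices(8)
        assert len(iu[0]) == 36

    def test_matrix_correlation_identity_and_affine(self, rng):
        parc = make_parcellation(40, 5, seed=1)
        bits = np.zeros(n_edges(40), dtype=bool)
        bits[rng.choice(n_edges(40), 80, replace=False)] = True
        nm = network_cell_proportions(EdgeMask(bits=bits), parc)
        r, p, df = network_matrix_correlation(nm, nm)
        assert r == pytest.approx(1.0)
        assert df == 15 - 2
        from dataclasses import replace

        # linear rescaling of the cell values leaves Pearson r at +1
        nm2 = replace(nm, selected=3 * nm.selected)
        r2, _, _ = network_matrix_correlation(nm, nm2)
        assert r2 == pytest.approx(1.0)

    def test_matches_closed_form_pearson(self, rng):
        parc = make_parcellation(50, 8, seed=3)
        masks = []
        for s in (10, 20):
            bits = np.zeros(n_edges(50), dtype=bool)
            bits[np.random.default_rng(s).choice(n_edges(50), 120, replace=False)] = True
            masks.append(network_cell_proportions(EdgeMask(bits=bits), parc))
        r, p, df = network_matrix_correlation(*masks)
        iu = np.triu_indices(8)
        a, b = masks[0].cells[iu], masks[1].cells[iu]
        ac, bc = a - a.mean(), b - b.mean()
        expect = np.sum(ac * bc) / np.sqrt(np.sum(ac**2) * np.sum(bc**2))
        assert r == pytest.approx(expect, abs=1e-12)


class TestNodeDegree:
    def test_empty_and_triangle(self):
        parc = make_parcellation(6, 2, seed=0)
        assert node_degree(np.zeros(n_edges(6), dtype=bool), parc).sum() == 0
        tri = mask_from_pairs([(0, 1), (1, 2), (0, 2)], 6)
        deg = node_degree(tri, parc)
        assert np.array_equal(deg[:3], [2, 2, 2])

    def test_handshake_lemma(self, rng):
        parc = make_parcellation(15, 3, seed=1)
        bits = np.zeros(n_edges(15), dtype=bool)
        bits[rng.choice(n_edges(15), 20, replace=False)] = True
        assert node_degree(bits, parc).sum() == 40


class TestSpinTest:
    def test_identical_maps_give_rho_one(self, rng):
        parc = make_parcellation(50, 4, seed=2)
        m = rng.random(50)
        res = spin_test(m, m, parc, n_perm=100, seed=0)
        assert res.rho == pytest.approx(1.0)

    def test_identity_rotation_reproduces_observed(self, rng):
        parc = make_parcellation(40, 3, seed=1)
        a, b = rng.random(40), rng.random(40)
        # identity rotation => nearest original centroid is the node itself
        assignment = np.argmax(parc.centroids @ parc.centroids.T, axis=1)
        assert np.array_equal(assignment, np.arange(40))

    def test_rotations_preserve_pairwise_distances(self, rng):
        cent = make_parcellation(30, 3, seed=5).centroids
        gram = cent @ cent.T
        for seed in range(20):
            rot = _uniform_rotation(np.random.default_rng(seed))
            rotated = cent @ rot.T
            assert np.max(np.abs(rotated @ rotated.T - gram)) < 1e-9

    def test_missing_centroid_rejected(self, rng):
        parc = make_parcellation(10, 2, seed=0)
        parc.centroids[3] = 0.0
        with pytest.raises(ValueError, match=r"\[3\]"):
            spin_test(rng.random(10), rng.random(10), parc, n_perm=10, seed=0)

    def test_null_centered_for_independent_maps(self, rng):
        parc = make_parcellation(100, 6, seed=7)
        a, b = rng.standard_normal(100), rng.standard_normal(100)
        res = spin_test(a, b, parc, n_perm=2000, seed=1)
        assert abs(res.null_rhos.mean()) < 0.02
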