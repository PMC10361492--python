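"""Agglomerative folding model: tree building, ring slicing, reshuffling,
model nestedness and the Q fit."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage

import chromnest as cn
from chromnest.folding_model import UNASSIGNED


def random_strengths(nd, seed):
    rng = np.random.default_rng(seed)
    s = rng.random((nd, nd))
    s = 0.5 * (s + s.T)
    np.fill_diagonal(s, 0.0)
    return s


class TestDomainInteraction:
    def test_two_single_bin_domains(self):
        m = cn.ContactMatrix(np.array([[0, 7.0], [7, 0]]))
        doms = [cn.Domain(1, 0, 1), cn.Domain(2, 1, 2)]
        s = cn.domain_interaction(m, doms)
        assert s[0, 1] == 7.0

    def test_mean_over_bin_pairs(self):
        a = np.zeros((3, 3))
        a[0, 2], a[1, 2] = 2.0, 4.0
        m = cn.ContactMatrix(a + a.T)
        doms = [cn.Domain(1, 0, 2), cn.Domain(2, 2, 3)]
        s = cn.domain_interaction(m, doms)
        assert s[0, 1] == 3.0

    def test_uniform_matrix_uniform_strengths(self):
        m = cn.ContactMatrix(np.ones((6, 6)) - np.eye(6))
        doms = [cn.Domain(i + 1, 2 * i, 2 * i + 2) for i in range(3)]
        s = cn.domain_interaction(m, doms)
        off = s[np.triu_indices(3, 1)]
        np.testing.assert_allclose(off, 1.0)


class TestAgglomerate:
    def test_greedy_merge_order(self):
        s = np.array([[0, 5, 1], [5, 0, 2], [1, 2, 0]], float)
        tree = cn.agglomerate(s)
        assert [(e[1], e[2]) for e in tree.merge_events] == [(0, 1), (2, 3)]

    def test_event_count_and_root(self):
        tree = cn.agglomerate(random_strengths(7, 0))
        assert len(tree.merge_events) == 6
        assert tree.members()[7 + 5] == frozenset(range(7))

    def test_asymmetric_rejected(self):
        s = np.array([[0, 1.0], [2, 0]])
        with pytest.raises(ValueError):
            cn.agglomerate(s)

    def test_tie_breaks_toward_smallest_pair(self):
        s = np.full((4, 4), 2.0)
        np.fill_diagonal(s, 0)
        tree = cn.agglomerate(s)
        assert (tree.merge_events[0][1], tree.merge_events[0][2]) == (0, 1)

    @pytest.mark.parametrize("nd,seed", [(4, 0), (6, 1), (8, 2), (10, 3), (10, 4)])
    def test_matches_average_linkage_oracle(self, nd, seed):
        """Independent oracle: scipy average-linkage clustering on distances
        1 - strength produces the same nested cluster system."""
        s = random_strengths(nd, seed)
        tree = cn.agglomerate(s)
        ours = {fs for sid, fs in tree.members().items() if sid >= nd}
        iu = np.triu_indices(nd, 1)
        z = linkage(1.0 - s[iu], method="average")
        scipy_members = {i: frozenset([i]) for i in range(nd)}
        theirs = set()
        for step, (a, b, _, _) in enumerate(z):
            merged = scipy_members[int(a)] | scipy_members[int(b)]
            scipy_members[nd + step] = merged
            theirs.add(merged)
        assert ours == theirs


class TestSliceRings:
    def test_root_ring(self):
        tree = cn.agglomerate(random_strengths(3, 0))
        rings = cn.slice_rings(tree, 1)
        assert len(rings) == 1
        assert (rings[0] == rings[0][0]).all()

    def test_ring_counts_increase_outward(self):
        tree = cn.agglomerate(random_strengths(12, 1))
        rings = cn.slice_rings(tree, 5)
        counts = [np.unique(r[r != UNASSIGNED]).size for r in rings]
        assert counts[0] == 1
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_too_many_rings_rejected(self):
        tree = cn.agglomerate(random_strengths(3, 0))
        with pytest.raises(ValueError):
            cn.slice_rings(tree, 3)

    def test_rings_structures_disjoint(self):
        tree = cn.agglomerate(random_strengths(15, 2))
        for ring in cn.slice_rings(tree, 6):
            assigned = ring[ring != UNASSIGNED]
            # each domain appears once, trivially disjoint; check sizes >= 2
            sizes = np.bincount(assigned)
            assert (sizes[sizes > 0] >= 2).all()


class TestReshuffle:
    def test_q_zero_identity(self):
        tree = cn.agglomerate(random_strengths(10, 3))
        rings = cn.slice_rings(tree, 4)
        out = cn.reshuffle(rings, 0.0, seed=9)
        for a, b in zip(rings, out):
            np.testing.assert_array_equal(a, b)

    def test_sizes_preserved(self):
        tree = cn.agglomerate(random_strengths(20, 4))
        rings = cn.slice_rings(tree, 6)
        out = cn.reshuffle(rings, 0.8, seed=1)
        for a, b in zip(rings, out):
            assert sorted(np.bincount(a[a != UNASSIGNED]).tolist()) == sorted(
                np.bincount(b[b != UNASSIGNED]).tolist()
            )

    def test_bit_reproducible(self):
        tree = cn.agglomerate(random_strengths(20, 4))
        rings = cn.slice_rings(tree, 5)
        r1 = cn.reshuffle(rings, 0.5, seed=123)
        r2 = cn.reshuffle(rings, 0.5, seed=123)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a, b)

    def test_q_out_of_range(self):
        with pytest.raises(ValueError):
            cn.reshuffle([np.array([0, 0, 1, 1])], 1.5)

    def test_q_one_change_rate_matches_pairing_oracle(self):
        """At Q = 1 every pair swaps, so the fraction of changed memberships
        equals the fraction of cross-structure pairs under uniform pairing.
        Oracle: direct simulation of the pairing process."""
        memb = np.repeat(np.arange(4), [10, 14, 9, 17])  # 50 domains
        n_seeds = 200
        changed = []
        for seed in range(n_seeds):
            out = cn.reshuffle([memb], 1.0, seed=seed)[0]
            changed.append(np.mean(out != memb))
        oracle = []
        rng = np.random.default_rng(10_000)
        for _ in range(n_seeds):
            perm = rng.permutation(memb.size)
            cross = 0
            for t in range(0, memb.size - 1, 2):
                if memb[perm[t]] != memb[perm[t + 1]]:
                    cross += 2
            oracle.append(cross / memb.size)
        se = np.hypot(np.std(changed) / np.sqrt(n_seeds), np.std(oracle) / np.sqrt(n_seeds))
        assert abs(np.mean(changed) - np.mean(oracle)) < 3 * se + 1e-12


class TestModelNestedness:
    def test_q_zero_fully_nested_or_segregated(self):
        tree = cn.agglomerate(random_strengths(40, 0))
        recs = cn.model_nestedness(cn.slice_rings(tree, 5))
        for r in recs:
            assert r.S in (0, min(r.d_i, r.d_j))
            if not r.degenerate:
                assert np.round(r.N, 12) in (-1.0, 1.0)

    def test_q_one_interior_mass(self):
        tree = cn.agglomerate(random_strengths(40, 0))
        rings = cn.reshuffle(cn.slice_rings(tree, 5), 1.0, seed=3)
        N = np.array([r.N for r in cn.model_nestedness(rings)])
        assert ((np.abs(N) < 0.8) & (N != 0)).sum() > 0

    def test_same_ring_pairs_never_compared(self):
        tree = cn.agglomerate(random_strengths(12, 1))
        recs = cn.model_nestedness(cn.slice_rings(tree, 4))
        assert all(r.gamma_i != r.gamma_j for r in recs)

    def test_needs_two_rings(self):
        with pytest.raises(ValueError):
            cn.model_nestedness([np.array([0, 0, 1, 1])])


class TestFitQ:
    def test_grid_of_length_one(self):
        s = random_strengths(30, 5)
        tree = cn.agglomerate(s)
        emp = cn.model_nestedness(cn.reshuffle(cn.slice_rings(tree, 5), 0.5, seed=0))
        fit = cn.fit_q(emp, s, q_grid=[0.4], replicates=2, seed=1)
        assert fit.q_opt == 0.4

    def test_all_mass_at_extremes_rejected(self):
        s = random_strengths(30, 5)
        tree = cn.agglomerate(s)
        emp = cn.model_nestedness(cn.slice_rings(tree, 5))  # Q=0: only +-1 and degenerate
        with pytest.raises(ValueError):
            cn.fit_q(emp, s, q_grid=[0.0, 0.5], replicates=2, seed=1)

    def test_self_recovery_coarse(self):
        """Parameter recovery on self-generated data at Q* = 0.3 (coarse grid,
        small tree; the full-scale recovery runs in the acceptance suite)."""
        s = random_strengths(100, 6)
        tree = cn.agglomerate(s)
        emp = cn.model_nestedness(cn.reshuffle(cn.slice_rings(tree, 8), 0.3, seed=42))
        fit = cn.fit_q(emp, s, q_grid=np.arange(0, 1.01, 0.1), replicates=10, seed=7, n_rings=8)
        assert abs(fit.q_opt - 0.3) <= 0.1
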