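"""Chromatin-state enrichment, BH correction, grouping and community modularity."""

import itertools

import numpy as np
import pandas as pd
import pytest

import chromnest as cn
from chromnest.chromatin_enrichment import STATES, group_modularity_medians


def make_track(rows):
    return cn.ChromatinTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "state"]))


class TestCountPeakStarts:
    def test_start_only_rule(self):
        track = make_track([("chr1", 150_000, 450_000, "S1")])
        counts = cn.count_peak_starts(track, {1}, bin_size=100_000)
        assert counts["S1"] == 1

    def test_peak_crossing_border_not_counted_downstream(self):
        track = make_track([("chr1", 150_000, 450_000, "S1")])
        counts = cn.count_peak_starts(track, {2, 3, 4}, bin_size=100_000)
        assert sum(counts.values()) == 0

    def test_empty_community(self):
        track = make_track([("chr1", 0, 100, "S2")])
        counts = cn.count_peak_starts(track, set(), bin_size=100_000)
        assert sum(counts.values()) == 0

    def test_malformed_peak_rejected(self):
        with pytest.raises(ValueError):
            make_track([("chr1", 500, 100, "S1")])


class TestHypergeomEnrichment:
    def test_whole_chromosome_p_one(self):
        expected, p, _ = cn.hypergeom_enrichment(5, 20, 5, 20)
        assert p == 1.0
        assert expected == 5.0

    def test_hand_example(self):
        expected, p, direction = cn.hypergeom_enrichment(4, 4, 5, 10)
        assert np.isclose(p, 2 * 5 / 210)
        assert direction == "enriched"
        assert expected == 2.0

    def test_infeasible_k_rejected(self):
        # with K = N - n_comm, every draw of n_comm peaks must hit >= 0 of the
        # other states; k=0 impossible when K covers all remaining peaks
        with pytest.raises(ValueError):
            cn.hypergeom_enrichment(0, 4, 8, 10)

    @pytest.mark.parametrize("N_tot,K,n_comm", [(8, 3, 4), (10, 5, 5), (12, 6, 3)])
    def test_two_sided_p_matches_enumeration(self, N_tot, K, n_comm):
        """Exhaustive oracle: enumerate all peak subsets directly."""
        from math import comb

        for k in range(max(0, n_comm - (N_tot - K)), min(n_comm, K) + 1):
            total = comb(N_tot, n_comm)
            pmf = {
                x: comb(K, x) * comb(N_tot - K, n_comm - x) / total
                for x in range(max(0, n_comm - (N_tot - K)), min(n_comm, K) + 1)
            }
            lower = sum(v for x, v in pmf.items() if x <= k)
            upper = sum(v for x, v in pmf.items() if x >= k)
            want = min(1.0, 2 * min(lower, upper))
            _, p, _ = cn.hypergeom_enrichment(k, n_comm, K, N_tot)
            assert np.isclose(p, want)
            assert 0 < p <= 1


class TestBH:
    def test_single_p(self):
        adj, rej = cn.bh_adjust([0.04], fdr=0.05)
        assert np.isclose(adj[0], 0.04)
        assert rej[0]

    def test_hand_example(self):
        adj, _ = cn.bh_adjust([0.01, 0.02, 0.03, 0.9])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.9])

    def test_all_equal(self):
        adj, _ = cn.bh_adjust([0.2, 0.2, 0.2])
        np.testing.assert_allclose(adj, 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cn.bh_adjust([0.5, 1.2])

    def test_matches_independent_step_up(self):
        """Property check against a direct implementation of the step-up rule."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(rng.integers(1, 30))
            adj, rej = cn.bh_adjust(p, fdr=0.05)
            m = p.size
            order = np.argsort(p)
            direct = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                idx = order[rank - 1]
                running = min(running, p[idx] * m / rank)
                direct[idx] = running
            np.testing.assert_allclose(adj, direct, atol=1e-12)
            np.testing.assert_array_equal(rej, direct <= 0.05)


@pytest.fixture(scope="module")
def planted_enrichment():
    spec = cn.SyntheticSpec(n_bins=128, seed=3)
    h = cn.synth_hierarchy(spec)
    bias = {0: np.full(15, 0.01)}
    bias[0][0] = 1.0  # branch 0 heavy on S1
    track = cn.synth_chromatin_track(spec, h, state_bias=bias)
    m = cn.kr_balance(cn.synth_contact_matrix(spec, h)).scaled
    ps = cn.gamma_sweep(m, cn.default_gamma_grid(6), seed=0, restarts=5)
    domains = cn.extract_domains(ps)
    mt = cn.build_membership(ps, domains)
    return spec, track, mt, domains


class TestEnrichCommunities:
    def test_planted_state_detected_as_group_A(self, planted_enrichment):
        spec, track, mt, domains = planted_enrichment
        recs, labels = cn.enrich_communities(track, mt, domains, spec.bin_size)
        a_labels = [l for l in labels if "A" in l.groups]
        assert a_labels, "planted S1-rich branch not detected"
        enriched_states = {r.state for r in recs if r.status == "enriched"}
        assert "S1" in enriched_states

    def test_group_table(self):
        from chromnest.chromatin_enrichment import _STATE_TO_GROUPS

        assert _STATE_TO_GROUPS["S1"] == ("A",)
        assert _STATE_TO_GROUPS["S13"] == ("D",)
        assert _STATE_TO_GROUPS["S8"] == ()  # insulator: no group

    def test_zero_peak_community_flagged(self, planted_enrichment):
        spec, _, mt, domains = planted_enrichment
        empty = cn.ChromatinTrack(
            pd.DataFrame(
                [("chrS", 0, 50_000, "S1")], columns=["chrom", "start", "end", "state"]
            )
        )
        recs, labels = cn.enrich_communities(empty, mt, domains, spec.bin_size)
        assert any(l.degenerate for l in labels)


class TestGroupNestedness:
    def _labels(self, assignments):
        return [
            cn.GroupLabel(gamma=g, community=c, groups=frozenset(gr))
            for (g, c), gr in assignments.items()
        ]

    def _record(self, ki, kj, N):
        return cn.OverlapRecord(
            gamma_i=ki[0], comm_i=ki[1], gamma_j=kj[0], comm_j=kj[1],
            d_i=2, d_j=2, n=10, S=1, mu=0.4, omega=1.0, N=N, p=0.5, significant=False,
        )

    def test_only_AA_populated(self):
        labels = self._labels({(0.5, 0): "A", (0.9, 0): "A"})
        recs = [self._record((0.5, 0), (0.9, 0), 0.7)]
        out = cn.group_nestedness(recs, labels)
        assert out[("A", "A")]["union"].tolist() == [0.7]
        assert all(
            out[k]["union"].size == 0 for k in out if k != ("A", "A")
        )

    def test_intersection_plus_difference_equals_union(self):
        labels = self._labels(
            {(0.5, 0): "AB", (0.5, 1): "A", (0.9, 0): "B", (0.9, 1): "AB"}
        )
        recs = [
            self._record((0.5, c1), (0.9, c2), 0.1 * (c1 + c2 + 1))
            for c1 in (0, 1)
            for c2 in (0, 1)
        ]
        out = cn.group_nestedness(recs, labels)
        ab = out[("A", "B")]
        assert ab["intersection"].size + ab["difference"].size == ab["union"].size

    def test_planted_nested_branch_raises_AA_mean(self, hierarchy_run):
        """Communities planted on nested branches and labeled A nest more
        than the chromosome-wide average."""
        spec, _, matrix, ps, domains, mt = hierarchy_run
        recs = cn.pairwise_nestedness(mt)
        # label every community containing domain 1 as group A: these lie on
        # one root-to-leaf branch of the perfect hierarchy, hence fully nested
        labels = []
        for g in mt.gammas:
            for c in mt.communities_at(g)["community_id"].unique():
                doms = mt.domains_of(g, int(c))
                groups = frozenset("A") if 1 in doms else frozenset("B")
                labels.append(cn.GroupLabel(gamma=float(g), community=int(c), groups=groups))
        out = cn.group_nestedness(recs, labels)
        aa = out[("A", "A")]["union"]
        all_N = np.array([r.N for r in recs])
        assert aa.mean() > all_N.mean()


class TestCommunityModularity:
    def test_sum_equals_global(self, hierarchy_run):
        _, _, matrix, ps, domains, mt = hierarchy_run
        null = cn.fg_null(matrix)
        for part in ps:
            df = cn.community_modularity(matrix, null, part, mt)
            assert np.isclose(df["M_c"].sum(), part.modularity, atol=1e-9)

    def test_singleton_community_zero(self):
        a = np.ones((4, 4)) - np.eye(4)
        m = cn.ContactMatrix(a)
        null = cn.fg_null(m)
        part = cn.Partition(gamma=1.0, membership=np.array([0, 0, 0, 1]), modularity=0.0, seed=0)
        df = cn.community_modularity(m, null, part)
        assert df.loc[df.community == 1, "M_c"].item() == 0.0

    def test_hand_example(self, toy3):
        null = cn.fg_null(toy3)
        part = cn.Partition(gamma=1.0, membership=np.array([0, 0, 1]), modularity=0.0, seed=0)
        df = cn.community_modularity(toy3, null, part)
        assert np.isclose(df.loc[df.community == 0, "M_c"].item(), (1 / 6) * 2 * (1 - 1.2))
        assert df.loc[df.community == 1, "M_c"].item() == 0.0

    def test_rescaling_removes_size_trend(self, hierarchy_run):
        """|regression slope vs size| drops after dividing M_c by size."""
        _, _, matrix, ps, domains, mt = hierarchy_run
        null = cn.fg_null(matrix)
        rows = []
        for part in ps:
            rows.append(cn.community_modularity(matrix, null, part, mt))
        df = pd.concat(rows)
        df = df[df.n_domains > 0]
        raw_slope = np.polyfit(df.n_domains, df.M_c, 1)[0]
        res_slope = np.polyfit(df.n_domains, df.M_c_rescaled, 1)[0]
        assert abs(res_slope) < abs(raw_slope)

    def test_group_medians_table(self, hierarchy_run):
        _, _, matrix, ps, domains, mt = hierarchy_run
        null = cn.fg_null(matrix)
        part = ps.partitions[-1]
        df = cn.community_modularity(matrix, null, part, mt)
        labels = [
            cn.GroupLabel(gamma=part.gamma, community=int(c), groups=frozenset("A"))
            for c in df.community
        ]
        med = group_modularity_medians(df, labels)
        a_row = med[med.group == "A"].iloc[0]
        all_row = med[med.group == "all"].iloc[0]
        assert np.isclose(a_row.median_rescaled_M_c, all_row.median_rescaled_M_c)
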