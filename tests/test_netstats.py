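"""Edge-wise F tests and NBS permutation inference."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from plinet._seeding import derive_rng
from plinet.netstats import (ContrastSpec, Edge, NetworkResult, edge_f_test,
                             nbs_contrast, network_effect_size, node_degrees,
                             split_by_direction, subject_mean)


def sym_stack(rng, n, r, loc=0.5, sd=0.1):
    A = rng.normal(loc, sd, size=(n, r, r))
    A = np.abs((A + A.transpose(0, 2, 1)) / 2)
    for x in A:
        np.fill_diagonal(x, 0.0)
    return np.clip(A, 0.0, 1.0)


def add_edges(A, edges, shift):
    for i, j in edges:
        A[:, i, j] += shift
        A[:, j, i] += shift
    return A


class TestEdgeFTest:
    def test_identical_groups_zero(self, rng):
        A = sym_stack(rng, 6, 5)
        np.testing.assert_array_equal(edge_f_test(A, A.copy()), 0.0)

    def test_matches_squared_paired_t(self, rng):
        """Independent oracle: scipy's paired t, squared, edge by edge."""
        A, B = sym_stack(rng, 5, 4), sym_stack(rng, 5, 4)
        F = edge_f_test(A, B)
        for i in range(4):
            for j in range(i + 1, 4):
                t = stats.ttest_rel(A[:, i, j], B[:, i, j]).statistic
                assert F[i, j] == pytest.approx(t**2, rel=1e-10)

    def test_shift_invariance(self, rng):
        A, B = sym_stack(rng, 6, 4), sym_stack(rng, 6, 4)
        F1 = edge_f_test(A, B)
        F2 = edge_f_test(A + 0.17, B + 0.17)
        np.testing.assert_allclose(F1, F2, atol=1e-8)

    def test_pooled_conditions_use_subject_means(self, rng):
        mats = [[sym_stack(rng, 1, 4)[0] for _ in range(3)] for _ in range(5)]
        pooled = subject_mean(mats)
        assert pooled.shape == (5, 4, 4)
        np.testing.assert_allclose(pooled[2], np.mean(mats[2], axis=0))

    def test_too_few_subjects(self, rng):
        A = sym_stack(rng, 2, 4)
        with pytest.raises(ValueError, match="3 subjects"):
            edge_f_test(A, A)


class TestNbsContrast:
    def test_planted_component_recovered(self, rng):
        planted = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6)]
        A, B = sym_stack(rng, 25, 20), sym_stack(rng, 25, 20)
        add_edges(A, planted, 0.15)
        res = nbs_contrast(A, B, ContrastSpec(n_perm=1000, seed=3))
        got = {(min(e.i, e.j), max(e.i, e.j)) for e in res.edges}
        assert res.significant
        assert res.p_fwe <= 0.05
        assert len(got & set(planted)) >= 5

    def test_no_supra_edges_gives_empty_result_p_one(self, rng):
        A = sym_stack(rng, 6, 5)
        res = nbs_contrast(A, A.copy(), ContrastSpec(n_perm=50, seed=0))
        assert res.edges == []
        assert res.p_fwe == 1.0
        assert res.threshold is None

    def test_p_respects_permutation_granularity(self, rng):
        """n_perm = 10 cannot produce p below 1/10."""
        A, B = sym_stack(rng, 6, 5), sym_stack(rng, 6, 5)
        add_edges(A, [(0, 1), (1, 2)], 0.5)
        res = nbs_contrast(A, B, ContrastSpec(n_perm=10, seed=1))
        assert res.p_fwe >= 1.0 / 10

    def test_observed_sizes_monotone_in_threshold(self, rng):
        """Raising F never enlarges the supra-threshold edge set."""
        A, B = sym_stack(rng, 10, 8), sym_stack(rng, 10, 8)
        add_edges(A, [(0, 1), (1, 2)], 0.2)
        res = nbs_contrast(A, B, ContrastSpec(n_perm=20, seed=0))
        assert all(b <= a for a, b in zip(res.observed_sizes,
                                          res.observed_sizes[1:]))

    def test_roi_relabeling_invariance(self, rng):
        A, B = sym_stack(rng, 12, 8), sym_stack(rng, 12, 8)
        add_edges(A, [(0, 1), (1, 2), (2, 3)], 0.2)
        spec = ContrastSpec(n_perm=500, seed=9)
        res = nbs_contrast(A, B, spec)
        perm = np.random.default_rng(4).permutation(8)
        Ap = A[:, perm][:, :, perm]
        Bp = B[:, perm][:, :, perm]
        res_p = nbs_contrast(Ap, Bp, spec)
        assert res_p.p_fwe == res.p_fwe
        assert res_p.n_edges == res.n_edges

    def test_max_edges_truncation(self, rng):
        A, B = sym_stack(rng, 10, 8), sym_stack(rng, 10, 8)
        comp = [(i, j) for i in range(6) for j in range(i + 1, 6)]
        add_edges(A, comp, 0.4)
        res = nbs_contrast(A, B, ContrastSpec(n_perm=200, seed=2, max_edges=5))
        assert res.n_edges == 5
        fs = [e.f for e in res.edges]
        assert fs == sorted(fs, reverse=True)

    def test_exact_permutation_matches_enumeration_oracle(self, rng):
        """For n <= 6 the exact null equals brute-force enumeration of all
        2^n sign flips, computed independently with scipy + networkx."""
        n, r = 5, 6
        A, B = sym_stack(rng, n, r), sym_stack(rng, n, r)
        add_edges(A, [(0, 1), (1, 2)], 0.25)
        spec = ContrastSpec(n_perm=1, permutations="exact", seed=0,
                            f_range=(3.0, 10.0), f_step=0.5)
        res = nbs_contrast(A, B, spec)

        thresholds = spec.thresholds()
        D = A - B
        oracle = np.zeros((2**n, thresholds.size), dtype=int)
        for p_idx, signs in enumerate(itertools.product([1.0, -1.0], repeat=n)):
            Ds = D * np.array(signs)[:, None, None]
            mean = Ds.mean(axis=0)
            sd = Ds.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                F = n * mean**2 / sd**2
            F = np.nan_to_num(F)
            for t_idx, thr in enumerate(thresholds):
                g = nx.Graph()
                ii, jj = np.where(np.triu(F, 1) >= thr)
                g.add_edges_from(zip(ii, jj))
                if g.number_of_edges():
                    oracle[p_idx, t_idx] = max(
                        g.subgraph(c).number_of_edges()
                        for c in nx.connected_components(g))
        # identical multiset of maximal component sizes at every threshold
        obs_sizes = res.meta["null_sizes"]
        for t_idx in range(thresholds.size):
            assert sorted(obs_sizes[:, t_idx]) == sorted(oracle[:, t_idx])

    def test_exchangeable_null_rank_uniform(self):
        """Under within-subject swaps of null data the observed statistic is
        a draw from its own permutation null (no systematic extremeness)."""
        ranks = []
        for rep in range(40):
            rng = derive_rng(5, "rank", rep)
            A, B = sym_stack(rng, 8, 6), sym_stack(rng, 8, 6)
            res = nbs_contrast(A, B, ContrastSpec(n_perm=200, seed=rep))
            # rank of observed min-p within null min-p values is encoded in
            # p_fwe: uniform p values on (0, 1] under the null
            ranks.append(res.p_fwe)
        assert np.mean(ranks) > 0.3        # not systematically extreme
        assert min(ranks) >= 1.0 / 200


class TestDirectionSplit:
    def result_with(self, diffs):
        edges = [Edge(i, i + 1, 5.0, d) for i, d in enumerate(diffs)]
        return NetworkResult(threshold=3.0, edges=edges, p_fwe=0.01,
                             labels=[f"R{k}" for k in range(len(diffs) + 1)],
                             alpha=0.05, thresholds=np.array([3.0]),
                             p_per_threshold=np.array([0.01]),
                             observed_sizes=np.array([len(diffs)]))

    def test_all_positive(self):
        up, down = split_by_direction(self.result_with([0.1, 0.2, 0.3]))
        assert len(up) == 3 and down == []

    def test_three_up_two_down(self):
        res = self.result_with([0.1, -0.2, 0.3, -0.4, 0.5])
        up, down = split_by_direction(res)
        assert len(up) == 3 and len(down) == 2
        assert set(up) | set(down) == set(res.edges)
        assert set(up) & set(down) == set()

    def test_sign_flip_swaps_subnetworks(self):
        diffs = [0.1, -0.2, 0.3]
        up1, down1 = split_by_direction(self.result_with(diffs))
        up2, down2 = split_by_direction(self.result_with([-d for d in diffs]))
        assert {(e.i, e.j) for e in up1} == {(e.i, e.j) for e in down2}
        assert {(e.i, e.j) for e in down1} == {(e.i, e.j) for e in up2}

    def test_empty_network_rejected(self):
        res = self.result_with([0.1])
        res.edges = []
        with pytest.raises(ValueError):
            split_by_direction(res)


class TestDegreesAndEffectSize:
    def test_star_graph(self):
        edges = [Edge(0, k, 4.0, 0.1) for k in range(1, 5)]
        deg = node_degrees(edges, n_rois=5)
        assert deg[0] == 4
        assert all(deg[k] == 1 for k in range(1, 5))

    def test_empty_network_all_zero(self):
        assert node_degrees([], n_rois=4).sum() == 0

    def test_toy_network_hand_count(self):
        pairs = [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4), (5, 6)]
        edges = [Edge(i, j, 4.0, 0.1) for i, j in pairs]
        deg = node_degrees(edges, n_rois=7)
        assert list(deg) == [2, 2, 3, 2, 1, 1, 1]

    def test_lobe_summary(self):
        edges = [Edge(0, 1, 4.0, 0.1), Edge(1, 2, 4.0, 0.1)]
        deg, lobes = node_degrees(edges, n_rois=4,
                                  lobe_map=["frontal", "frontal",
                                            "parietal", "parietal"])
        assert lobes["frontal"]["connections"] == 3
        assert lobes["parietal"]["connections"] == 1
        assert lobes["frontal"]["percent"] == pytest.approx(75.0)

    def test_cohens_d_closed_form(self):
        """Paired differences [0.5, 1.0, 1.5]: mean 1, sd 0.5, d = 2."""
        B = np.zeros((3, 2, 2))
        A = B.copy()
        for s, d in enumerate([0.5, 1.0, 1.5]):
            A[s, 0, 1] = A[s, 1, 0] = d
        d_val = network_effect_size(A, B, [Edge(0, 1, 9.0, 1.0)])
        assert d_val == pytest.approx(2.0)

    def test_identical_groups_zero_d(self, rng):
        A = sym_stack(rng, 4, 3)
        B = A + 1e-9 * rng.standard_normal(A.shape)  # avoid zero variance
        d_val = network_effect_size(A, B, [Edge(0, 1, 9.0, 0.0)])
        assert abs(d_val) < 1.0

    def test_sign_flip_negates_d(self, rng):
        A, B = sym_stack(rng, 5, 3), sym_stack(rng, 5, 3)
        e = [Edge(0, 1, 9.0, 0.1)]
        assert network_effect_size(A, B, e) == pytest.approx(
            -network_effect_size(B, A, e))

    def test_zero_variance_rejected(self):
        A = np.zeros((3, 2, 2))
        B = A.copy()
        with pytest.raises(ZeroDivisionError):
            network_effect_size(A, B, [Edge(0, 1, 9.0, 0.0)])
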