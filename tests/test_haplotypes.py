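"""Haplotype deconvolution, heterozygosity, distances, network."""

import warnings
from itertools import combinations, permutations, product

import numpy as np
import pytest

from rdnavar.haplotypes import (build_network, capped_haplotype_count,
                                deconvolve, expected_heterozygosity,
                                haplotype_cap, he_cn_regression,
                                pairwise_differences, select_k, simplex_lstsq,
                                _p_step, _sse)
from rdnavar.simulate import (SimConfig, make_haplotypes,
                              simulate_frequency_matrix)


def rows_match(H_a, H_b):
    return {tuple(r) for r in H_a} == {tuple(r) for r in H_b}


def aligned_p_rmse(model, H_true, P_true):
    for perm in permutations(range(H_true.shape[0])):
        if np.array_equal(model.H[list(perm)], H_true):
            return float(np.sqrt(((model.P[:, list(perm)] - P_true) ** 2).mean()))
    return np.inf


class TestCapRule:
    @pytest.mark.parametrize("S,cap", [(25, 4), (42, 5), (16, 4), (2, 1)])
    def test_log2_floor(self, S, cap):
        assert haplotype_cap(S) == cap

    def test_anticipated_count_capped(self):
        assert capped_haplotype_count(10, 25) == 4
        assert capped_haplotype_count(3, 25) == 3

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            haplotype_cap(1)


class TestSimplexLstsq:
    def test_interior_solution_matches_unconstrained(self, rng):
        A = rng.normal(size=(8, 3))
        p_true = np.array([0.5, 0.3, 0.2])
        p = simplex_lstsq(A, A @ p_true)
        assert np.allclose(p, p_true, atol=1e-9)

    def test_boundary_solution_is_global_optimum(self, rng):
        # target far outside the simplex face forces active constraints;
        # compare against a dense grid over the 2-simplex
        A = rng.normal(size=(6, 3))
        f = A @ np.array([2.0, -0.5, -0.5])
        p = simplex_lstsq(A, f)
        best = np.inf
        for a in np.linspace(0, 1, 101):
            for b in np.linspace(0, 1 - a, int(101 * (1 - a)) + 1):
                q = np.array([a, b, 1 - a - b])
                best = min(best, float(((f - A @ q) ** 2).sum()))
        achieved = float(((f - A @ p) ** 2).sum())
        assert achieved <= best + 1e-6
        assert p.min() >= 0 and p.sum() == pytest.approx(1.0)


class TestDeconvolve:
    def test_k1_pure_samples_exact(self):
        v = np.array([1, 0, 1, 1, 0, 0], dtype=float)
        F = np.tile(v, (5, 1))
        model = deconvolve(F, 1, n_restarts=3, seed=0)
        assert model.K == 1 and model.sse == pytest.approx(0.0, abs=1e-12)
        assert np.array_equal(model.H[0], v.astype(int))
        assert np.allclose(model.P, 1.0)

    def test_noiseless_k2_matches_exhaustive_oracle(self, rng):
        """Exact recovery of a noiseless 2-haplotype mixture, verified
        against brute force over all 4^6 binary column assignments."""
        H_true = np.array([[0, 1, 0, 1, 1, 0], [1, 0, 0, 1, 0, 1]], dtype=np.int8)
        P_true = np.column_stack([np.linspace(0.1, 0.9, 10)])
        P_true = np.hstack([P_true, 1 - P_true])
        F = P_true @ H_true
        model = deconvolve(F, 2, n_restarts=10, seed=1)
        assert rows_match(model.H, H_true)
        assert aligned_p_rmse(model, H_true, P_true) < 1e-6
        # oracle: enumerate every K=2 binary matrix column by column
        observed = np.ones_like(F, dtype=bool)
        best_sse = np.inf
        for cols in product(range(4), repeat=6):
            H_cand = np.array([[(c >> 1) & 1 for c in cols],
                               [c & 1 for c in cols]], dtype=np.int8)
            P_cand = _p_step(F, H_cand, observed)
            best_sse = min(best_sse, _sse(F, P_cand, H_cand, observed))
        assert model.sse <= best_sse + 1e-9

    def test_simulated_sx_scale_recovery(self):
        cfg = SimConfig()  # K=4, S=25
        F, P_true, H_true = simulate_frequency_matrix(cfg, 35, seed=2)
        model = deconvolve(F, 4, n_restarts=20, seed=2)
        assert rows_match(model.H, H_true)
        assert aligned_p_rmse(model, H_true, P_true) < 0.02

    def test_p_rows_on_simplex_and_sse_nonnegative(self):
        cfg = SimConfig()
        F, _, _ = simulate_frequency_matrix(cfg, 20, seed=3)
        model = deconvolve(F, 3, n_restarts=5, seed=3)
        assert np.allclose(model.P.sum(axis=1), 1.0, atol=1e-9)
        assert (model.P >= -1e-12).all()
        assert model.sse >= 0

    def test_missing_cells_masked_not_imputed(self):
        cfg = SimConfig()
        F, P_true, H_true = simulate_frequency_matrix(cfg, 25, seed=4)
        F_missing = F.copy()
        rng = np.random.default_rng(4)
        holes = rng.random(F.shape) < 0.1
        F_missing[holes] = np.nan
        model = deconvolve(F_missing, 4, n_restarts=20, seed=4)
        assert rows_match(model.H, H_true)

    def test_label_permutation_equivalence(self):
        cfg = SimConfig()
        F, _, _ = simulate_frequency_matrix(cfg, 15, seed=5)
        m = deconvolve(F, 3, n_restarts=5, seed=5)
        perm = [2, 0, 1]
        observed = ~np.isnan(F)
        assert _sse(np.nan_to_num(F), m.P[:, perm], m.H[perm], observed) == \
            pytest.approx(m.sse)

    def test_canonical_order_decreasing_mean_frequency(self):
        cfg = SimConfig()
        F, _, _ = simulate_frequency_matrix(cfg, 25, seed=6)
        m = deconvolve(F, 4, n_restarts=10, seed=6)
        means = m.P.mean(axis=0)
        assert (np.diff(means) <= 1e-9).all()

    def test_rank_deficient_p_flagged(self):
        # identical composition in every sample: mixtures indistinguishable
        H_true = np.array([[0, 1, 0, 1, 1, 0], [1, 0, 0, 1, 0, 1]], dtype=np.int8)
        P_true = np.tile([0.6, 0.4], (8, 1))
        F = P_true @ H_true
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = deconvolve(F, 2, n_restarts=5, seed=7)
        assert model.rank_deficient or model.K == 1

    def test_constant_matrix_collapses_to_single_haplotype(self):
        F = np.zeros((6, 8))
        with pytest.warns(UserWarning):
            model = deconvolve(F, 3, n_restarts=2, seed=8)
        assert model.K == 1

    def test_impossible_k_rejected(self):
        with pytest.raises(ValueError):
            deconvolve(np.zeros((4, 2)), 5)

    def test_recovery_degrades_with_noise(self):
        cfg = SimConfig()
        rmses = []
        for sigma in (0.005, 0.01, 0.05):
            vals = []
            for seed in range(5):
                F, P_true, H_true = simulate_frequency_matrix(
                    cfg, 35, seed=100 + seed, noise_sd=sigma)
                m = deconvolve(F, 4, n_restarts=10, seed=seed)
                if rows_match(m.H, H_true):
                    vals.append(aligned_p_rmse(m, H_true, P_true))
                else:
                    vals.append(0.5)
            rmses.append(np.mean(vals))
        assert rmses[0] < rmses[2]


class TestSelectK:
    def test_recovers_simulated_component_count(self):
        cfg = SimConfig()
        F, _, _ = simulate_frequency_matrix(cfg, 35, seed=9)
        assert select_k(F, seed=9) == 4

    def test_cap_binds_for_many_haplotypes(self):
        # 5 true haplotypes but only 16 sites -> cap 4 binds
        cfg = SimConfig(n_haplotypes=5, n_snps=16,
                        block_structure=None, progenitor_haploid_cn=190)
        F, _, _ = simulate_frequency_matrix(cfg, 30, seed=10)
        assert select_k(F, seed=10) <= 4


class TestHeterozygosity:
    @pytest.mark.parametrize("p,expected", [
        ((1.0,), 0.0),
        ((0.25, 0.25, 0.25, 0.25), 0.75),
        ((0.5, 0.3, 0.2), 0.62),
    ])
    def test_direct_values(self, p, expected):
        assert expected_heterozygosity(p) == pytest.approx(expected)

    def test_bounded_by_uniform_maximum(self, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(4))
            he = expected_heterozygosity(p)
            assert 0 <= he <= 0.75 + 1e-12

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError):
            expected_heterozygosity([0.5, 0.2])


class TestHeCnRegression:
    def test_constant_he_zero_slope(self):
        res = he_cn_regression([0.5, 0.5, 0.5, 0.5], [300, 400, 500, 600])
        assert res["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_minor_haplotype_expansion_yields_positive_slope(self, rng):
        """When gains preferentially duplicate the minor haplotype, higher
        copy number means a more even pool, hence positive He~CN slope."""
        signs = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            cn = r.uniform(300, 700, size=30)
            minor = 0.1 + 0.3 * (cn - 300) / 400  # minor expands with cn
            he = [expected_heterozygosity([1 - m, m]) for m in minor]
            res = he_cn_regression(he, cn)
            signs += res["slope"] > 0
        assert signs >= 19

    def test_haplotype_blind_gains_give_null_slope(self):
        """Gains that copy haplotypes proportionally leave He unrelated to
        copy number; the slope should rarely reach significance."""
        non_sig = 0
        for rep in range(20):
            r = np.random.default_rng(1000 + rep)
            cn = r.uniform(300, 700, size=30)
            p_minor = np.clip(r.normal(0.3, 0.02, size=30), 0, 1)
            he = [expected_heterozygosity([1 - m, m]) for m in p_minor]
            res = he_cn_regression(he, cn)
            non_sig += res["p"] >= 0.05
        assert non_sig >= 18


class TestPairwiseDifferences:
    def test_small_matrix_by_hand(self):
        H = np.array([[0, 0, 0, 1], [0, 1, 1, 0]])
        D, stats = pairwise_differences(H)
        assert D[0, 1] == 3 and stats["mean"] == 3.0

    def test_complement_pair_distance_is_s(self):
        H = np.array([[0, 1, 0, 1, 1], [1, 0, 1, 0, 0]])
        D, _ = pairwise_differences(H)
        assert D[0, 1] == 5

    def test_matches_bitcount_oracle(self):
        H = make_haplotypes(5, 42, seed=11)
        D, _ = pairwise_differences(H)
        for i, j in combinations(range(5), 2):
            expected = int(np.bitwise_xor(H[i], H[j]).sum())
            assert D[i, j] == D[j, i] == expected


class TestBuildNetwork:
    def test_two_haplotypes_single_edge(self):
        D = np.array([[0, 4], [4, 0]])
        assert build_network(D) == [(0, 1, 4)]

    def test_equilateral_triangle_keeps_all_ties(self):
        D = np.full((3, 3), 7)
        np.fill_diagonal(D, 0)
        assert len(build_network(D)) == 3

    def _all_mst_union(self, D):
        K = D.shape[0]
        edges = [(i, j) for i in range(K) for j in range(i + 1, K)]
        best_w, union = np.inf, set()
        for tree in combinations(edges, K - 1):
            parent = list(range(K))

            def find(a):
                while parent[a] != a:
                    a = parent[a]
                return a

            ok = True
            for u, v in tree:
                ru, rv = find(u), find(v)
                if ru == rv:
                    ok = False
                    break
                parent[ru] = rv
            if not ok:
                continue
            w = sum(D[u, v] for u, v in tree)
            if w < best_w - 1e-12:
                best_w, union = w, set(tree)
            elif w == best_w:
                union |= set(tree)
        return union

    def test_matches_bruteforce_union_of_all_msts(self, rng):
        for trial in range(5):
            r = np.random.default_rng(trial)
            vals = r.integers(1, 6, size=(5, 5))
            D = np.triu(vals, 1)
            D = D + D.T
            got = {(u, v) for u, v, _ in build_network(D)}
            assert got == self._all_mst_union(D)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1], [2, 0]])
        with pytest.raises(ValueError):
            build_network(D)
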