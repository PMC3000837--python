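"""Pooled SNP-BLUP: pools, normal-equation reconstruction, GEBVs."""

import numpy as np
import pytest
from scipy import linalg

from poolgs import pooling
from poolgs.pooling import (
    bias_regression_b,
    effective_pool_size,
    estimate_xtx,
    form_pools,
    gebv_marker_only,
    gebv_with_group_mean,
    ridge_lambda,
    solve_marker_effects,
    standardize_genotypes,
    standardized_pool_delta,
)


def random_pool_dataset(rng, n_groups=3, group_size=20, n_markers=8):
    """Random individual-level dataset: dosages, continuous phenotypes,
    group labels with equal even-sized groups."""
    n = n_groups * group_size
    dosage = rng.integers(0, 3, size=(n, n_markers)).astype(np.int16)
    phen = rng.permutation(n).astype(np.float64)  # unique, no ties
    group = np.repeat(np.arange(n_groups), group_size)
    return dosage, phen, group


def pooled_within_group_covariance(x, phen, group):
    """Brute-force oracle: covariance (1/n) between standardized genotype
    and the 0/1 H-pool label, pooled over groups weighted by group size."""
    n = phen.size
    cov = np.zeros(x.shape[1])
    for g in np.unique(group):
        idx = np.flatnonzero(group == g)
        half = idx.size // 2
        order = idx[np.argsort(-phen[idx])]
        y = np.zeros(idx.size)
        y[:half] = 1.0  # the H-pool members
        xg = x[order]
        cov += idx.size * np.mean(
            (xg - xg.mean(axis=0)) * (y - y.mean())[:, None], axis=0
        )
    return cov / n


class TestPools:
    def test_hand_enumerated_four_individual_group(self):
        # phenotypes {3,1,4,2}; H-pool = {4,3} = individuals 2 and 0 with
        # dosages {1, 0} -> freq_H = 1/4; L-pool dosages {2, 1} -> 3/4
        dosage = np.array([[0], [1], [1], [2]], dtype=np.int16)
        phen = np.array([3.0, 1.0, 4.0, 2.0])
        pools = form_pools(phen, np.zeros(4, dtype=int), dosage)
        assert pools.freq_h[0, 0] == pytest.approx(0.25)
        assert pools.freq_l[0, 0] == pytest.approx(0.75)
        assert pools.pool_size[0] == 2

    def test_pool_mean_equals_group_frequency_without_noise(self):
        rng = np.random.default_rng(0)
        dosage, phen, group = random_pool_dataset(rng)
        pools = form_pools(phen, group, dosage)
        for gi, g in enumerate(pools.group_ids):
            idx = group == g
            overall = dosage[idx].mean(axis=0) / 2.0
            assert np.allclose(0.5 * (pools.freq_h[gi] + pools.freq_l[gi]), overall)

    def test_all_equal_phenotypes_split_by_id(self):
        dosage = np.zeros((4, 1), dtype=np.int16)
        pools = form_pools(np.ones(4), np.zeros(4, dtype=int), dosage)
        assert pools.pool_size[0] == 2  # deterministic id tie-break

    def test_odd_group_size_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            form_pools(np.arange(3.0), np.zeros(3, dtype=int), np.zeros((3, 1), np.int16))

    def test_global_scope_forms_one_pool_pair(self):
        rng = np.random.default_rng(1)
        dosage, phen, group = random_pool_dataset(rng)
        pools = form_pools(phen, group, dosage, scope="global")
        assert pools.group_ids.size == 1
        assert pools.test_count[0] == phen.size

    def test_technical_noise_stays_in_unit_interval(self):
        rng = np.random.default_rng(2)
        dosage, phen, group = random_pool_dataset(rng)
        pools = form_pools(phen, group, dosage, vt=0.05, m=2, rng=rng)
        assert np.all((pools.freq_h >= 0) & (pools.freq_h <= 1))
        assert pools.vt == 0.05 and pools.m == 2


class TestPoolDelta:
    def test_single_group_arithmetic(self):
        pools = pooling.PoolSummary(
            group_ids=np.array([0]),
            freq_h=np.array([[0.6]]),
            freq_l=np.array([[0.4]]),
            pool_size=np.array([10]),
        )
        dx = standardized_pool_delta(pools, np.array([0.5]))
        assert dx[0] == pytest.approx(2 * 0.2 / np.sqrt(0.5))

    def test_zero_when_pools_identical(self):
        pools = pooling.PoolSummary(
            group_ids=np.array([0, 1]),
            freq_h=np.full((2, 3), 0.3),
            freq_l=np.full((2, 3), 0.3),
            pool_size=np.array([5, 5]),
        )
        assert np.all(standardized_pool_delta(pools, np.full(3, 0.3)) == 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_quarter_delta_equals_pooled_covariance_exactly(self, seed):
        # 0.25 * dx (standardized) is the within-group-pooled covariance
        # between standardized genotype and the 0/1 pool label
        rng = np.random.default_rng(seed)
        dosage, phen, group = random_pool_dataset(
            rng, n_groups=rng.integers(1, 4), group_size=2 * rng.integers(2, 15)
        )
        p = dosage.mean(axis=0) / 2.0
        pools = form_pools(phen, group, dosage)
        dx = standardized_pool_delta(pools, p)
        x = standardize_genotypes(dosage, p)
        oracle = pooled_within_group_covariance(x, phen, group)
        assert np.allclose(0.25 * dx, oracle, atol=1e-12)

    def test_group_shift_immunity(self):
        # adding a constant to one group's phenotypes changes nothing
        rng = np.random.default_rng(9)
        dosage, phen, group = random_pool_dataset(rng)
        p = dosage.mean(axis=0) / 2.0
        dx1 = standardized_pool_delta(form_pools(phen, group, dosage), p)
        shifted = phen + np.where(group == 1, 1000.0, 0.0)
        dx2 = standardized_pool_delta(form_pools(shifted, group, dosage), p)
        assert np.allclose(dx1, dx2)


class TestNormalEquations:
    def test_homozygote_split_diagonal(self):
        # candidates split 50/50 between the homozygotes at p = 0.5: the
        # standardized codes are +-sqrt(2), so Var = 2 and X'X = 2 n_test
        dosage = np.array([[0], [2]] * 10, dtype=np.int16)
        xtx = estimate_xtx(dosage, np.array([0.5]), n_test=1000)
        code_var = np.var([np.sqrt(2), -np.sqrt(2)])
        assert xtx[0, 0] == pytest.approx(1000 * code_var)

    def test_duplicated_marker_off_diagonal_is_geometric_mean(self):
        rng = np.random.default_rng(4)
        col = rng.integers(0, 3, size=(30, 1)).astype(np.int16)
        dosage = np.hstack([col, col])
        p = dosage.mean(axis=0) / 2.0
        xtx = estimate_xtx(dosage, p, n_test=100)
        assert xtx[0, 1] == pytest.approx(np.sqrt(xtx[0, 0] * xtx[1, 1]))

    def test_monomorphic_marker_zeroed(self):
        dosage = np.array([[0, 1], [0, 2], [0, 0], [0, 1]], dtype=np.int16)
        p = dosage.mean(axis=0) / 2.0
        xtx = estimate_xtx(dosage, p, n_test=10)
        assert xtx[0, 0] == 0 and xtx[0, 1] == 0

    def test_requires_two_candidates(self):
        with pytest.raises(ValueError):
            estimate_xtx(np.zeros((1, 3), np.int16), np.full(3, 0.5), 10)

    def test_ridge_parameter_liability_conversion(self):
        # h2 = 0.4, 10 000 markers: lambda ~ 29 270 on the 0/1 scale
        assert ridge_lambda(0.4, 10_000) == pytest.approx(29_270, rel=1e-3)

    def test_ridge_parameter_scales_with_marker_count(self):
        assert ridge_lambda(0.4, 2000) == pytest.approx(2 * ridge_lambda(0.4, 1000))

    def test_ridge_parameter_vanishes_as_direct_h2_approaches_one(self):
        lams = [ridge_lambda(h2, 100, mode="direct") for h2 in (0.5, 0.9, 0.999)]
        assert lams[0] > lams[1] > lams[2]
        assert lams[2] < 0.11
        with pytest.raises(ValueError):
            ridge_lambda(1.0, 100, mode="direct")

    def test_diagonal_solve_closed_form(self):
        # C = I, n = 100, lambda = 100: a_1 = 100*0.25*0.4/(100+100) = 0.05
        xtx = 100 * np.eye(2)
        a = solve_marker_effects(xtx, np.array([0.4, 0.0]), 100.0, n_test=100)
        assert np.allclose(a, [0.05, 0.0])

    def test_zero_delta_gives_zero_effects(self):
        a = solve_marker_effects(np.eye(3) * 50, np.zeros(3), 10.0, n_test=50)
        assert np.all(a == 0)

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError):
            solve_marker_effects(np.eye(2), np.array([np.nan, 0.0]), 1.0, 10)

    def test_pooled_reconstruction_equals_direct_ridge_when_candidates_are_tests(self):
        # when the genotyped candidates ARE the test individuals, the pooled
        # reconstruction must reproduce the individual-genotype ridge
        # solution exactly (the covariance identity is exact)
        rng = np.random.default_rng(12)
        n, m = 2000, 50
        p_true = rng.uniform(0.1, 0.9, m)
        dosage = rng.binomial(2, p_true, size=(n, m)).astype(np.int16)
        beta = rng.normal(0, 0.1, m)
        phen = dosage @ beta + rng.normal(0, 1.0, n)
        group = np.zeros(n, dtype=int)
        p = dosage.mean(axis=0) / 2.0
        lam = ridge_lambda(0.4, m)

        pools = form_pools(phen, group, dosage)
        dx = standardized_pool_delta(pools, p)
        a_pooled = solve_marker_effects(estimate_xtx(dosage, p, n), dx, lam, n)

        x = standardize_genotypes(dosage, p)
        xc = x - x.mean(axis=0)
        order = np.argsort(-phen)
        y = np.zeros(n)
        y[order[: n // 2]] = 1.0
        yc = y - y.mean()
        a_direct = linalg.solve(xc.T @ xc + lam * np.eye(m), xc.T @ yc, assume_a="pos")
        assert np.allclose(a_pooled, a_direct, atol=1e-10)

    def test_shrinkage_monotonically_reduces_effect_norm(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(60, 10))
        xtx = x.T @ x
        dx = rng.normal(size=10) * 0.1
        norms = [
            np.linalg.norm(solve_marker_effects(xtx, dx, lam, 60))
            for lam in (1.0, 10.0, 100.0, 1000.0)
        ]
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_marker_determined_trait_is_predicted_accurately(self):
        # all causal variants on the panel, h2 = 1, one large group: the
        # estimated GEBV should rank candidates almost perfectly
        rng = np.random.default_rng(14)
        n_test, n_cand, m = 20_000, 1000, 50
        p_true = rng.uniform(0.2, 0.8, m)
        beta = rng.normal(0, 1.0, m)
        test_dos = rng.binomial(2, p_true, size=(n_test, m)).astype(np.int16)
        cand_dos = rng.binomial(2, p_true, size=(n_cand, m)).astype(np.int16)
        phen = test_dos @ beta  # fully genetic
        p = cand_dos.mean(axis=0) / 2.0
        pools = form_pools(phen, np.zeros(n_test, dtype=int), test_dos)
        dx = standardized_pool_delta(pools, p)
        lam = ridge_lambda(0.999, m, mode="direct")
        a = solve_marker_effects(estimate_xtx(cand_dos, p, n_test), dx, lam, n_test)
        scores = standardize_genotypes(cand_dos, p) @ a
        tbv = cand_dos @ beta
        assert np.corrcoef(scores, tbv)[0, 1] > 0.9


class TestGebv:
    def test_bias_regression_recovers_known_slopes(self):
        tbv = np.array([1.0, 2.0, 3.0, 4.0])
        assert bias_regression_b(tbv, tbv) == pytest.approx(1.0)
        assert bias_regression_b(2 * tbv, tbv) == pytest.approx(0.5)
        # hand least squares: scores 1..4 against TBV (1,1,3,3) -> 0.8
        assert bias_regression_b(tbv, np.array([1.0, 1.0, 3.0, 3.0])) == pytest.approx(0.8)

    def test_zero_score_variance_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert bias_regression_b(np.ones(5), np.arange(5.0)) == 0.0

    def test_marker_only_equation_arithmetic(self):
        # one marker, a = 0.1, homozygous derived at p = 0.5:
        # X = 2(1-p)/sqrt(H) = sqrt(2), GEBV = 0.1*sqrt(2)
        x = standardize_genotypes(np.array([[2]], dtype=np.int16), np.array([0.5]))
        score = (x @ np.array([0.1]))[0]
        res = gebv_marker_only(np.array([score]), b=1.0, group=np.array([0]))
        assert res.gebv[0] == pytest.approx(0.1 * np.sqrt(2))

    def test_zero_effects_give_zero_gebv(self):
        res = gebv_marker_only(np.zeros(4), b=0.7, group=np.zeros(4))
        assert np.all(res.gebv == 0)

    def test_group_mean_equation_centers_on_phenotype_mean(self):
        rng = np.random.default_rng(20)
        scores = rng.normal(size=12)
        group = np.repeat([0, 1], 6)
        mu_p = {0: 3.0, 1: -1.0}
        res = gebv_with_group_mean(scores, b=0.6, group=group, group_phen_mean=mu_p)
        for g, mu in mu_p.items():
            assert res.gebv[group == g].mean() == pytest.approx(mu)

    def test_zero_b_reduces_to_between_group_selection(self):
        scores = np.arange(6.0)
        group = np.repeat([0, 1], 3)
        res = gebv_with_group_mean(scores, 0.0, group, {0: 1.0, 1: 2.0})
        assert np.allclose(res.gebv, np.where(group == 0, 1.0, 2.0))

    def test_single_group_equations_differ_by_constant(self):
        rng = np.random.default_rng(21)
        scores = rng.normal(size=10)
        group = np.zeros(10, dtype=int)
        eq2 = gebv_marker_only(scores, 0.8, group)
        eq3 = gebv_with_group_mean(scores, 0.8, group, {0: 5.0})
        diff = eq3.gebv - eq2.gebv
        assert np.allclose(diff, diff[0])
        assert np.array_equal(np.argsort(eq2.gebv), np.argsort(eq3.gebv))


class TestEffectivePoolSize:
    def test_no_technical_error_returns_pool_count(self):
        assert effective_pool_size(500, 0.0, 0.3) == pytest.approx(500)

    def test_reported_plugin_value(self):
        # N = 10 000, Vt = 6.8e-5, p = 0.5, m = 1 -> ~2688
        assert effective_pool_size(10_000, 6.8e-5, 0.5) == pytest.approx(2688, rel=1e-3)

    def test_large_pool_limit_set_by_technical_error(self):
        limit = 0.5 * 0.5 * 2 / 1e-4
        assert effective_pool_size(10**9, 1e-4, 0.5, m=2) == pytest.approx(limit, rel=1e-3)

    def test_degenerate_frequency_rejected(self):
        with pytest.raises(ValueError):
            effective_pool_size(100, 1e-4, 1.0)
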