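"""Combined-matrix eigenvalues and the three comparison tests."""

import math

import numpy as np
import pytest
from scipy import stats

from covfun import (
    BandwidthSpec,
    combined_matrix,
    forkman_test,
    permutation_test,
    significance_trace,
    simlab,
    tracy_widom_test,
    tw_centering_scaling,
)
from covfun import _tw, cmptest
from covfun.exceptions import (
    InvalidParameterError,
    LogitDomainError,
    SingularMatrixError,
)


def _random_psd(rng, p, scale=1.0):
    A = rng.standard_normal((p, p))
    return scale * (A @ A.T / p + 0.1 * np.eye(p))


class TestCombinedMatrix:
    def test_equal_covariances_equal_sizes_give_half(self, rng):
        S = _random_psd(rng, 3)
        ce = combined_matrix(S, S, 200, 200)
        np.testing.assert_allclose(ce.eigenvalues, 0.5, atol=1e-12)

    def test_equal_covariances_unbalanced_sizes(self, rng):
        S = _random_psd(rng, 2)
        ce = combined_matrix(S, S, 100, 300)
        np.testing.assert_allclose(ce.eigenvalues, 0.75, atol=1e-12)

    def test_two_by_two_diagonal_oracle(self):
        # S0 = I, S1 = diag(2, 1), n0 = n1: eigenvalues 2/(1+2) and 1/(1+1)
        ce = combined_matrix(np.eye(2), np.diag([2.0, 1.0]), 50, 50)
        np.testing.assert_allclose(ce.eigenvalues, [2.0 / 3.0, 0.5], atol=1e-12)

    def test_trace_identity_and_range(self, rng):
        for _ in range(20):
            p = rng.integers(2, 5)
            S0 = _random_psd(rng, p)
            S1 = _random_psd(rng, p, scale=float(rng.uniform(0.2, 3)))
            n0, n1 = int(rng.integers(20, 500)), int(rng.integers(20, 500))
            ce = combined_matrix(S0, S1, n0, n1)
            assert np.all(ce.eigenvalues >= 0) and np.all(ce.eigenvalues <= 1)
            assert np.trace(ce.Z) == pytest.approx(ce.eigenvalues.sum(), abs=1e-10)
            assert np.all(np.diff(ce.eigenvalues) <= 1e-12)  # descending

    def test_whitened_route_agrees_with_naive_inverse(self, rng):
        for p in (2, 3):
            S0 = _random_psd(rng, p)
            S1 = _random_psd(rng, p)
            ce = combined_matrix(S0, S1, 80, 120)
            naive = np.sort(
                np.linalg.eigvals(np.linalg.solve(80 * S0 + 120 * S1, 120 * S1)).real
            )[::-1]
            np.testing.assert_allclose(ce.eigenvalues, naive, atol=1e-10)

    def test_singular_combined_matrix_rejected(self):
        Z = np.zeros((2, 2))
        with pytest.raises(SingularMatrixError):
            combined_matrix(Z, Z, 10, 10)


class TestTWParams:
    def test_matches_longhand_evaluation(self):
        # frozen from an independent longhand evaluation, p=2, n0=n1=500
        params = tw_centering_scaling(2, 500, 500)
        assert params.gamma == pytest.approx(0.07751783294544871, rel=1e-12)
        assert params.phi == pytest.approx(1.5707963267948968, rel=1e-12)
        assert params.mu == pytest.approx(0.15519116814372, rel=1e-12)
        assert params.sigma == pytest.approx(0.059275911218167346, rel=1e-12)

    def test_sigma_decreases_with_total_sample_size(self):
        sigmas = [tw_centering_scaling(2, n, n).sigma for n in (50, 100, 500, 2000)]
        assert np.all(np.diff(sigmas) < 0)

    def test_equal_sizes_invariant_to_group_swap(self):
        a = tw_centering_scaling(3, 400, 400)
        b = tw_centering_scaling(3, 400, 400)
        assert (a.mu, a.sigma) == (b.mu, b.sigma)

    def test_domain_violation_rejected(self):
        with pytest.raises(InvalidParameterError):
            tw_centering_scaling(5, 3, 3)


class TestTW1Approximation:
    def test_quantiles_match_published_tables(self):
        # TW1 0.95 quantile from published tables
        assert float(_tw.tw1_ppf(0.95)) == pytest.approx(0.9793, abs=1e-3)

    def test_cdf_limits_and_monotonicity(self):
        ts = np.linspace(-8, 8, 41)
        sf = _tw.tw1_sf(ts)
        assert sf[0] > 0.999999 and sf[-1] < 1e-6
        assert np.all(np.diff(sf) < 0)


class TestTracyWidomTest:
    def test_pvalue_decreasing_in_group1_excess(self, rng):
        S0 = np.eye(2)
        ps = [
            tracy_widom_test(S0, np.eye(2) * c + 0.0, 300, 300).p_value
            for c in (1.0, 1.2, 1.5, 2.0)
        ]
        assert np.all(np.diff(ps) < 0)

    def test_boundary_eigenvalue_raises_logit_error(self):
        with pytest.raises(LogitDomainError):
            tracy_widom_test(np.zeros((2, 2)) + 0.0, np.eye(2), 10, 10)

    def test_null_rejection_rate_within_binomial_band(self):
        """Monte-Carlo calibration of the TW1 approximation at p=2, n=500."""
        reps, n, alpha = 200, 500, 0.05
        rej = 0
        for rep in range(reps):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=77, spawn_key=(rep,))
            )
            S0 = cmptest._centered_cov(rng.standard_normal((n, 2)))
            S1 = cmptest._centered_cov(rng.standard_normal((n, 2)))
            rej += tracy_widom_test(S0, S1, n, n).p_value <= alpha
        lo = stats.binom.ppf(0.025, reps, alpha) / reps
        hi = stats.binom.ppf(0.975, reps, alpha) / reps
        assert lo <= rej / reps <= hi


class TestForkmanTest:
    def test_statistic_is_top_eigenvalue_share(self, rng):
        S0 = _random_psd(rng, 3)
        S1 = _random_psd(rng, 3)
        res = forkman_test(S0, S1, 100, 100, B=5, seed=0)
        ce = combined_matrix(S0, S1, 100, 100)
        assert res.statistic == pytest.approx(
            ce.eigenvalues[0] / ce.eigenvalues.sum(), rel=1e-12
        )
        assert 1.0 / 3 <= res.statistic <= 1.0

    def test_equal_inputs_give_half_statistic(self, rng):
        S = _random_psd(rng, 2)
        res = forkman_test(S, S, 100, 100, B=5, seed=0)
        assert res.statistic == pytest.approx(0.5, rel=1e-12)

    def test_seeded_pvalue_reproducible_and_on_lattice(self, rng):
        S0 = _random_psd(rng, 2)
        S1 = _random_psd(rng, 2)
        a = forkman_test(S0, S1, 200, 200, B=500, seed=42)
        b = forkman_test(S0, S1, 200, 200, B=500, seed=42)
        assert a.p_value == b.p_value
        assert 0.0 <= a.p_value <= 1.0
        assert (a.p_value * 500) == pytest.approx(round(a.p_value * 500), abs=1e-9)

    def test_invalid_b_rejected(self, rng):
        S = _random_psd(rng, 2)
        with pytest.raises(InvalidParameterError):
            forkman_test(S, S, 100, 100, B=0)


class TestPermutationTest:
    def test_single_draw_pvalue_on_unit_lattice(self, groups_1d):
        g0, g1 = groups_1d
        bw = BandwidthSpec(h=0.6, mean_h=0.4)
        res = permutation_test(g0, g1, 0.0, bw, bw, B=1, seed=3)
        assert res.p_value in (0.0, 1.0)

    def test_seeded_reproducibility(self, groups_1d):
        g0, g1 = groups_1d
        bw = BandwidthSpec(h=0.6, mean_h=0.4)
        a = permutation_test(g0, g1, 0.5, bw, bw, B=99, seed=7)
        b = permutation_test(g0, g1, 0.5, bw, bw, B=99, seed=7)
        assert a.p_value == b.p_value and a.statistic == b.statistic

    def test_label_exchange_symmetry(self, null_groups_1d):
        """Swapping group labels reflects the observed eigenvalues and leaves
        the permutation null distribution unchanged in law."""
        g0, g1 = null_groups_1d
        bw = BandwidthSpec(h=0.6, mean_h=0.4)
        a = permutation_test(g0, g1, 0.0, bw, bw, B=400, seed=5, return_boot=True)
        b = permutation_test(g1, g0, 0.0, bw, bw, B=400, seed=5, return_boot=True)
        # exact eigenvalue reflection of the observed combined matrix:
        # lambda_k(swapped) = 1 - lambda_{p+1-k}(original)
        assert a.lambda1 is not None and b.lambda1 is not None
        # p=2: recover the spectrum from (lambda1, share) and reflect it
        lam_sum_a = a.lambda1 / a.statistic
        lam2 = lam_sum_a - a.lambda1
        swapped_expected = (1 - lam2) / ((1 - a.lambda1) + (1 - lam2))
        assert b.statistic == pytest.approx(swapped_expected, rel=1e-10)
        # permutation null distributions agree in law (same seed, two
        # equally-distributed partition streams): two-sample KS not significant
        ks = stats.ks_2samp(a.boot, b.boot)
        assert ks.pvalue > 0.01

    def test_null_pvalue_not_degenerate(self, null_groups_1d):
        g0, g1 = null_groups_1d
        bw = BandwidthSpec(h=1.0, mean_h=0.4)
        res = permutation_test(g0, g1, 0.0, bw, bw, B=199, seed=8)
        assert 0.0 <= res.p_value <= 1.0
        assert (res.p_value * 199) == pytest.approx(round(res.p_value * 199), abs=1e-9)


class TestNullEigenvalueInflation:
    def test_mean_top_eigenvalue_at_least_half_under_null(self):
        """Estimation noise pushes the top eigenvalue above its null value 0.5."""
        lams = []
        for rep in range(50):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=55, spawn_key=(rep,))
            )
            S0 = cmptest._centered_cov(rng.standard_normal((200, 2)))
            S1 = cmptest._centered_cov(rng.standard_normal((200, 2)))
            lams.append(combined_matrix(S0, S1, 200, 200).lambda1)
        lams = np.asarray(lams)
        mc_se = lams.std(ddof=1) / np.sqrt(lams.size)
        assert lams.mean() >= 0.5 - 3 * mc_se


class TestSignificanceTrace:
    def test_singleton_grid_deterministic_method_matches_direct_call(
        self, groups_1d
    ):
        g0, g1 = groups_1d
        bw = BandwidthSpec(h=0.6, mean_h=0.4)
        table = significance_trace(
            g0, g1, [0.25], bw, bw, methods=("tracy_widom",), seed=0
        )
        assert len(table) == 1
        from covfun.condcov import compute_means

        R0 = g0.X - compute_means(g0, bw)
        R1 = g1.X - compute_means(g1, bw)
        from covfun.condcov import _point_weights

        S0 = cmptest._weighted_cov(_point_weights(g0, np.array([0.25]), bw, None), R0)
        S1 = cmptest._weighted_cov(_point_weights(g1, np.array([0.25]), bw, None), R1)
        direct = tracy_widom_test(S0, S1, g0.n, g1.n)
        assert table["p_value"].iloc[0] == pytest.approx(direct.p_value, rel=1e-12)

    def test_identical_seeds_give_identical_tables(self, groups_1d):
        g0, g1 = groups_1d
        bw = BandwidthSpec(h=0.6, mean_h=0.4)
        t1 = significance_trace(g0, g1, [-0.5, 0.0, 0.5], bw, bw, B=49, seed=13)
        t2 = significance_trace(g0, g1, [-0.5, 0.0, 0.5], bw, bw, B=49, seed=13)
        assert t1.equals(t2)

    def test_row_accounting_one_method(self, groups_1d):
        g0, g1 = groups_1d
        bw = BandwidthSpec(h=0.6, mean_h=0.4)
        t = significance_trace(
            g0, g1, np.linspace(-0.8, 0.8, 7), bw, bw, methods=("forkman",),
            B=29, seed=1,
        )
        assert len(t) == 7
        assert set(t["method"]) == {"forkman"}

    def test_pvalues_smaller_where_groups_differ_more(self):
        """theta2=1 vs theta1=0.5: group separation grows with |u|, so
        p-values at u=+-1 undercut those at u=0 on average."""
        diffs = []
        for rep in range(20):
            ss = np.random.SeedSequence(entropy=99, spawn_key=(rep,))
            s0, s1 = ss.spawn(2)
            g0 = simlab.simulate_group_1d(400, 0.5, s0)
            g1 = simlab.simulate_group_1d(400, 1.0, s1)
            bw = BandwidthSpec(h=0.5, mean_h=0.4)
            t = significance_trace(
                g0, g1, [-1.0, 0.0, 1.0], bw, bw, methods=("tracy_widom",), seed=0
            )
            p = dict(zip(t["u"], t["p_value"]))
            diffs.append(0.5 * (p[-1.0] + p[1.0]) - p[0.0])
        assert np.mean(diffs) < 0

    def test_empty_grid_rejected(self, groups_1d):
        g0, g1 = groups_1d
        bw = BandwidthSpec(h=0.6)
        with pytest.raises(InvalidParameterError):
            significance_trace(g0, g1, [], bw, bw)
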