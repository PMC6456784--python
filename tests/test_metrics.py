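"""The ten connectivity metrics against independent brute-force oracles."""

import math

import numpy as np
import pytest

from dynfc import (
    ConvergenceError,
    DegenerateInputError,
    HistogramPdf,
    MetricConfig,
    MetricId,
    entropy_bits,
    kendall_corr,
    kl_symmetrized_bits,
    marginal_pdf,
    metric_value,
    mtd_pair_series,
    mtd_series,
    mutual_information_bits,
    partial_residuals,
    pearson_corr,
    pearson_partial,
    rank_transform,
    sparse_precision,
    spearman_corr,
    spearman_partial,
    variation_of_information_bits,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def mi_cell_sum_oracle(x, y, bins):
    """Brute-force MI: iterate every occupied joint histogram cell."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    N = x.size

    def edges(a):
        lo, hi = a.min(), a.max()
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        return np.linspace(lo, hi, bins + 1)

    ex, ey = edges(x), edges(y)

    def bin_of(v, e):
        k = np.searchsorted(e, v, side="right") - 1
        return min(k, bins - 1)

    joint = {}
    for xv, yv in zip(x, y):
        key = (bin_of(xv, ex), bin_of(yv, ey))
        joint[key] = joint.get(key, 0) + 1
    mx, my = {}, {}
    for (i, j), c in joint.items():
        mx[i] = mx.get(i, 0) + c
        my[j] = my.get(j, 0) + c
    mi = 0.0
    for (i, j), c in joint.items():
        pj = c / N
        mi += pj * math.log2(pj / ((mx[i] / N) * (my[j] / N)))
    return mi


def entropy_counts_oracle(counts, N):
    return -sum((c / N) * math.log2(c / N) for c in counts if c > 0)


def kendall_enumeration_oracle(x, y):
    """Exhaustive pair enumeration following the literal concordance rules."""
    N = len(x)
    nc = nd = 0
    for a in range(N):
        for b in range(a + 1, N):
            if (x[a] > x[b] and y[a] > y[b]) or (x[a] < x[b] and y[a] < y[b]):
                nc += 1
            elif (x[a] > x[b] and y[a] < y[b]) or (x[a] < x[b] and y[a] > y[b]):
                nd += 1
    return 2.0 * (nc - nd) / (N * (N - 1))


def rank_counting_oracle(x):
    """O(N^2): rank = 1 + #smaller + (#equal - 1)/2."""
    x = np.asarray(x, float)
    return np.array(
        [1 + np.sum(x < v) + (np.sum(x == v) - 1) / 2.0 for v in x]
    )


def mtd_loop_oracle(x, y, w):
    x, y = np.asarray(x, float), np.asarray(y, float)
    dx, dy = np.diff(x), np.diff(y)
    sx, sy = dx.std(), dy.std()
    out = []
    for t in range(w, dx.size - w):
        acc = sum(dx[k] * dy[k] / (sx * sy) for k in range(t - w, t + w + 1))
        out.append(acc / (2 * w + 1))
    return np.array(out)


# ---------------------------------------------------------------------------
# Pearson / Spearman / partials
# ---------------------------------------------------------------------------


class TestPearson:
    def test_exact_linear_dependence(self):
        assert pearson_corr([1, 2, 3, 4], [2, 4, 6, 8]) == pytest.approx(1.0)
        assert pearson_corr([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_expanded_value(self):
        # deviations: x -> [-1.5,-.5,.5,1.5], y -> [-1.5,.5,-.5,1.5]
        # sum of products 4; each sum of squares 5 => r = 4/5
        assert pearson_corr([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_input_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pearson_corr([1.0, 1.0, 1.0], [1, 2, 3])


class TestRanksAndSpearman:
    def test_simple_and_tied_ranks(self):
        np.testing.assert_array_equal(rank_transform([3, 1, 2]), [3, 1, 2])
        np.testing.assert_array_equal(rank_transform([1, 1, 2]), [1.5, 1.5, 3])

    def test_ranks_match_counting_oracle(self, rng):
        x = rng.integers(0, 20, size=50).astype(float)  # force ties
        np.testing.assert_allclose(rank_transform(x), rank_counting_oracle(x))

    def test_monotone_maps(self):
        assert spearman_corr([1, 2, 3], [1, 8, 27]) == pytest.approx(1.0)
        assert spearman_corr([1, 2, 3], [9, 4, 1]) == pytest.approx(-1.0)
        assert spearman_corr([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_definition_identity(self, rng):
        x, y = rng.normal(size=80), rng.normal(size=80)
        assert spearman_corr(x, y) == pearson_corr(
            rank_transform(x), rank_transform(y)
        )


class TestPartials:
    def test_perfect_fit_gives_zero_residual(self, rng):
        X = rng.normal(size=(3, 50))
        X[0] = X[2]  # target equals a conditioning series
        ex, _ = partial_residuals(X, 0, 1)
        assert np.max(np.abs(ex)) < 1e-9

    def test_orthogonal_conditioning_changes_nothing(self, rng):
        # conditioning series with zero sample correlation to both targets
        x = rng.normal(size=400)
        y = rng.normal(size=400)
        z = rng.normal(size=400)
        for v in (x, y):
            z -= (z - z.mean()) @ (v - v.mean()) / ((v - v.mean()) @ (v - v.mean())) * (v - v.mean())
        X = np.vstack([x, y, z])
        assert pearson_partial(X, 0, 1) == pytest.approx(
            pearson_corr(*partial_residuals(X, 0, 1)), abs=1e-12
        )

    def test_residuals_match_normal_equations_oracle(self, rng):
        X = rng.normal(size=(4, 200))
        ex, ey = partial_residuals(X, 0, 1)
        # explicit Gram-matrix least squares
        Z = np.column_stack([np.ones(200), X[2], X[3]])
        beta = np.linalg.inv(Z.T @ Z) @ Z.T @ np.column_stack([X[0], X[1]])
        resid = np.column_stack([X[0], X[1]]) - Z @ beta
        np.testing.assert_allclose(ex, resid[:, 0], atol=1e-9)
        np.testing.assert_allclose(ey, resid[:, 1], atol=1e-9)
        # orthogonality to regressors and the constant
        for r in (ex, ey):
            assert abs(r.sum()) < 1e-8 * np.abs(X[0]).sum()
            assert abs(r @ X[2]) < 1e-7 * np.linalg.norm(r) * np.linalg.norm(X[2])

    def test_collinear_conditioning_is_degenerate(self, rng):
        X = rng.normal(size=(5, 100))
        X[4] = X[2] + X[3]  # conditioning set of pair (0,1) is rank-deficient
        with pytest.raises(DegenerateInputError, match="rank"):
            partial_residuals(X, 0, 1)

    def test_matches_precision_matrix_identity(self, rng):
        # partial correlation == -P_ij / sqrt(P_ii P_jj), P = inv(corr matrix)
        X = rng.normal(size=(5, 300))
        C = np.corrcoef(X)
        P = np.linalg.inv(C)
        for i in range(5):
            for j in range(i + 1, 5):
                expected = -P[i, j] / np.sqrt(P[i, i] * P[j, j])
                assert pearson_partial(X, i, j) == pytest.approx(
                    expected, abs=1e-6
                )

    def test_spearman_partial_runs(self, rng):
        X = rng.normal(size=(4, 120))
        v = spearman_partial(X, 0, 1)
        assert -1.0 <= v <= 1.0


class TestKendall:
    def test_perfect_agreement_and_reversal(self, rng):
        x = rng.permutation(10).astype(float)
        assert kendall_corr(x, x) == pytest.approx(1.0)
        assert kendall_corr(x, -x) == pytest.approx(-1.0)

    def test_worked_triple(self):
        # NC=2, ND=1, N=3 -> 2(2-1)/(3*2) = 1/3
        assert kendall_corr([1, 2, 3], [1, 3, 2]) == pytest.approx(1 / 3)

    def test_matches_enumeration_oracle_with_ties(self, rng):
        x = rng.integers(0, 6, size=30).astype(float)
        y = rng.integers(0, 6, size=30).astype(float)
        assert kendall_corr(x, y) == pytest.approx(
            kendall_enumeration_oracle(x, y), abs=1e-12
        )


# ---------------------------------------------------------------------------
# Histogram / information metrics
# ---------------------------------------------------------------------------


class TestHistogramPdf:
    def test_uniform_four_bins(self):
        pdf = marginal_pdf([0, 1, 2, 3], 4)
        np.testing.assert_allclose(pdf.probabilities, [0.25] * 4)

    def test_constant_input_single_bin(self):
        pdf = marginal_pdf([2.0, 2.0, 2.0], 5)
        np.testing.assert_allclose(pdf.probabilities, [1.0])

    def test_probabilities_sum_to_one(self, rng):
        pdf = marginal_pdf(rng.normal(size=100), 100)
        assert pdf.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_entropy_values(self):
        one = HistogramPdf([0, 1], [1.0])
        assert entropy_bits(one) == 0.0
        uniform4 = HistogramPdf([0, 1, 2, 3, 4], [0.25] * 4)
        assert entropy_bits(uniform4) == pytest.approx(2.0)
        skew = HistogramPdf([0, 1, 2, 3], [0.5, 0.25, 0.25])
        assert entropy_bits(skew) == pytest.approx(1.5)


class TestMutualInformation:
    def test_self_information_equals_entropy(self, rng):
        x = rng.permutation(16).astype(float)  # no ties
        cfg = MetricConfig()
        pdf = marginal_pdf(x, len(x))
        assert mutual_information_bits(x, x, cfg) == pytest.approx(
            entropy_bits(pdf), abs=1e-10
        )

    def test_constant_partner_gives_zero(self, rng):
        x = rng.normal(size=20)
        assert mutual_information_bits(x, np.zeros(20)) == 0.0

    def test_matches_cell_sum_oracle(self, rng):
        for _ in range(5):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            assert mutual_information_bits(x, y) == pytest.approx(
                mi_cell_sum_oracle(x, y, 8), abs=1e-10
            )


class TestVariationOfInformation:
    def test_identity_is_zero(self, rng):
        x = rng.normal(size=30)
        assert variation_of_information_bits(x, x) == pytest.approx(0.0, abs=1e-10)

    def test_symmetry(self, rng):
        x, y = rng.normal(size=25), rng.normal(size=25)
        assert variation_of_information_bits(x, y) == pytest.approx(
            variation_of_information_bits(y, x)
        )

    def test_matches_h_plus_h_minus_2i_oracle(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        N = 12
        hx = entropy_bits(marginal_pdf(x, N))
        hy = entropy_bits(marginal_pdf(y, N))
        expected = hx + hy - 2 * mi_cell_sum_oracle(x, y, N)
        assert variation_of_information_bits(x, y) == pytest.approx(
            expected, abs=1e-10
        )


class TestSymmetrizedKL:
    def test_identity_and_symmetry(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        assert kl_symmetrized_bits(x, x) == pytest.approx(0.0, abs=1e-10)
        assert kl_symmetrized_bits(x, y) == pytest.approx(
            kl_symmetrized_bits(y, x)
        )

    def test_two_bin_worked_value(self):
        # p=[0.75,0.25], q=[0.25,0.75] on shared edges:
        # KLs = 0.5*log2(3) in each direction
        cfg = MetricConfig(bin_rule=2)
        x = np.array([0.0, 0.0, 0.0, 1.0])
        y = np.array([0.0, 1.0, 1.0, 1.0])
        assert kl_symmetrized_bits(x, y, cfg) == pytest.approx(
            0.5 * math.log2(3), abs=1e-12
        )


class TestMtd:
    def test_self_pair_is_nonnegative(self, rng):
        x = rng.normal(size=40)
        assert np.all(mtd_pair_series(x, x, 3) >= 0)

    def test_sign_antisymmetry(self, rng):
        x = rng.normal(size=40)
        np.testing.assert_allclose(
            mtd_pair_series(x, -x, 3), -mtd_pair_series(x, x, 3), atol=1e-12
        )

    def test_matches_loop_oracle(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        np.testing.assert_allclose(
            mtd_pair_series(x, y, 2), mtd_loop_oracle(x, y, 2), atol=1e-12
        )

    def test_constant_region_is_degenerate(self):
        with pytest.raises(DegenerateInputError, match="region"):
            mtd_pair_series(np.ones(20), np.arange(20.0), 2)

    def test_all_pairs_matrix_is_symmetric(self, rng):
        out = mtd_series(rng.normal(size=(3, 30)), w=2)
        np.testing.assert_allclose(out, out.transpose(1, 0, 2))


class TestSparsePrecision:
    def test_lambda_zero_is_direct_inverse(self, rng):
        X = rng.normal(size=(3, 500))
        cfg = MetricConfig(icov_lambda=0.0)
        expected = np.linalg.inv(np.cov(X, ddof=0))
        np.testing.assert_allclose(sparse_precision(X, cfg), expected, rtol=1e-6)

    def test_large_penalty_forces_diagonal_solution(self, rng):
        X = rng.normal(size=(3, 200))
        cov = np.cov(X, ddof=0)
        lam = np.abs(cov - np.diag(np.diag(cov))).max() * 1.5
        P = sparse_precision(X, MetricConfig(icov_lambda=lam))
        off = P - np.diag(np.diag(P))
        assert np.all(off == 0.0)

    def test_independent_noise_off_diagonal_is_small(self, rng):
        X = rng.normal(size=(2, 2000))
        P = sparse_precision(X, MetricConfig(icov_lambda=0.1))
        assert abs(P[0, 1]) < 0.05

    def test_result_is_symmetric_positive_definite(self, rng):
        X = rng.normal(size=(4, 300))
        P = sparse_precision(X, MetricConfig(icov_lambda=0.1))
        np.testing.assert_allclose(P, P.T, atol=1e-8)
        assert np.all(np.linalg.eigvalsh(P) > 0)


# ---------------------------------------------------------------------------
# Dispatch + cross-metric properties
# ---------------------------------------------------------------------------


class TestDispatch:
    def test_identical_rows(self, rng):
        x = rng.normal(size=60)
        X = np.vstack([x, x, rng.normal(size=60)])
        assert metric_value(MetricId.PEARSON, X, 0, 1) == pytest.approx(1.0)
        assert metric_value(
            MetricId.VARIATION_OF_INFORMATION, X, 0, 1
        ) == pytest.approx(0.0, abs=1e-10)

    def test_kendall_worked_triple_through_dispatch(self):
        X = np.array([[1.0, 2.0, 3.0], [1.0, 3.0, 2.0]])
        assert metric_value("kendall", X, 0, 1) == pytest.approx(1 / 3)


ALL_METRICS = list(MetricId)


class TestCrossMetricProperties:
    @pytest.mark.parametrize("metric", ALL_METRICS)
    @pytest.mark.parametrize("seed", range(10))
    def test_symmetry_in_pair_arguments(self, metric, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(4, 40))
        cfg = MetricConfig(mtd_inner_w=4)
        a = metric_value(metric, X, 0, 1, cfg)
        b = metric_value(metric, X, 1, 0, cfg)
        assert a == pytest.approx(b, abs=1e-10)

    @pytest.mark.parametrize(
        "metric", [MetricId.PEARSON, MetricId.SPEARMAN, MetricId.KENDALL]
    )
    def test_affine_invariance(self, metric, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        X1 = np.vstack([x, y])
        X2 = np.vstack([3.0 * x + 7.0, 0.5 * y - 2.0])
        assert metric_value(metric, X1, 0, 1) == pytest.approx(
            metric_value(metric, X2, 0, 1), abs=1e-9
        )

    @pytest.mark.parametrize("metric", [MetricId.SPEARMAN, MetricId.KENDALL])
    def test_rank_metrics_survive_monotone_transform(self, metric, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        X1 = np.vstack([x, y])
        X2 = np.vstack([np.exp(x), y**3])
        assert metric_value(metric, X1, 0, 1) == pytest.approx(
            metric_value(metric, X2, 0, 1), abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_information_measures_are_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert mutual_information_bits(x, y) >= 0.0
        assert variation_of_information_bits(x, y) >= 0.0
        assert kl_symmetrized_bits(x, y) >= 0.0
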