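"""Unit and property tests for the dependence measures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wdscreen import measures as M
from tests.conftest import dcor_bruteforce


def _pearson_by_hand(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return abs((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


class TestUnivariateBaselines:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3, 4], [2, 4, 6, 8], 1.0),  # exact linearity
            ([1, -1, 1, -1], [1, 1, -1, -1], 0.0),  # orthogonal patterns
            ([1, 2, 3, 5], [1, 4, 9, 25], _pearson_by_hand([1, 2, 3, 5], [1, 4, 9, 25])),
        ],
    )
    def test_pearson_examples(self, x, y, expected):
        assert M.pearson_dependence(x, y) == pytest.approx(expected, abs=1e-12)

    def test_pearson_returns_magnitude(self):
        assert M.pearson_dependence([1, 2, 3], [6, 4, 2]) == pytest.approx(1.0)

    def test_pearson_constant_block_warns_zero(self):
        with pytest.warns(M.ConstantBlockWarning):
            assert M.pearson_dependence([1, 1, 1], [1, 2, 3]) == 0.0

    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [10, 20, 30], 1.0),  # ranks collinear with x
            # ranks of a cube are (1,2,3,4), collinear with x
            ([1, 2, 3, 4], [1, 8, 27, 64], 1.0),
        ],
    )
    def test_rank_response_examples(self, x, y, expected):
        assert M.rank_response_dependence(x, y) == pytest.approx(expected)

    def test_rank_response_is_pearson_against_ranks(self, rng):
        x = rng.standard_normal(15)
        y = rng.standard_normal(15)
        from scipy.stats import rankdata

        assert M.rank_response_dependence(x, y) == pytest.approx(
            M.pearson_dependence(x, rankdata(y))
        )

    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [3, 2, 1], 1.0),  # fully discordant, magnitude taken
            # exhaustive pair count: 5 concordant, 1 discordant -> 4/6
            ([1, 2, 3, 4], [1, 3, 2, 4], 2 / 3),
        ],
    )
    def test_kendall_examples(self, x, y, expected):
        assert M.kendall_dependence(x, y) == pytest.approx(expected)

    def test_kendall_matches_bruteforce_pair_count(self, rng):
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        conc = disc = 0
        for i in range(12):
            for j in range(i + 1, 12):
                s = np.sign((x[i] - x[j]) * (y[i] - y[j]))
                conc += s > 0
                disc += s < 0
        assert M.kendall_dependence(x, y) == pytest.approx(
            abs(conc - disc) / (12 * 11 / 2)
        )

    def test_kendall_all_ties_warns_zero(self):
        with pytest.warns(M.ConstantBlockWarning):
            assert M.kendall_dependence([2, 2, 2], [1, 2, 3]) == 0.0


class TestDistanceCorrelation:
    def test_identical_blocks_score_one(self, rng):
        x = rng.standard_normal((10, 2))
        assert M.distance_correlation(x, x) == pytest.approx(1.0)

    def test_constant_block_scores_zero(self):
        assert M.distance_correlation([1, 1, 1, 1], [1, 2, 3, 4]) == 0.0

    def test_matches_bruteforce_oracle_small_example(self):
        x = [1, 2, 3, 4]
        y = [1, 4, 9, 16]
        assert M.distance_correlation(x, y) == pytest.approx(
            dcor_bruteforce(x, y), abs=1e-10
        )

    @pytest.mark.parametrize("n,dx,q", [(5, 1, 1), (12, 2, 3), (30, 3, 1), (17, 1, 4)])
    def test_matches_bruteforce_oracle_random(self, rng, n, dx, q):
        x = rng.standard_normal((n, dx))
        y = rng.standard_normal((n, q))
        assert M.distance_correlation(x, y) == pytest.approx(
            dcor_bruteforce(x, y), abs=1e-10
        )

    def test_mismatched_n_rejected(self, rng):
        with pytest.raises(ValueError, match="sample dimension"):
            M.distance_correlation(rng.standard_normal(5), rng.standard_normal(6))

    def test_double_centered_rows_and_columns_sum_to_zero(self, rng):
        struct = M.double_centered_distances(rng.standard_normal((20, 3)))
        assert np.abs(struct.centered.sum(axis=0)).max() < 1e-9
        assert np.abs(struct.centered.sum(axis=1)).max() < 1e-9
        assert np.allclose(struct.a, struct.a.T)
        assert np.abs(np.diag(struct.a)).max() == 0.0

    def test_rank_response_variant_invariant_to_monotone_transform(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        assert M.distance_correlation_rank_response(x, y) == pytest.approx(
            M.distance_correlation_rank_response(x, np.exp(3 * y))
        )

    def test_rank_response_variant_is_dcor_on_ranks(self):
        x = [1, 2, 3]
        y = [5, 7, 6]
        assert M.distance_correlation_rank_response(x, y) == pytest.approx(
            M.distance_correlation(x, [1, 3, 2])
        )

    def test_rank_response_variant_matches_oracle_composition(self, rng):
        from scipy.stats import rankdata

        x = rng.standard_normal(10)
        y = rng.standard_normal(10)
        assert M.distance_correlation_rank_response(x, y) == pytest.approx(
            dcor_bruteforce(x, rankdata(y)), abs=1e-10
        )


class TestProjectionCorrelation:
    def test_univariate_closed_form(self):
        assert M.projection_correlation([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_univariate_equals_abs_pearson(self, rng):
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        assert M.projection_correlation(x, y) == pytest.approx(
            M.pearson_dependence(x, y)
        )

    def test_monotone_in_direction_set(self, rng):
        x = rng.standard_normal((30, 2))
        y = rng.standard_normal((30, 2))
        small = M.draw_projection_set(2, 2, 20, seed=5)
        big = M.ProjectionSet(
            np.hstack([small.u_directions, M.draw_projection_set(2, 2, 80, seed=6).u_directions]),
            np.hstack([small.v_directions, M.draw_projection_set(2, 2, 80, seed=6).v_directions]),
        )
        assert M.projection_correlation(x, y, small) <= M.projection_correlation(
            x, y, big
        ) + 1e-12

    def test_2d_estimate_close_to_dense_grid_oracle(self, rng):
        x = rng.standard_normal((40, 2))
        y = x @ np.array([[1.0, 0.3], [0.2, -0.8]]) + 0.5 * rng.standard_normal((40, 2))
        # dense 1-degree sweep over both projection angles
        angles = np.deg2rad(np.arange(0, 180))
        best = 0.0
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        for t in angles:
            u = np.array([np.cos(t), np.sin(t)])
            px = xc @ u
            for s in angles:
                v = np.array([np.cos(s), np.sin(s)])
                py = yc @ v
                denom = np.sqrt((px @ px) * (py @ py))
                if denom > 0:
                    best = max(best, abs(px @ py) / denom)
        est = M.projection_correlation(x, y, n_directions=500, seed=7)
        # the 1-degree grid itself undershoots the continuous supremum by
        # O(grid step squared), so allow that much on the upper side
        assert est <= best + 1e-3
        assert est >= best - 0.02

    def test_degenerate_projection_contributes_zero(self):
        x = np.zeros((10, 2))
        y = np.arange(20.0).reshape(10, 2)
        assert M.projection_correlation(x, y, n_directions=8, seed=1) == 0.0

    def test_wrong_dimension_directions_rejected(self, rng):
        dirs = M.draw_projection_set(3, 2, 10, seed=0)
        with pytest.raises(ValueError, match="wrong dimensions"):
            M.projection_correlation(
                rng.standard_normal((10, 2)), rng.standard_normal((10, 2)), dirs
            )


class TestWassersteinDependence:
    def test_uncorrelated_blocks_score_exactly_zero(self):
        # sample cross-covariance is exactly 0 -> block-diagonal joint
        assert M.wasserstein_dependence([1, -1, 1, -1], [1, 1, -1, -1]) == 0.0

    def test_identical_univariate_blocks_score_one(self, rng):
        x = 3.0 * rng.standard_normal(20) + 1.0
        assert M.wasserstein_dependence(x, x) == pytest.approx(1.0)

    def test_closed_form_on_standardized_univariate_pair(self, rng):
        # for unit variances and correlation rho the joint eigenvalues are
        # 1 +- rho, giving D1 = (2 - sqrt(1+rho) - sqrt(1-rho)) / (2 - sqrt(2))
        for rho in (0.6, 0.15, 0.9):
            x = rng.standard_normal(50)
            z = rng.standard_normal(50)
            xc = (x - x.mean()) / x.std(ddof=1)
            z = z - z.mean()
            z -= (z @ xc) / (xc @ xc) * xc
            z /= z.std(ddof=1)
            y = rho * xc + np.sqrt(1 - rho**2) * z
            expected = (2 - np.sqrt(1 + rho) - np.sqrt(1 - rho)) / (2 - np.sqrt(2))
            assert M.wasserstein_dependence(xc, y) == pytest.approx(expected, abs=1e-10)
        # spot value quoted for rho = 0.6
        assert (2 - np.sqrt(1.6) - np.sqrt(0.4)) / (2 - np.sqrt(2)) == pytest.approx(
            0.1752, abs=5e-5
        )

    def test_constant_blocks_warn_zero(self):
        with pytest.warns(M.ConstantBlockWarning):
            assert M.wasserstein_dependence([1, 1, 1], [2, 2, 2]) == 0.0

    def test_same_ranking_as_pearson_on_equal_variance_features(self, rng):
        # univariate equal-variance case: D1 is an increasing function of
        # |rho| only, so the induced feature ranking matches SIS
        n, p = 80, 50
        y = rng.standard_normal(n)
        y = (y - y.mean()) / y.std(ddof=1)
        d1 = np.empty(p)
        r = np.empty(p)
        for j in range(p):
            x = rng.standard_normal(n)
            x = (x - x.mean()) / x.std(ddof=1)
            d1[j] = M.wasserstein_dependence(x, y)
            r[j] = M.pearson_dependence(x, y)
        assert np.array_equal(np.argsort(-d1), np.argsort(-r))

    def test_spectrum_invariants(self, rng):
        x = rng.standard_normal((30, 3))
        y = rng.standard_normal((30, 2))
        spec = M.covariance_spectrum(x, y)
        assert np.all(spec.lambda_joint >= 0)
        assert spec.lambda_joint.sum() == pytest.approx(
            np.trace(spec.sigma_x) + np.trace(spec.sigma_y)
        )
        assert spec.max_dim == 3


@st.composite
def block_pair(draw):
    n = draw(st.integers(5, 20))
    dx = draw(st.sampled_from([1, 2, 3, 10]))
    q = draw(st.sampled_from([1, 2, 3, 10]))
    seed = draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, dx)) * draw(st.floats(0.1, 10))
    y = rng.standard_normal((n, q))
    return x, y


class TestMeasureProperties:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(block_pair())
    def test_scores_in_unit_interval(self, pair):
        x, y = pair
        for fn in (
            M.distance_correlation,
            M.wasserstein_dependence,
            lambda a, b: M.projection_correlation(a, b, n_directions=20, seed=0),
        ):
            score = fn(x, y)
            assert 0.0 <= score <= 1.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(block_pair(), st.floats(-50, 50), st.floats(-50, 50))
    def test_shift_invariance(self, pair, cx, cy):
        x, y = pair
        assert M.distance_correlation(x, y) == pytest.approx(
            M.distance_correlation(x + cx, y + cy), abs=1e-8
        )
        assert M.wasserstein_dependence(x, y) == pytest.approx(
            M.wasserstein_dependence(x + cx, y + cy), abs=1e-7
        )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(block_pair(), st.floats(0.01, 100))
    def test_common_rescaling_invariance(self, pair, c):
        x, y = pair
        assert M.distance_correlation(x, y) == pytest.approx(
            M.distance_correlation(c * x, c * y), abs=1e-8
        )
        assert M.wasserstein_dependence(x, y) == pytest.approx(
            M.wasserstein_dependence(c * x, c * y), abs=1e-8
        )

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(4, 30))
    def test_dcor_matches_oracle_everywhere(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((n, rng.integers(1, 4)))
        y = rng.standard_normal((n, rng.integers(1, 4)))
        assert M.distance_correlation(x, y) == pytest.approx(
            dcor_bruteforce(x, y), abs=1e-10
        )
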