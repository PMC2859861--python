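"""Background correction, M/A, control-spot loess, Aquantile."""

import numpy as np
import pytest
from scipy import integrate, stats

from subscreen import arrays as aio
from subscreen.preprocess import (
    LoessConfig,
    MAset,
    NormexpConfig,
    compute_ma,
    compute_spot_weights,
    normalize_between_aquantile,
    normalize_within_control_loess,
    normexp_correct,
    normexp_fit,
    normexp_signal,
)


def _spots(rows):
    import pandas as pd

    df = pd.DataFrame(
        rows,
        columns=["block", "row", "col", "clone_id", "fg_cy5", "bg_cy5", "fg_cy3",
                 "bg_cy3", "bg_sd_cy5", "bg_sd_cy3", "flag"],
    )
    df["name"] = df["clone_id"]
    for ch in ("cy5", "cy3"):
        df[f"snr_{ch}"] = (df[f"fg_{ch}"] - df[f"bg_{ch}"]) / df[f"bg_sd_{ch}"]
    return aio.ArraySpots(array_id="t", spots=df, channel_names=("532", "635"))


class TestSpotWeights:
    @pytest.mark.parametrize(
        "fg, bg, sd, flag, expected",
        [
            (1000, 100, 50, 0, 1.0),  # SNR 18 in both channels
            (500, 480, 10, 0, 0.0),  # SNR 2 < 3
            (1000, 100, 50, -50, 0.0),  # flagged bad despite high SNR
        ],
    )
    def test_threshold_and_flag_rules(self, fg, bg, sd, flag, expected):
        arr = _spots([[1, 1, 1, "x", fg, bg, fg, bg, sd, sd, flag]])
        assert compute_spot_weights(arr, snr_threshold=3.0)[0] == expected

    def test_weight_zero_if_either_channel_weak(self):
        arr = _spots([[1, 1, 1, "x", 1000, 100, 500, 480, 50, 10, 0]])
        assert compute_spot_weights(arr)[0] == 0.0


def _posterior_mean_oracle(x, mu, sigma, alpha):
    """E[S | x] by numerical integration of the normexp posterior.

    The shared normalizing constant (the prior x normal density at s = 0)
    is divided out inside the integrand so the quadrature stays scaled
    near 1 even far into the background's left tail.
    """
    s_mode = max(x - mu, 0.0)
    log_c = -s_mode / alpha + stats.norm.logpdf(x - s_mode, mu, sigma)

    def kernel(s):
        return np.exp(-s / alpha + stats.norm.logpdf(x - s, mu, sigma) - log_c)

    hi = max(x - mu, 0) + 12 * sigma + 5 * alpha
    a, _ = integrate.quad(lambda s: s * kernel(s), 0, hi, limit=400)
    b, _ = integrate.quad(kernel, 0, hi, limit=400)
    return a / b


class TestNormexp:
    def test_conditional_mean_matches_integration_oracle(self):
        for x in (-20.0, 0.0, 5.0, 50.0, 400.0):
            expected = _posterior_mean_oracle(x, mu=0.0, sigma=1.0, alpha=100.0)
            got = normexp_signal((0.0, 1.0, 100.0), np.array([x]))[0]
            assert got == pytest.approx(expected, rel=1e-6), f"x={x}"

    def test_worked_value_x50(self):
        got = normexp_signal((0.0, 1.0, 100.0), np.array([50.0]))[0]
        assert got == pytest.approx(49.99, abs=0.005)

    def test_linear_tail_far_above_background(self):
        mu, sigma, alpha = 10.0, 20.0, 500.0
        x = np.array([5000.0, 9000.0])
        got = normexp_signal((mu, sigma, alpha), x)
        np.testing.assert_allclose(got, x - mu - sigma**2 / alpha, rtol=1e-10)

    def test_positivity_far_below_background(self):
        got = normexp_signal((0.0, 50.0, 300.0), np.array([-200.0]))[0]
        assert got > 0

    def test_monotone_in_input(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.normal(0, 40, 500) + rng.exponential(400, 500))
        corrected = normexp_correct(x, NormexpConfig(offset=50))
        assert np.all(np.diff(corrected) >= -1e-8)
        assert np.all(corrected > 0)

    def test_fit_recovers_parameters(self):
        rng = np.random.default_rng(42)
        mu, sigma, alpha = 80.0, 30.0, 600.0
        x = rng.normal(mu, sigma, 4000) + rng.exponential(alpha, 4000)
        mu_h, sigma_h, alpha_h = normexp_fit(x)
        assert mu_h == pytest.approx(mu, abs=10)
        assert sigma_h == pytest.approx(sigma, rel=0.25)
        assert alpha_h == pytest.approx(alpha, rel=0.1)

    def test_too_few_values_is_an_error(self):
        with pytest.raises(ValueError, match="10"):
            normexp_correct(np.arange(5.0))


class TestComputeMA:
    def test_worked_examples(self):
        m, a = compute_ma(np.array([400.0, 256.0]), np.array([100.0, 256.0]))
        assert m[0] == pytest.approx(2.0)
        assert a[0] == pytest.approx((np.log2(400) + np.log2(100)) / 2)
        assert m[1] == 0.0 and a[1] == 8.0

    def test_swap_negates_m_preserves_a(self):
        rng = np.random.default_rng(1)
        cy5, cy3 = rng.uniform(10, 1e4, 50), rng.uniform(10, 1e4, 50)
        m1, a1 = compute_ma(cy5, cy3)
        m2, a2 = compute_ma(cy3, cy5)
        np.testing.assert_allclose(m1, -m2)
        np.testing.assert_allclose(a1, a2)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            compute_ma(np.array([0.0]), np.array([1.0]))


def _ma_single(m, a, roles, printtip=None, weights=None):
    n = len(m)
    return MAset(
        m=np.asarray(m, float),
        a=np.asarray(a, float),
        weights=np.ones(n) if weights is None else np.asarray(weights, float),
        clone_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        roles=np.asarray(roles, dtype=object),
        printtip=np.ones(n, dtype=int) if printtip is None else np.asarray(printtip),
        array_ids=["a1"],
    )


class TestControlLoess:
    def test_constant_control_offset_removed_exactly(self):
        n = 60
        a = np.linspace(4, 14, n)
        roles = np.array(["control_gfp"] * 20 + ["forward_library"] * 40, dtype=object)
        m = np.where(np.arange(n) < 20, 0.5, 2.0)
        a = np.concatenate([np.linspace(4, 14, 20), np.linspace(4, 14, 40)])
        ma = _ma_single(m, a, roles)
        out = normalize_within_control_loess(ma, LoessConfig())
        np.testing.assert_allclose(out.m[:20, 0], 0.0, atol=1e-9)
        np.testing.assert_allclose(out.m[20:, 0], 1.5, atol=1e-9)
        np.testing.assert_array_equal(out.a, ma.a)
        np.testing.assert_array_equal(out.weights, ma.weights)

    def test_smooth_dye_bias_shrinks_control_sd(self):
        rng = np.random.default_rng(3)
        n_ctrl, n_lib = 120, 600
        a = np.concatenate([rng.uniform(4, 14, n_ctrl), rng.uniform(4, 14, n_lib)])
        bias = 0.8 * np.sin(a / 2)
        noise = rng.normal(0, 0.08, n_ctrl + n_lib)
        m = bias + noise
        roles = np.array(
            ["control_globin"] * n_ctrl + ["forward_library"] * n_lib, dtype=object
        )
        ma = _ma_single(m, a, roles)
        out = normalize_within_control_loess(ma, LoessConfig())
        sd_before = np.std(ma.m[:n_ctrl, 0])
        sd_after = np.std(out.m[:n_ctrl, 0])
        assert sd_after < sd_before
        assert sd_after < 0.12  # residual ~ injected noise level
        # residual curvature: a fresh loess of the normalized controls is ~flat
        import statsmodels.api as sm

        resid = sm.nonparametric.lowess(
            out.m[:n_ctrl, 0], a[:n_ctrl], frac=0.4, it=2, return_sorted=True
        )
        assert np.max(np.abs(resid[:, 1])) < 0.05

    def test_extrapolation_holds_boundary_value(self):
        # controls only in the middle of the A range; bias linear in A
        a_ctrl = np.linspace(8, 10, 30)
        a_lib = np.array([4.0, 14.0])
        a = np.concatenate([a_ctrl, a_lib])
        m = 0.3 * (a - 9.0)
        roles = np.array(["control_its"] * 30 + ["forward_library"] * 2, dtype=object)
        ma = _ma_single(m, a, roles)
        out = normalize_within_control_loess(ma, LoessConfig())
        # fitted curve clamps at the boundary control fit: 0.3*(8-9), 0.3*(10-9)
        assert out.m[30, 0] == pytest.approx(0.3 * (4 - 9) - 0.3 * (8 - 9), abs=1e-6)
        assert out.m[31, 0] == pytest.approx(0.3 * (14 - 9) - 0.3 * (10 - 9), abs=1e-6)

    def test_weight_zero_spots_normalized_but_not_fitted(self):
        a = np.linspace(4, 14, 40)
        roles = np.array(["control_gfp"] * 20 + ["forward_library"] * 20, dtype=object)
        m = np.full(40, 0.5)
        weights = np.ones(40)
        # a wild weight-0 control must not bend the curve
        m[5] = 50.0
        weights[5] = 0.0
        ma = _ma_single(m, a, roles, weights=weights)
        out = normalize_within_control_loess(ma, LoessConfig())
        np.testing.assert_allclose(np.delete(out.m[:, 0], 5), 0.0, atol=1e-9)
        assert out.m[5, 0] == pytest.approx(49.5)  # adjusted, not refit

    def test_no_controls_is_an_error(self):
        ma = _ma_single([0.1, 0.2], [5, 6], ["forward_library"] * 2)
        with pytest.raises(ValueError, match="control"):
            normalize_within_control_loess(ma)


class TestAquantile:
    def _two_arrays(self, a1, a2, m1=None, m2=None):
        n = len(a1)
        mk = lambda m, a, aid: MAset(
            m=np.zeros(n) if m is None else np.asarray(m, float),
            a=np.asarray(a, float),
            weights=np.ones(n),
            clone_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
            roles=np.array(["forward_library"] * n, dtype=object),
            printtip=np.ones(n, dtype=int),
            array_ids=[aid],
        )
        return [mk(m1, a1, "a1"), mk(m2, a2, "a2")]

    def test_rank_mean_by_hand(self):
        out = normalize_between_aquantile(self._two_arrays([1, 3], [2, 4]))
        np.testing.assert_allclose(out.a[:, 0], [1.5, 3.5])
        np.testing.assert_allclose(out.a[:, 1], [1.5, 3.5])

    def test_identical_arrays_unchanged(self):
        out = normalize_between_aquantile(self._two_arrays([5, 7, 6], [5, 7, 6]))
        np.testing.assert_allclose(out.a[:, 0], [5, 7, 6])
        np.testing.assert_allclose(out.a[:, 1], [5, 7, 6])

    def test_m_bit_identical(self):
        rng = np.random.default_rng(5)
        m1, m2 = rng.normal(size=30), rng.normal(size=30)
        sets = self._two_arrays(rng.uniform(4, 14, 30), rng.uniform(4, 14, 30), m1, m2)
        out = normalize_between_aquantile(sets)
        np.testing.assert_array_equal(out.m[:, 0], m1)
        np.testing.assert_array_equal(out.m[:, 1], m2)

    def test_sorted_a_columns_identical_after(self):
        rng = np.random.default_rng(6)
        sets = self._two_arrays(rng.uniform(4, 14, 100), rng.uniform(4, 14, 100))
        out = normalize_between_aquantile(sets)
        np.testing.assert_allclose(np.sort(out.a[:, 0]), np.sort(out.a[:, 1]))

    def test_ties_share_the_rank_mean(self):
        out = normalize_between_aquantile(self._two_arrays([2, 2, 5], [1, 3, 9]))
        # reference = mean of sorted columns = [1.5, 2.5, 7]; the tied 2s
        # share mean(1.5, 2.5) = 2
        np.testing.assert_allclose(out.a[:, 0], [2.0, 2.0, 7.0])

    def test_single_array_is_noop(self):
        sets = self._two_arrays([1, 2], [3, 4])[:1]
        out = normalize_between_aquantile(sets)
        np.testing.assert_allclose(out.a[:, 0], [1, 2])
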