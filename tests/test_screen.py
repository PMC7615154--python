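"""Hit calling, robust Z-scores, and group-comparison statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aceid.screen import (
    MAD_SCALE,
    bh_adjust,
    call_hits,
    outlier_flag,
    robust_zscore,
    spearman,
    welch_ttest,
)


class TestRobustZ:
    def test_hand_computed_example(self):
        """Controls [10,12,14,10,12]: median 12, MAD 2 -> z(18) = 6/2.9652."""
        z = robust_zscore(18.0, [10, 12, 14, 10, 12])
        assert z == pytest.approx(6 / (MAD_SCALE * 2), rel=1e-12)
        assert z == pytest.approx(2.0235, abs=5e-4)

    def test_control_median_maps_to_zero(self):
        assert robust_zscore(12.0, [10, 12, 14, 10, 12]) == 0.0

    @given(
        st.lists(st.floats(-100, 100), min_size=5, max_size=30),
        st.floats(-50, 50),
    )
    @settings(deadline=None, max_examples=50)
    def test_matches_bruteforce_and_location_equivariant(self, ctrl, shift):
        ctrl = np.round(np.asarray(ctrl), 6)
        med = float(np.median(ctrl))
        mad = float(np.median(np.abs(ctrl - med)))
        if mad == 0:
            return
        x = np.linspace(-5, 5, 7)
        z = robust_zscore(x, ctrl)
        oracle = (x - med) / (1.4826 * mad)
        np.testing.assert_allclose(z, oracle, rtol=1e-9)
        z_shifted = robust_zscore(x + shift, np.asarray(ctrl) + shift)
        np.testing.assert_allclose(z_shifted, z, rtol=1e-6, atol=1e-6)

    def test_degenerate_control_rejected(self):
        with pytest.raises(ValueError, match="MAD"):
            robust_zscore(1.0, [5, 5, 5, 5])

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            robust_zscore(1.0, [1, 2, 3])


class TestHitCalls:
    CTRL = [0.9, 1.0, 1.1, 0.95, 1.05, 1.0, 0.98, 1.02]

    def test_controls_against_themselves_are_no_effect(self):
        calls = call_hits({"X": self.CTRL}, self.CTRL)
        assert calls[0].label == "no_effect"

    def test_threshold_arithmetic(self):
        """mu=1.0, sd=0.1: mean 1.35 -> increase; 1.25 -> no_effect;
        0.65 -> decrease."""
        rng = np.random.default_rng(0)
        ctrl = rng.normal(1.0, 0.1, 200)
        mu, sd = ctrl.mean(), ctrl.std(ddof=1)
        conds = {
            "up": [mu + 3.5 * sd] * 3,
            "flat": [mu + 2.5 * sd] * 3,
            "down": [mu - 3.5 * sd] * 3,
        }
        labels = {c.condition_id: c.label for c in call_hits(conds, ctrl)}
        assert labels == {"up": "increase", "flat": "no_effect", "down": "decrease"}

    def test_few_controls_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            call_hits({"X": [1, 2]}, [1.0] * 5)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            call_hits({"X": [1, 2]}, [1.0] * 8)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicate"):
            call_hits({"X": [1.0]}, self.CTRL)

    def test_operating_characteristics_match_theory(self):
        """3-SD rule on 4-replicate means at 15% CV: null FPR <= 1% and
        sensitivity at a 1.5x multiplier close to its closed-form value
        P(N(1.5, 1.5*cv/2) > mu_c + 3*sigma_c)."""
        from scipy import stats

        rng = np.random.default_rng(123)
        cv = 0.15
        sigma = np.sqrt(np.log(1 + cv**2))

        def draw(mult, n):
            return mult * rng.lognormal(-sigma**2 / 2, sigma, n)

        ctrl = draw(1.0, 16)
        null_calls = call_hits({f"N{i}": draw(1.0, 4) for i in range(500)}, ctrl)
        pos_calls = call_hits({f"P{i}": draw(1.5, 4) for i in range(500)}, ctrl)
        fpr = np.mean([c.label != "no_effect" for c in null_calls])
        sens = np.mean([c.label == "increase" for c in pos_calls])
        assert fpr <= 0.01
        threshold = ctrl.mean() + 3 * ctrl.std(ddof=1)
        expected = 1 - stats.norm.cdf(threshold, loc=1.5, scale=1.5 * cv / 2)
        assert sens == pytest.approx(expected, abs=0.08)


class TestOutlierFlag:
    def test_below_threshold(self):
        assert outlier_flag([1.2, 2.9]) is False

    def test_single_replicate_above(self):
        assert outlier_flag([0.5, 3.1]) is True

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            outlier_flag([])

    def test_null_rate_matches_resampling(self):
        """Flag rate of k-replicate null conditions ~ P(max of k z-draws > 3)."""
        rng = np.random.default_rng(7)
        ctrl = rng.normal(0, 1, 200)
        k, n_cond = 4, 2000
        flags = [
            outlier_flag(robust_zscore(rng.normal(0, 1, k), ctrl))
            for _ in range(n_cond)
        ]
        # resampling oracle under the same empirical null
        draws = robust_zscore(rng.normal(0, 1, (5000, k)).ravel(), ctrl).reshape(5000, k)
        expected = float(np.mean(draws.max(axis=1) > 3))
        assert np.mean(flags) == pytest.approx(expected, abs=0.01)


class TestGroupStats:
    def test_welch_closed_form(self):
        """a=[1,2,3], b=[2,4,6]: t = -2/sqrt(5/3), df = 50/17."""
        t, df, p = welch_ttest([1, 2, 3], [2, 4, 6])
        assert t == pytest.approx(-2 / np.sqrt(5 / 3), rel=1e-9)
        assert t == pytest.approx(-1.549, abs=1e-3)
        assert df == pytest.approx(50 / 17, rel=1e-9)
        assert 0 < p < 1

    def test_identical_groups(self):
        t, _, p = welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_identical_constant_groups(self):
        t, _, p = welch_ttest([2.0] * 4, [2.0] * 4)
        assert (t, p) == (0.0, 1.0)

    def test_distinct_constant_groups_undefined(self):
        with pytest.raises(ValueError, match="zero variance"):
            welch_ttest([1.0] * 4, [2.0] * 4)

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=30)
    def test_welch_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 2, 11)
        t, df, p = welch_ttest(a, b)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_o = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_o = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        assert t == pytest.approx(t_o, rel=1e-9)
        assert df == pytest.approx(df_o, rel=1e-9)

    def test_spearman_monotone(self):
        rho, p = spearman([1, 2, 3, 4, 5], [2, 4, 9, 16, 30])
        assert rho == pytest.approx(1.0)


def bh_oracle(p):
    """Step-up enumeration of Benjamini–Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        adj[idx] = prev
    return adj


class TestBH:
    def test_enumerated_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04], rtol=1e-12
        )

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=30)
    def test_matches_stepup_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, rng.integers(1, 40))
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), rtol=1e-9)

    def test_preserves_order_and_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 25)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
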