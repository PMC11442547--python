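"""Closed-form loss/metric values and oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from collimap.io import BrainMask, CollateralMapSet
from collimap.metrics import (
    LossConfig,
    SSIMConfig,
    berhu_loss,
    berhu_loss_grad,
    evaluate_subject,
    mae,
    r_squared,
    ssim_global,
    tanimoto,
)


class TestBerHu:
    def test_linear_branch(self):
        assert berhu_loss(np.array([0.1]), np.array([0.0])) == pytest.approx(0.1)

    def test_quadratic_branch(self):
        # (0.4^2 + 0.2^2) / (2 * 0.2) = 0.5
        assert berhu_loss(np.array([0.4]), np.array([0.0])) == pytest.approx(0.5)

    def test_continuity_at_threshold(self):
        c = 0.2
        below = berhu_loss(np.array([c - 1e-9]), np.array([0.0]))
        at = berhu_loss(np.array([c]), np.array([0.0]))
        above = berhu_loss(np.array([c + 1e-9]), np.array([0.0]))
        assert at == pytest.approx(c)
        assert below == pytest.approx(at, abs=1e-8)
        assert above == pytest.approx(at, abs=1e-8)

    @given(st.floats(-2.0, 2.0), st.floats(-2.0, 2.0))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_monotone_in_absolute_residual(self, a, b):
        la = berhu_loss(np.array([a]), np.array([0.0]))
        lb = berhu_loss(np.array([b]), np.array([0.0]))
        if abs(a) <= abs(b):
            assert la <= lb + 1e-12

    def test_equals_l1_below_threshold(self, rng):
        r = rng.uniform(-0.19, 0.19, size=100)
        assert berhu_loss(r, np.zeros(100)) == pytest.approx(np.abs(r).mean())

    def test_gradient_matches_finite_differences(self, rng):
        pred = rng.uniform(-1, 1, size=32)
        target = rng.uniform(-0.9, 0.9, size=32)
        loss, grad = berhu_loss_grad(pred, target)
        eps = 1e-7
        for i in range(0, 32, 5):
            p = pred.copy()
            p[i] += eps
            lp, _ = berhu_loss_grad(p, target)
            p[i] -= 2 * eps
            lm, _ = berhu_loss_grad(p, target)
            assert grad[i] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(c=0.0)


class TestClosedFormMetrics:
    def test_r_squared_exact_prediction(self, rng):
        y = rng.normal(size=50)
        assert r_squared(y, y) == pytest.approx(1.0)

    def test_r_squared_mean_prediction_is_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.full(3, 2.0)) == pytest.approx(0.0)

    def test_r_squared_hand_value(self):
        assert r_squared(np.array([1.0, 2.0, 3.0]),
                         np.array([1.0, 2.0, 4.0])) == pytest.approx(0.5)

    def test_r_squared_constant_truth_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            r_squared(np.ones(5), np.zeros(5))

    def test_mae_hand_value(self):
        assert mae(np.array([1.0, 2.0, 3.0]),
                   np.array([2.0, 2.0, 2.0])) == pytest.approx(2.0 / 3.0)

    def test_mae_symmetry(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert mae(a, b) == pytest.approx(mae(b, a))

    def test_tanimoto_identity(self, rng):
        y = rng.normal(size=30)
        assert tanimoto(y, y) == pytest.approx(1.0)

    def test_tanimoto_orthogonal(self):
        assert tanimoto(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_tanimoto_hand_value(self):
        assert tanimoto(np.array([1.0, 2.0]),
                        np.array([2.0, 1.0])) == pytest.approx(2.0 / 3.0)

    def test_tanimoto_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            tanimoto(np.zeros(4), np.zeros(4))

    def test_ssim_identity(self, rng):
        y = rng.normal(size=100)
        assert ssim_global(y, y) == pytest.approx(1.0)

    def test_ssim_penalises_constant_shift(self, rng):
        y = rng.normal(0.0, 0.3, size=500)
        shifted = y + 0.2
        val = ssim_global(y, shifted)
        # direct evaluation of the formula as an independent oracle
        mu_y, mu_p = y.mean(), shifted.mean()
        cfg = SSIMConfig()
        expected = ((2 * mu_p * mu_y + cfg.C1) * (2 * y.var() + cfg.C2)) / \
                   ((mu_p ** 2 + mu_y ** 2 + cfg.C1) * (2 * y.var() + cfg.C2))
        assert val == pytest.approx(expected, abs=1e-12)
        assert val < 1.0

    def test_ssim_constant_equal_maps(self):
        assert ssim_global(np.full(10, 0.3), np.full(10, 0.3)) == pytest.approx(1.0)


class TestOracleEquivalence:
    """Vectorised implementations agree with naive one-line formulas."""

    @given(arrays(np.float64, st.integers(2, 200),
                  elements=st.floats(-1.0, 1.0, width=32)),
           st.integers(0, 2 ** 31 - 1))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_all_metrics_match_naive_formulas(self, y, seed):
        y_hat = y + np.random.default_rng(seed).normal(0, 0.1, size=y.shape)
        n = y.size
        assert mae(y, y_hat) == pytest.approx(
            sum(abs(y[i] - y_hat[i]) for i in range(n)) / n, abs=1e-10)
        sstot = sum((v - y.mean()) ** 2 for v in y)
        if sstot > 1e-6:  # avoid float-noise amplification in the ratio
            naive_r2 = 1 - sum((y[i] - y_hat[i]) ** 2 for i in range(n)) / sstot
            assert r_squared(y, y_hat) == pytest.approx(naive_r2, abs=1e-8)
        dot = sum(y[i] * y_hat[i] for i in range(n))
        denom = sum(v * v for v in y) + sum(v * v for v in y_hat) - dot
        if abs(denom) > 1e-6:
            assert tanimoto(y, y_hat) == pytest.approx(dot / denom, abs=1e-10)

    @given(st.integers(0, 1000))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=64)
        y_hat = rng.normal(size=64)
        perm = rng.permutation(64)
        assert r_squared(y, y_hat) == pytest.approx(r_squared(y[perm], y_hat[perm]))
        assert tanimoto(y, y_hat) == pytest.approx(tanimoto(y[perm], y_hat[perm]))
        assert ssim_global(y, y_hat) == pytest.approx(
            ssim_global(y[perm], y_hat[perm]))


class TestEvaluateSubject:
    @staticmethod
    def _pair(rng):
        truth = rng.uniform(-0.9, 0.9, size=(5, 3, 8, 8))
        mask = np.zeros((3, 8, 8), dtype=bool)
        mask[:, 2:6, 2:6] = True
        return (CollateralMapSet(maps=truth, value_range="signed"),
                BrainMask(mask=mask))

    def test_perfect_prediction_scores(self, rng):
        truth, mask = self._pair(rng)
        res = evaluate_subject(truth, truth, mask)
        for phase, metrics in res.items():
            assert metrics["r_squared"] == pytest.approx(1.0)
            assert metrics["mae"] == 0.0
            assert metrics["ssim"] == pytest.approx(1.0)
            assert metrics["tanimoto"] == pytest.approx(1.0)

    def test_record_has_five_phases_four_metrics(self, rng):
        truth, mask = self._pair(rng)
        res = evaluate_subject(truth, truth, mask)
        assert set(res) == {"Art", "Cap", "EVen", "LVen", "Del"}
        assert all(len(m) == 4 for m in res.values())

    def test_shuffled_prediction_scores_poorly(self, noiseless_phantom):
        from collimap.preprocess import PreprocessConfig, preprocess_targets
        cfg = PreprocessConfig(crop_size=32)
        truth = preprocess_targets(noiseless_phantom.maps, cfg)
        rng = np.random.default_rng(0)
        flat = truth.maps.reshape(5, -1).copy()
        for row in flat:
            rng.shuffle(row)
        shuffled = CollateralMapSet(maps=flat.reshape(truth.maps.shape),
                                    value_range="signed")
        res = evaluate_subject(shuffled, truth, noiseless_phantom.brain)
        assert np.mean([m["r_squared"] for m in res.values()]) <= 0.0
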