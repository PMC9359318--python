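"""Threshold mechanics: summaries, abstention reports, the learned cutoff."""

import numpy as np
import pytest

from vdpnet.detect import (
    ThresholdRegressor,
    ThresholdRegressorSpec,
    apply_learned_threshold,
    apply_threshold,
    build_threshold_training_set,
    select_fixed_threshold,
    summarize_variance,
    train_threshold_regressor,
)
from vdpnet.network import PredictionRecord


def rec(var, correct, bin_label="none"):
    return PredictionRecord(
        decision=0,
        mean_vector=np.array([0.6, 0.4]),
        predictive_variance=var,
        correctness=correct,
        noise_bin=bin_label,
    )


class TestSummaries:
    def test_all_correct_bin_marks_incorrect_median_absent(self):
        out = summarize_variance({"none": [rec(1.0, True), rec(2.0, True), rec(3.0, True)]})
        s = out[0]
        assert s.median_correct == 2.0
        assert s.median_incorrect is None
        assert s.median_combined == 2.0
        assert s.accuracy_pct == 100.0

    def test_split_medians(self):
        records = [rec(0.1, True), rec(0.3, True), rec(0.9, False)]
        s = summarize_variance({"b": records})[0]
        assert s.median_correct == pytest.approx(0.2)
        assert s.median_incorrect == pytest.approx(0.9)
        assert s.median_combined == pytest.approx(0.3)

    def test_order_invariance(self):
        records = [rec(v, c) for v, c in [(0.5, True), (0.1, False), (0.9, True), (0.2, False)]]
        a = summarize_variance({"b": records})[0]
        b = summarize_variance({"b": records[::-1]})[0]
        assert (a.median_correct, a.median_incorrect, a.median_combined) == (
            b.median_correct, b.median_incorrect, b.median_combined)

    def test_empty_bin_rejected(self):
        with pytest.raises(ValueError):
            summarize_variance({"none": []})


class TestFixedThresholdSelection:
    def make_summaries(self):
        return summarize_variance(
            {
                "none": [rec(0.0008, True), rec(0.5, False)],
                "high": [rec(0.9, True), rec(2.0, False)],
            }
        )

    def test_correct_median_at_minimum_noise(self):
        assert select_fixed_threshold(self.make_summaries()) == pytest.approx(0.0008)

    def test_combined_median_strategy(self):
        tau = select_fixed_threshold(self.make_summaries(), "combined-at-min-noise")
        assert tau == pytest.approx((0.0008 + 0.5) / 2)

    def test_manual_echoes_value(self):
        assert select_fixed_threshold([], "manual", manual_value=0.03) == 0.03

    def test_only_minimum_noise_bin_is_read(self):
        a = self.make_summaries()
        b = summarize_variance(
            {
                "none": [rec(0.0008, True), rec(0.5, False)],
                "high": [rec(123.0, True), rec(456.0, False)],
            }
        )
        assert select_fixed_threshold(a) == select_fixed_threshold(b)

    def test_missing_bin_rejected(self):
        with pytest.raises(ValueError):
            select_fixed_threshold(self.make_summaries(), min_noise_bin="missing")


class TestApplyThreshold:
    def test_enumerated_split(self):
        records = [rec(0.1, True), rec(0.2, False), rec(0.9, True), rec(1.5, False)]
        report = apply_threshold(records, 0.5)
        assert report.abstained_pct == pytest.approx(50.0)
        assert report.pre_accuracy_pct == pytest.approx(50.0)
        assert report.post_accuracy_pct == pytest.approx(50.0)

    def test_infinite_threshold_retains_everything(self):
        records = [rec(0.1, True), rec(5.0, False)]
        report = apply_threshold(records, np.inf)
        assert report.abstained_pct == 0.0
        assert report.post_accuracy_pct == report.pre_accuracy_pct

    def test_zero_threshold_with_positive_variances_abstains_all(self):
        records = [rec(0.1, True), rec(0.2, False)]
        report = apply_threshold(records, 0.0)
        assert report.abstained_pct == 100.0
        assert report.post_accuracy_pct is None  # undefined, never 100%

    def test_tie_at_threshold_is_retained(self):
        report = apply_threshold([rec(0.5, True)], 0.5)
        assert report.abstained_pct == 0.0

    def test_pure_function(self):
        records = [rec(0.3, True), rec(0.7, False)]
        assert apply_threshold(records, 0.4) == apply_threshold(records, 0.4)

    def test_abstained_fraction_non_increasing_in_tau(self):
        rng = np.random.default_rng(0)
        records = [rec(float(v), bool(c)) for v, c in zip(rng.random(60), rng.random(60) > 0.4)]
        taus = np.sort(rng.random(15))
        fractions = [apply_threshold(records, t).abstained_pct for t in taus]
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))


class TestLearnedThreshold:
    def _stub_regressor(self, value, shape=(1, 14, 14)):
        reg = ThresholdRegressor(shape, ThresholdRegressorSpec(epochs=1))
        reg.fc2.w_mean.data[:] = 0.0
        reg.fc2.b_mean.data[:] = np.sqrt(value) if value > 0 else 0.0
        return reg

    def test_huge_cutoff_abstains_nothing_zero_cutoff_abstains_all(self):
        records = [rec(0.1, True), rec(0.4, False)]
        images = np.zeros((2, 1, 14, 14), np.float32)
        hi = apply_learned_threshold(records, images, self._stub_regressor(1e9))
        assert hi.abstained_pct == 0.0
        lo = apply_learned_threshold(records, images, self._stub_regressor(0.0))
        assert lo.abstained_pct == 100.0 and lo.post_accuracy_pct is None

    def test_noisy_copy_shares_clean_target(self, tiny_model):
        vdp, _ = tiny_model
        rng = np.random.default_rng(1)
        images = rng.random((8, 1, 14, 14)).astype(np.float32)
        spec = ThresholdRegressorSpec(noise_snrs_db=(10.0, 0.0), seed=3)
        x_all, y_all = build_threshold_training_set(vdp, images, spec)
        assert x_all.shape[0] == 3 * 8
        assert np.array_equal(y_all[:8], y_all[8:16])
        assert np.array_equal(y_all[:8], y_all[16:24])
        assert not np.array_equal(x_all[:8], x_all[8:16])

    def test_constant_targets_warn_and_predict_near_zero(self, tiny_model):
        vdp, _ = tiny_model
        for layer in vdp.layers():  # force a variance-free model
            layer.w_logvar.data[:] = -np.inf
            layer.b_logvar.data[:] = -np.inf
        rng = np.random.default_rng(2)
        images = rng.random((12, 1, 14, 14)).astype(np.float32)
        spec = ThresholdRegressorSpec(epochs=25, noise_snrs_db=(), seed=4)
        before = ThresholdRegressor((1, 14, 14), spec).predict(images)
        with pytest.warns(RuntimeWarning):
            reg, _ = train_threshold_regressor(vdp, images, spec)
        after = reg.predict(images)
        assert after.mean() < 0.25 * before.mean()  # shrinking toward the 0 target

    @pytest.mark.parametrize("preset,loss", [("fc", "mse"), ("conv-fc", "mae")])
    def test_fit_loss_non_increasing_early(self, tiny_model, preset, loss):
        vdp, _ = tiny_model
        rng = np.random.default_rng(5)
        images = rng.random((24, 1, 14, 14)).astype(np.float32)
        spec = ThresholdRegressorSpec(
            preset=preset, loss=loss, epochs=5, batch_size=96, lr=0.01,
            noise_snrs_db=(5.0,), seed=6,
        )
        _, fit_log = train_threshold_regressor(vdp, images, spec)
        losses = fit_log["loss"].to_numpy()
        assert np.all(np.diff(losses) <= 1e-12)

    def test_misaligned_inputs_rejected(self):
        reg = self._stub_regressor(1.0)
        with pytest.raises(ValueError):
            apply_learned_threshold([rec(0.1, True)], np.zeros((2, 1, 14, 14)), reg)


def test_invalid_regressor_spec():
    with pytest.raises(ValueError):
        ThresholdRegressorSpec(loss="huber")
    with pytest.raises(ValueError):
        ThresholdRegressorSpec(preset="transformer")
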