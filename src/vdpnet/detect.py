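"""Failure detection by thresholding the predictive variance.

Two mechanisms are provided.  The *fixed* threshold is a single variance
cutoff, by default the median predictive variance of the correct decisions
at the minimum tested noise level (the combined median and a manual value
are the alternatives).  The *learned* threshold is a small regression
network trained to map an image — clean or noise-corrupted — to the
predictive variance its clean counterpart receives from the trained
variational classifier; at test time each sample is compared against its
own predicted cutoff.

A sample abstains ("no decision") when its predictive variance is strictly
greater than the applicable threshold; a sample exactly at the threshold is
retained.  Reports carry the pre-threshold accuracy, the abstained
fraction, and the post-threshold accuracy over the retained samples (which
is undefined, not 100%, when everything abstains).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .network import PredictionRecord, VDPClassifier, _ConvLayer, _LinearLayer
from .perturb import add_gaussian_noise_at_snr

__all__ = [
    "VarianceSummary",
    "AbstentionReport",
    "ThresholdRegressorSpec",
    "ThresholdRegressor",
    "summarize_variance",
    "select_fixed_threshold",
    "apply_threshold",
    "train_threshold_regressor",
    "apply_learned_threshold",
    "summaries_to_frame",
]


@dataclass
class VarianceSummary:
    """Median predictive variances and accuracy for one noise bin."""

    bin_label: str
    median_correct: Optional[float]
    median_incorrect: Optional[float]
    median_combined: float
    accuracy_pct: float
    count: int


@dataclass
class AbstentionReport:
    threshold_desc: str
    pre_accuracy_pct: float
    abstained_pct: float
    post_accuracy_pct: Optional[float]  # None when no sample is retained


@dataclass
class ThresholdRegressorSpec:
    """Architecture and fit settings for the learned threshold."""

    preset: str = "fc"  # "fc" (fc-only) or "conv-fc"
    loss: str = "mse"  # "mse" or "mae"
    hidden: int = 32
    epochs: int = 20
    lr: float = 0.02
    batch_size: int = 64
    clip_norm: float = 1.0
    noise_snrs_db: Sequence[float] = (25.0, 15.0, 5.0)
    seed: int = 0

    def __post_init__(self):
        if self.loss not in ("mse", "mae"):
            raise ValueError("loss must be 'mse' or 'mae'")
        if self.preset not in ("fc", "conv-fc"):
            raise ValueError("preset must be 'fc' or 'conv-fc'")


# ----------------------------------------------------------------------
# summaries and thresholds
# ----------------------------------------------------------------------


def _median(values: List[float]) -> Optional[float]:
    return float(np.median(values)) if values else None


def summarize_variance(
    records_by_bin: Dict[str, Sequence[PredictionRecord]]
) -> List[VarianceSummary]:
    """Per-bin medians of correct / incorrect / combined predictive variance."""
    out = []
    for label, records in records_by_bin.items():
        if not records:
            raise ValueError(f"noise bin {label!r} has no records")
        if any(r.correctness is None for r in records):
            raise ValueError("variance summaries need correctness flags")
        correct = [r.predictive_variance for r in records if r.correctness]
        incorrect = [r.predictive_variance for r in records if not r.correctness]
        combined = [r.predictive_variance for r in records]
        out.append(
            VarianceSummary(
                bin_label=label,
                median_correct=_median(correct),
                median_incorrect=_median(incorrect),
                median_combined=float(np.median(combined)),
                accuracy_pct=100.0 * len(correct) / len(records),
                count=len(records),
            )
        )
    return out


def select_fixed_threshold(
    summaries: Sequence[VarianceSummary],
    strategy: str = "correct-at-min-noise",
    min_noise_bin: Optional[str] = None,
    manual_value: Optional[float] = None,
) -> float:
    """Pick the fixed variance cutoff from the minimum-noise bin.

    ``correct-at-min-noise`` (the default, and the setting reported to give
    the highest retained accuracy) returns that bin's correct-decision
    median; ``combined-at-min-noise`` the combined median; ``manual``
    echoes ``manual_value``.
    """
    if strategy == "manual":
        if manual_value is None:
            raise ValueError("manual strategy needs manual_value")
        return float(manual_value)
    min_noise_bin = summaries[0].bin_label if min_noise_bin is None else min_noise_bin
    match = [s for s in summaries if s.bin_label == min_noise_bin]
    if not match:
        raise ValueError(f"no summary for minimum-noise bin {min_noise_bin!r}")
    summary = match[0]
    if strategy == "correct-at-min-noise":
        if summary.median_correct is None:
            raise ValueError("minimum-noise bin has no correct decisions")
        return summary.median_correct
    if strategy == "combined-at-min-noise":
        return summary.median_combined
    raise ValueError(f"unknown strategy {strategy!r}")


def _report(retained_correct, n_retained, n_total, pre_acc, desc) -> AbstentionReport:
    abstained_pct = 100.0 * (n_total - n_retained) / n_total
    post = 100.0 * retained_correct / n_retained if n_retained else None
    return AbstentionReport(
        threshold_desc=desc,
        pre_accuracy_pct=pre_acc,
        abstained_pct=abstained_pct,
        post_accuracy_pct=post,
    )


def apply_threshold(records: Sequence[PredictionRecord], tau: float) -> AbstentionReport:
    """Abstain on variance strictly above ``tau``; ties are retained."""
    if tau < 0:
        raise ValueError("threshold must be non-negative")
    if not records:
        raise ValueError("no records to threshold")
    if any(r.correctness is None for r in records):
        raise ValueError("abstention reports need correctness flags")
    pre = 100.0 * np.mean([r.correctness for r in records])
    kept = [r for r in records if r.predictive_variance <= tau]
    return _report(
        sum(r.correctness for r in kept), len(kept), len(records), float(pre), f"fixed:{tau:g}"
    )


# ----------------------------------------------------------------------
# the learned threshold
# ----------------------------------------------------------------------


class ThresholdRegressor:
    """Small network mapping an image to a variance cutoff.

    ``fc`` preset: flatten - dense(hidden) - relu - dense(1).
    ``conv-fc`` preset: 3x3 conv (4 maps) - relu - 2x2 pool - flatten -
    dense(hidden) - relu - dense(1).
    The output is squared to keep predicted cutoffs non-negative.
    """

    def __init__(self, input_shape, spec: ThresholdRegressorSpec):
        self.spec = spec
        self.input_shape = tuple(input_shape)
        rng = np.random.default_rng(spec.seed)
        c, h, w = self.input_shape
        self.conv = None
        if spec.preset == "conv-fc":
            self.conv = _ConvLayer(c, 4, 3, 0, (h, w), rng, 0.0, stochastic=False)
            ho, wo = self.conv.out_hw
            ho, wo = ho // 2, wo // 2
            n_in = 4 * ho * wo
            self._pooled_hw = (ho, wo)
        else:
            n_in = c * h * w
        self.fc1 = _LinearLayer(n_in, spec.hidden, rng, 0.0, stochastic=False)
        self.fc2 = _LinearLayer(spec.hidden, 1, rng, 0.0, stochastic=False)

    def params(self):
        layers = [self.fc1, self.fc2] + ([self.conv] if self.conv else [])
        return [p for layer in layers for p in layer.params()]

    def _forward(self, x):
        batch = x.shape[0]
        if self.conv is not None:
            from .network import _maxpool_mv, _relu_mv

            h_out, _ = self.conv.forward(x, None, want_var=False)
            h_out, _ = _relu_mv(h_out, None)
            h_out, _ = _maxpool_mv(h_out, None)
            flat = ad.reshape(h_out, (batch, -1))
        else:
            c, hgt, wid = self.input_shape
            flat = ad.reshape(x, (batch, c * hgt * wid))
        hid, _ = self.fc1.forward(flat, None, want_var=False)
        hid = ad.relu(hid)
        out, _ = self.fc2.forward(hid, None, want_var=False)
        return out * out  # non-negative cutoff

    def predict(self, images: np.ndarray) -> np.ndarray:
        out = self._forward(Tensor(np.asarray(images, dtype=np.float32)))
        return out.data.reshape(-1).astype(float)

    def fit(self, images: np.ndarray, targets: np.ndarray) -> pd.DataFrame:
        spec = self.spec
        targets = np.asarray(targets, dtype=np.float32).reshape(-1, 1)
        if np.ptp(targets) == 0:
            warnings.warn(
                "all regression targets identical; fitting a constant predictor",
                RuntimeWarning,
            )
        images = np.asarray(images, dtype=np.float32)
        rng = np.random.default_rng(spec.seed)
        n = len(images)
        rows = []
        params = self.params()
        for epoch in range(spec.epochs):
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, spec.batch_size):
                sel = perm[start : start + spec.batch_size]
                pred = self._forward(Tensor(images[sel]))
                resid = pred - targets[sel]
                if spec.loss == "mse":
                    loss = ad.tsum(resid * resid) * (1.0 / len(sel))
                else:
                    # smooth |r| ~ sqrt(r^2 + delta) keeps the tape simple
                    loss = ad.tsum((resid * resid + 1e-12) ** 0.5) * (1.0 / len(sel))
                losses.append(float(loss.data))
                for p in params:
                    p.zero_grad()
                loss.backward()
                gnorm = np.sqrt(
                    sum(float((p.grad**2).sum()) for p in params if p.grad is not None)
                )
                step = spec.lr * min(1.0, spec.clip_norm / max(gnorm, 1e-12))
                for p in params:
                    if p.grad is not None:
                        p.data = p.data - step * p.grad.astype(p.data.dtype)
            rows.append({"epoch": epoch, "loss": float(np.mean(losses))})
        return pd.DataFrame(rows)


def build_threshold_training_set(
    model: VDPClassifier,
    images: np.ndarray,
    spec: ThresholdRegressorSpec,
):
    """Regression pairs for the learned threshold.

    Inputs are each clean image plus one Gaussian-corrupted copy per SNR in
    ``spec.noise_snrs_db``; every copy's regression target is the
    variational model's predictive variance for the *clean* image.
    """
    from .network import predict_batch

    images = np.asarray(images, dtype=np.float32)
    records = predict_batch(model, images)
    targets_clean = np.array([r.predictive_variance for r in records], dtype=np.float32)
    xs, ys = [images], [targets_clean]
    for j, snr in enumerate(spec.noise_snrs_db):
        noisy = np.stack(
            [
                add_gaussian_noise_at_snr(img, snr, seed=spec.seed + 104_729 * j + i)[0]
                for i, img in enumerate(images)
            ]
        ).astype(np.float32)
        xs.append(noisy)
        ys.append(targets_clean)  # noisy copy shares the clean target
    return np.concatenate(xs), np.concatenate(ys)


def train_threshold_regressor(
    model: VDPClassifier,
    train_images: np.ndarray,
    spec: ThresholdRegressorSpec,
    max_images: Optional[int] = None,
):
    """Fit the learned threshold; returns ``(regressor, fit_log)``.

    See :func:`build_threshold_training_set` for the dataset contract.
    ``max_images`` subsamples the clean pool before corruption.
    """
    images = np.asarray(train_images, dtype=np.float32)
    if max_images is not None and len(images) > max_images:
        rng = np.random.default_rng(spec.seed)
        images = images[rng.choice(len(images), max_images, replace=False)]
    x_all, y_all = build_threshold_training_set(model, images, spec)
    reg = ThresholdRegressor(model.spec.input_shape, spec)
    fit_log = reg.fit(x_all, y_all)
    return reg, fit_log


def apply_learned_threshold(
    records: Sequence[PredictionRecord],
    images: np.ndarray,
    regressor: ThresholdRegressor,
) -> AbstentionReport:
    """Abstain where a sample's variance exceeds its own predicted cutoff."""
    if len(records) != len(images):
        raise ValueError("records and images are misaligned")
    if any(r.correctness is None for r in records):
        raise ValueError("abstention reports need correctness flags")
    taus = regressor.predict(images)
    pre = 100.0 * np.mean([r.correctness for r in records])
    kept = [r for r, tau in zip(records, taus) if r.predictive_variance <= tau]
    return _report(
        sum(r.correctness for r in kept),
        len(kept),
        len(records),
        float(pre),
        f"learned:{regressor.spec.preset}/{regressor.spec.loss}",
    )


def summaries_to_frame(summaries: Sequence[VarianceSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin": [s.bin_label for s in summaries],
            "median_var_correct": [s.median_correct for s in summaries],
            "median_var_incorrect": [s.median_incorrect for s in summaries],
            "median_var_combined": [s.median_combined for s in summaries],
            "accuracy_pct": [s.accuracy_pct for s in summaries],
            "n": [s.count for s in summaries],
        }
    )
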