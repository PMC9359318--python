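"""Variational-density-propagation classifiers and their deterministic twins.

The classifier is a scaled-down residual CNN: stem convolution, one
residual block per stage with a max-pool and a channel-doubling transition
between stages, then a fully-connected head and a softmax.  The variational
model propagates elementwise (diagonal) variances through every layer using
the moment formulas of :mod:`vdpnet.moments`; the deterministic twin shares
the architecture and runs only the mean path, so with all weight variances
at zero the two forwards are identical arithmetic.

Training minimizes the negative ELBO (variational model) or cross-entropy
(twin) by plain stochastic gradient descent through the package's autodiff
engine.  Both objectives are internally scaled by ``1/N`` so learning rates
are per-sample quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .gaussian import RandomParameter
from .losses import LossConfig, ell_diag, kl_diag
from .moments import conv_out_side, patch_index_map

__all__ = [
    "NetworkSpec",
    "PredictionRecord",
    "TrainLog",
    "VDPClassifier",
    "build_network",
    "train",
    "predict_batch",
    "records_to_frame",
    "accuracy_probability_gap",
]

_VARIANCE_KINDS = ("decision", "trace", "max")


@dataclass
class NetworkSpec:
    """Architecture and initialization of a classifier pair.

    ``stage_channels`` gives the channel width of each stage; every stage is
    a residual block, and stages are separated by a 2x2 max-pool plus a 3x3
    transition convolution.  ``variance_kind`` selects the scalar reduction
    of the predictive covariance attached to each decision.
    """

    input_shape: Tuple[int, int, int] = (1, 28, 28)
    num_classes: int = 4
    stem_channels: int = 8
    stage_channels: Tuple[int, ...] = (8, 16)
    variance_kind: str = "decision"
    init_logvar: float = -6.0
    seed: int = 0

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.variance_kind not in _VARIANCE_KINDS:
            raise ValueError(f"variance_kind must be one of {_VARIANCE_KINDS}")
        if self.stage_channels and self.stage_channels[0] != self.stem_channels:
            raise ValueError("first stage width must match the stem width")


@dataclass
class PredictionRecord:
    decision: int
    mean_vector: np.ndarray
    predictive_variance: float
    correctness: Optional[bool] = None
    noise_bin: Optional[str] = None

    def __post_init__(self):
        if self.predictive_variance < 0:
            raise ValueError("predictive variance must be non-negative")


@dataclass
class TrainLog:
    rows: List[dict] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


# ----------------------------------------------------------------------
# layers
# ----------------------------------------------------------------------


class _ConvLayer:
    """3x3 convolution with Gaussian weights (mean + log-variance)."""

    def __init__(self, c_in, c_out, kernel, padding, in_hw, rng, init_logvar, stochastic):
        k = kernel
        fan_in = c_in * k * k
        std = math.sqrt(2.0 / fan_in)
        self.w_mean = Tensor(
            (std * rng.standard_normal((c_out, fan_in))).astype(np.float32),
            requires_grad=True,
        )
        self.b_mean = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
        self.stochastic = stochastic
        if stochastic:
            self.w_logvar = Tensor(
                np.full((c_out, fan_in), init_logvar, dtype=np.float32),
                requires_grad=True,
            )
            self.b_logvar = Tensor(
                np.full(c_out, init_logvar, dtype=np.float32), requires_grad=True
            )
        self.kernel = k
        self.padding = padding
        self.c_in, self.c_out = c_in, c_out
        h, w = in_hw
        self.in_hw = in_hw
        self.out_hw = (conv_out_side(h, k, 1, padding), conv_out_side(w, k, 1, padding))
        hp, wp = h + 2 * padding, w + 2 * padding
        idx, _, _ = patch_index_map((c_in, hp, wp), k, 1, 0)
        self._idx = idx  # (L, K) into a padded single image
        self._per_image = c_in * hp * wp
        self._batch_idx = {}

    def params(self):
        ps = [self.w_mean, self.b_mean]
        if self.stochastic:
            ps += [self.w_logvar, self.b_logvar]
        return ps

    def random_parameters(self):
        if not self.stochastic:
            return []
        return [
            RandomParameter(
                self.w_mean.data.astype(float),
                np.exp(self.w_logvar.data.astype(float)),
                role="conv-kernel",
            ),
            RandomParameter(
                self.b_mean.data.astype(float),
                np.exp(self.b_logvar.data.astype(float)),
                role="bias",
            ),
        ]

    def _indices(self, batch):
        if batch not in self._batch_idx:
            if len(self._batch_idx) >= 2:  # bound the cache: keep two batch sizes
                self._batch_idx.pop(next(iter(self._batch_idx)))
            offs = (np.arange(batch) * self._per_image)[:, None, None]
            self._batch_idx[batch] = (self._idx[None] + offs).astype(np.int32)
        return self._batch_idx[batch]

    def _patches(self, x):
        batch = x.shape[0]
        xp = ad.pad2d(x, self.padding)
        return ad.take(xp, self._indices(batch))  # (B, L, K)

    def forward(self, mean, var, want_var=True):
        batch = mean.shape[0]
        ho, wo = self.out_hw
        pm = self._patches(mean)
        out_mean = ad.matmul(pm, ad.transpose(self.w_mean)) + self.b_mean
        out_var = None
        if not want_var:
            pass
        elif self.stochastic:
            wv = ad.exp(self.w_logvar)
            bv = ad.exp(self.b_logvar)
            if var is None:  # first layer: constant input, random weights
                out_var = ad.matmul(pm * pm, ad.transpose(wv)) + bv
            else:  # random times random (diagonal form)
                pv = self._patches(var)
                out_var = (
                    ad.matmul(pv, ad.transpose(self.w_mean * self.w_mean + wv))
                    + ad.matmul(pm * pm, ad.transpose(wv))
                    + bv
                )
        elif var is not None:  # deterministic weights on a random signal
            pv = self._patches(var)
            out_var = ad.matmul(pv, ad.transpose(self.w_mean * self.w_mean))

        def to_maps(t):
            return ad.reshape(
                ad.transpose(ad.reshape(t, (batch, ho * wo, self.c_out)), (0, 2, 1)),
                (batch, self.c_out, ho, wo),
            )

        return to_maps(out_mean), (None if out_var is None else to_maps(out_var))


class _LinearLayer:
    def __init__(self, n_in, n_out, rng, init_logvar, stochastic):
        std = math.sqrt(2.0 / n_in)
        self.w_mean = Tensor(
            (std * rng.standard_normal((n_out, n_in))).astype(np.float32),
            requires_grad=True,
        )
        self.b_mean = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)
        self.stochastic = stochastic
        if stochastic:
            self.w_logvar = Tensor(
                np.full((n_out, n_in), init_logvar, dtype=np.float32), requires_grad=True
            )
            self.b_logvar = Tensor(
                np.full(n_out, init_logvar, dtype=np.float32), requires_grad=True
            )

    def params(self):
        ps = [self.w_mean, self.b_mean]
        if self.stochastic:
            ps += [self.w_logvar, self.b_logvar]
        return ps

    def random_parameters(self):
        if not self.stochastic:
            return []
        return [
            RandomParameter(
                self.w_mean.data.astype(float),
                np.exp(self.w_logvar.data.astype(float)),
                role="fc-weight",
            ),
            RandomParameter(
                self.b_mean.data.astype(float),
                np.exp(self.b_logvar.data.astype(float)),
                role="bias",
            ),
        ]

    def forward(self, mean, var, want_var=True):
        out_mean = ad.matmul(mean, ad.transpose(self.w_mean)) + self.b_mean
        out_var = None
        if not want_var:
            pass
        elif self.stochastic:
            wv = ad.exp(self.w_logvar)
            bv = ad.exp(self.b_logvar)
            if var is None:
                out_var = ad.matmul(mean * mean, ad.transpose(wv)) + bv
            else:
                out_var = (
                    ad.matmul(var, ad.transpose(self.w_mean * self.w_mean + wv))
                    + ad.matmul(mean * mean, ad.transpose(wv))
                    + bv
                )
        elif var is not None:
            out_var = ad.matmul(var, ad.transpose(self.w_mean * self.w_mean))
        return out_mean, out_var


def _relu_mv(mean, var):
    mask = (mean.data if isinstance(mean, Tensor) else mean) > 0
    out_mean = ad.relu(mean)
    return out_mean, (None if var is None else var * mask.astype(np.float32))


def _maxpool_mv(mean, var, window=2):
    batch, c, h, w = mean.shape
    ho, wo = (h - window) // window + 1, (w - window) // window + 1
    mean = ad.crop2d(mean, ho * window, wo * window)
    if var is not None:
        var = ad.crop2d(var, ho * window, wo * window)

    def windows(t):
        t = ad.reshape(t, (batch, c, ho, window, wo, window))
        t = ad.transpose(t, (0, 1, 2, 4, 3, 5))
        return ad.reshape(t, (batch, c, ho, wo, window * window))

    mw = windows(mean)
    arg = (mw.data if isinstance(mw, Tensor) else mw).argmax(axis=-1)
    out_mean = ad.select_last(mw, arg)
    out_var = None if var is None else ad.select_last(windows(var), arg)
    return out_mean, out_var


def _softmax_mv(mean, var):
    g = ad.softmax(mean, axis=-1)
    if var is None:
        return g, None
    s = ad.tsum(g * g * var, axis=-1, keepdims=True)
    out_var = g * g * (var * (1.0 - 2.0 * g) + s)
    return g, out_var


# ----------------------------------------------------------------------
# the classifier
# ----------------------------------------------------------------------


class VDPClassifier:
    """Residual CNN propagating diagonal Gaussian moments (or means only)."""

    def __init__(self, spec: NetworkSpec, stochastic: bool = True, rng=None):
        self.spec = spec
        self.stochastic = stochastic
        rng = np.random.default_rng(spec.seed) if rng is None else rng
        c_in, h, w = spec.input_shape
        ilv = spec.init_logvar
        self.stem = _ConvLayer(c_in, spec.stem_channels, 3, 0, (h, w), rng, ilv, stochastic)
        hw = self.stem.out_hw
        hw = (hw[0] // 2, hw[1] // 2)  # pool directly after the stem
        chans = spec.stem_channels
        self.stages = []  # (transition conv or None, residual pair)
        for si, width in enumerate(spec.stage_channels):
            if si > 0:
                hw = (hw[0] // 2, hw[1] // 2)  # pool between stages
                trans = _ConvLayer(chans, width, 3, 1, hw, rng, ilv, stochastic)
                hw = trans.out_hw
                chans = width
            else:
                trans = None
            block = (
                _ConvLayer(chans, chans, 3, 1, hw, rng, ilv, stochastic),
                _ConvLayer(chans, chans, 3, 1, hw, rng, ilv, stochastic),
            )
            self.stages.append((trans, block))
        hw = (hw[0] // 2, hw[1] // 2)  # final pool
        self.head = _LinearLayer(
            chans * hw[0] * hw[1], spec.num_classes, rng, ilv, stochastic
        )
        self._flat = chans * hw[0] * hw[1]

    # -- parameters --------------------------------------------------
    def layers(self):
        out = [self.stem]
        for trans, block in self.stages:
            if trans is not None:
                out.append(trans)
            out.extend(block)
        out.append(self.head)
        return out

    def params(self) -> List[Tensor]:
        return [p for layer in self.layers() for p in layer.params()]

    def random_parameters(self) -> List[RandomParameter]:
        return [rp for layer in self.layers() for rp in layer.random_parameters()]

    def zero_grad(self):
        for p in self.params():
            p.zero_grad()

    # -- forward ------------------------------------------------------
    def forward(self, x, with_variance: bool = True):
        """Propagate a batch ``(B, C, H, W)``; returns (probs, var or None)."""
        if not isinstance(x, Tensor):
            x = np.asarray(x, dtype=np.float32)
        mean, var = x, None
        want_var = with_variance and self.stochastic
        mean, var = self.stem.forward(mean, None, want_var)
        mean, var = _relu_mv(mean, var)
        mean, var = _maxpool_mv(mean, var)
        for si, (trans, block) in enumerate(self.stages):
            if trans is not None:
                mean, var = _maxpool_mv(mean, var)
                mean, var = trans.forward(mean, var, want_var)
                mean, var = _relu_mv(mean, var)
            skip_m, skip_v = mean, var
            mean, var = block[0].forward(mean, var, want_var)
            mean, var = _relu_mv(mean, var)
            mean, var = block[1].forward(mean, var, want_var)
            # skip and branch treated as uncorrelated in diagonal mode
            mean = mean + skip_m
            if var is not None and skip_v is not None:
                var = var + skip_v
            mean, var = _relu_mv(mean, var)
        mean, var = _maxpool_mv(mean, var)
        batch = mean.shape[0]
        mean = ad.reshape(mean, (batch, self._flat))
        if var is not None:
            var = ad.reshape(var, (batch, self._flat))
        mean, var = self.head.forward(mean, var, want_var)
        return _softmax_mv(mean, var)

    # -- gradients for adversarial crafting ---------------------------
    def input_gradient(self, images: np.ndarray, labels: np.ndarray) -> np.ndarray:
        """d/dx of mean cross-entropy on the predictive mean."""
        x = Tensor(np.asarray(images, dtype=np.float32), requires_grad=True)
        probs, _ = self.forward(x, with_variance=False)
        batch = probs.shape[0]
        onehot = np.eye(self.spec.num_classes, dtype=np.float32)[np.asarray(labels)]
        loss = -ad.tsum(onehot * ad.log(probs + 1e-12)) * (1.0 / batch)
        loss.backward()
        return np.asarray(x.grad)


def build_network(spec: NetworkSpec):
    """Build the variational classifier and its deterministic twin.

    Both models draw their initial weight means from the same seeded stream,
    so the twin starts exactly at the variational mean forward.
    """
    vdp = VDPClassifier(spec, stochastic=True)
    twin = VDPClassifier(spec, stochastic=False)
    for pv, pt in zip(
        [l for l in vdp.layers()], [l for l in twin.layers()]
    ):
        pt.w_mean.data = pv.w_mean.data.copy()
        pt.b_mean.data = pv.b_mean.data.copy()
    return vdp, twin


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------


def _batch_loss(model: VDPClassifier, images, onehot, config: LossConfig):
    if model.stochastic:
        probs, var = model.forward(images, with_variance=True)
        ell = ell_diag(onehot, probs, var, config.N, config.jitter)
        kl = None
        for layer in model.layers():
            for m, lv in (
                [(layer.w_mean, layer.w_logvar), (layer.b_mean, layer.b_logvar)]
            ):
                term = kl_diag(m, lv, config.prior_mean, config.prior_variance)
                kl = term if kl is None else kl + term
        objective = (ell * -1.0) + config.kl_weight * kl
    else:
        probs, _ = model.forward(images, with_variance=False)
        ce = -ad.tsum(onehot * ad.log(probs + 1e-12))
        objective = ce * (config.N / onehot.shape[0])
    return objective * (1.0 / config.N), probs


def train(
    model: VDPClassifier,
    dataset,
    epochs: int,
    lr: float,
    batch_size: int,
    config: Optional[LossConfig] = None,
    seed: int = 0,
    clip_norm: Optional[float] = 5.0,
) -> TrainLog:
    """SGD on the negative ELBO (variational) or cross-entropy (twin).

    ``dataset`` is a :class:`vdpnet.data.Splits`; the model is updated in
    place and a per-epoch log of training loss and validation accuracy is
    returned.  A non-finite loss aborts with a diagnostic.
    """
    x_train, y_train = dataset.split("train")
    x_val, y_val = dataset.split("val")
    n = len(y_train)
    k = model.spec.num_classes
    if config is None:
        config = LossConfig(N=n, H=k, jitter=1e-3)
    eye = np.eye(k, dtype=np.float32)
    rng = np.random.default_rng(seed)
    log = TrainLog()
    params = model.params()
    for epoch in range(epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            sel = perm[start : start + batch_size]
            loss, _ = _batch_loss(model, x_train[sel], eye[y_train[sel]], config)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (loss={value}); "
                    "reduce the learning rate or raise the variance jitter"
                )
            losses.append(value)
            if lr != 0.0:
                model.zero_grad()
                loss.backward()
                scale = 1.0
                if clip_norm is not None:
                    gnorm = math.sqrt(
                        sum(float((p.grad**2).sum()) for p in params if p.grad is not None)
                    )
                    if gnorm > clip_norm:
                        scale = clip_norm / gnorm
                for p in params:
                    if p.grad is not None:
                        p.data = p.data - (lr * scale) * p.grad.astype(p.data.dtype)
        val_acc = accuracy(model, x_val, y_val)
        log.rows.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_accuracy": val_acc}
        )
    return log


def accuracy(model: VDPClassifier, images, labels, batch_size: int = 256) -> float:
    correct = 0
    for start in range(0, len(labels), batch_size):
        probs, _ = model.forward(images[start : start + batch_size], with_variance=False)
        correct += int((probs.data.argmax(axis=1) == labels[start : start + batch_size]).sum())
    return correct / len(labels)


# ----------------------------------------------------------------------
# prediction records and calibration summaries
# ----------------------------------------------------------------------


def _scalar_variance(var_row: np.ndarray, decision: int, kind: str) -> float:
    if kind == "decision":
        value = var_row[decision]
    elif kind == "trace":
        value = var_row.sum()
    else:
        value = var_row.max()
    return float(max(value, 0.0))


def predict_batch(
    model: VDPClassifier,
    images: np.ndarray,
    labels: Optional[np.ndarray] = None,
    noise_bin: Optional[str] = None,
    batch_size: int = 128,
) -> List[PredictionRecord]:
    """Per-sample decisions with the scalar predictive variance attached.

    The scalar is the predictive-covariance diagonal entry at the predicted
    class (configurable to trace or max-diagonal via the network spec).  For
    a deterministic twin the variance is reported as zero.
    """
    if np.asarray(images).shape[1:] != tuple(model.spec.input_shape):
        raise ValueError(
            f"image shape {np.asarray(images).shape[1:]} != spec {model.spec.input_shape}"
        )
    kind = model.spec.variance_kind
    records = []
    for start in range(0, len(images), batch_size):
        chunk = images[start : start + batch_size]
        probs, var = model.forward(chunk, with_variance=True)
        pd_ = probs.data
        vd = var.data if var is not None else np.zeros_like(pd_)
        for i in range(len(chunk)):
            decision = int(pd_[i].argmax())
            correctness = None
            if labels is not None:
                correctness = bool(decision == int(labels[start + i]))
            records.append(
                PredictionRecord(
                    decision=decision,
                    mean_vector=pd_[i].astype(float),
                    predictive_variance=_scalar_variance(vd[i], decision, kind),
                    correctness=correctness,
                    noise_bin=noise_bin,
                )
            )
    return records


def save_checkpoint(model: VDPClassifier, path, log: Optional[TrainLog] = None) -> None:
    """Persist a model (means, log-variances, spec, training log) as one npz."""
    import json
    from dataclasses import asdict

    arrays = {
        "spec_json": np.frombuffer(
            json.dumps(asdict(model.spec)).encode(), dtype=np.uint8
        ),
        "stochastic": np.array(model.stochastic),
    }
    for i, layer in enumerate(model.layers()):
        arrays[f"w_mean_{i}"] = layer.w_mean.data
        arrays[f"b_mean_{i}"] = layer.b_mean.data
        if model.stochastic:
            arrays[f"w_logvar_{i}"] = layer.w_logvar.data
            arrays[f"b_logvar_{i}"] = layer.b_logvar.data
    if log is not None:
        arrays["log_json"] = np.frombuffer(
            json.dumps(log.rows).encode(), dtype=np.uint8
        )
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Load a checkpoint written by :func:`save_checkpoint`.

    Returns ``(model, log-or-None)``.
    """
    import json

    with np.load(path) as npz:
        if "spec_json" not in npz.files:
            raise KeyError(f"{path} is not a model checkpoint (no spec)")
        raw = dict(npz)
    spec_d = json.loads(bytes(raw["spec_json"]).decode())
    spec_d["input_shape"] = tuple(spec_d["input_shape"])
    spec_d["stage_channels"] = tuple(spec_d["stage_channels"])
    spec = NetworkSpec(**spec_d)
    model = VDPClassifier(spec, stochastic=bool(raw["stochastic"]))
    for i, layer in enumerate(model.layers()):
        layer.w_mean.data = raw[f"w_mean_{i}"]
        layer.b_mean.data = raw[f"b_mean_{i}"]
        if model.stochastic:
            layer.w_logvar.data = raw[f"w_logvar_{i}"]
            layer.b_logvar.data = raw[f"b_logvar_{i}"]
    log = None
    if "log_json" in raw:
        log = TrainLog(rows=json.loads(bytes(raw["log_json"]).decode()))
    return model, log


def records_to_frame(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": np.arange(len(records)),
            "decision": [r.decision for r in records],
            "correct": [r.correctness for r in records],
            "pred_var": [r.predictive_variance for r in records],
            "bin": [r.noise_bin for r in records],
            "max_prob": [float(r.mean_vector.max()) for r in records],
        }
    )


def accuracy_probability_gap(records_by_bin: dict) -> pd.DataFrame:
    """Mean max-probability vs accuracy per noise bin, both in percent.

    A positive gap means the softmax scores overstate the model's accuracy;
    for a calibrated model the gap is zero.
    """
    rows = []
    for name, records in records_by_bin.items():
        if not records:
            raise ValueError(f"noise bin {name!r} has no records")
        if any(r.correctness is None for r in records):
            raise ValueError("accuracy-probability gap needs correctness flags")
        mean_prob = 100.0 * float(np.mean([r.mean_vector.max() for r in records]))
        acc = 100.0 * float(np.mean([r.correctness for r in records]))
        rows.append(
            {
                "bin": name,
                "mean_max_probability_pct": mean_prob,
                "accuracy_pct": acc,
                "gap_pct": mean_prob - acc,
            }
        )
    return pd.DataFrame(rows)
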