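"""End-to-end experiment orchestration.

One :class:`ExperimentConfig` describes a complete run: dataset (synthetic
spec or an npz archive), network, training settings, the Gaussian-noise
bins, the adversarial-attack settings, and the threshold mechanisms.  A
global seed fans out to named per-stage streams so stages are individually
reproducible.

The outputs mirror the standard reporting of variance-based failure
detection studies, as plain DataFrames (CSV on disk via the CLI):

* ``curves`` — per noise bin: classifier accuracy, variance medians
  (correct / incorrect / combined), and the deterministic twin's mean
  max-probability and accuracy-probability gap;
* ``attacks`` — per attack: both models' accuracies and the variance
  medians under attack;
* ``thresholds`` — per bin and per attack: pre-threshold accuracy,
  abstained fraction and post-threshold accuracy for the fixed and the
  learned threshold.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .data import Splits, SyntheticSpec, generate_dataset, read_fixture
from .detect import (
    ThresholdRegressorSpec,
    apply_learned_threshold,
    apply_threshold,
    select_fixed_threshold,
    summarize_variance,
    train_threshold_regressor,
)
from .losses import LossConfig
from .network import (
    NetworkSpec,
    TrainLog,
    VDPClassifier,
    accuracy_probability_gap,
    build_network,
    predict_batch,
    train,
)
from .perturb import add_gaussian_noise_at_snr, fgsm, pgd

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "apply_noise_bin"]

DEFAULT_BINS = (("none", None), ("low", -2.0), ("medium", -6.0), ("high", -10.0))


@dataclass
class AttackConfig:
    epsilon: float = 0.1
    alpha: float = 0.01
    steps: int = 20
    n_samples: int = 200


@dataclass
class ExperimentConfig:
    dataset: SyntheticSpec = field(default_factory=SyntheticSpec)
    dataset_path: Optional[str] = None  # overrides `dataset` when given
    network: NetworkSpec = field(default_factory=NetworkSpec)
    epochs: int = 6
    lr: float = 0.05
    batch_size: int = 64
    jitter: float = 1e-3
    clip_norm: float = 5.0
    noise_bins: Tuple = DEFAULT_BINS
    attack: AttackConfig = field(default_factory=AttackConfig)
    regressor: ThresholdRegressorSpec = field(default_factory=ThresholdRegressorSpec)
    regressor_max_images: int = 300
    seed: int = 0

    def __post_init__(self):
        self.noise_bins = tuple((str(l), None if s is None else float(s)) for l, s in self.noise_bins)

    # -- seed fan-out ---------------------------------------------------
    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed (FNV mix)."""
        h = 2166136261
        for ch in stage:
            h = ((h ^ ord(ch)) * 16777619) % 2**64
        return (self.seed * 2654435761 + h) % (2**31 - 1)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["noise_bins"] = [list(b) for b in self.noise_bins]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "dataset" in d and isinstance(d["dataset"], dict):
            d["dataset"] = SyntheticSpec(**d["dataset"])
        if "network" in d and isinstance(d["network"], dict):
            net = dict(d["network"])
            for key in ("input_shape", "stage_channels"):
                if key in net:
                    net[key] = tuple(net[key])
            d["network"] = NetworkSpec(**net)
        if "attack" in d and isinstance(d["attack"], dict):
            d["attack"] = AttackConfig(**d["attack"])
        if "regressor" in d and isinstance(d["regressor"], dict):
            reg = dict(d["regressor"])
            if "noise_snrs_db" in reg:
                reg["noise_snrs_db"] = tuple(reg["noise_snrs_db"])
            d["regressor"] = ThresholdRegressorSpec(**reg)
        if "noise_bins" in d:
            d["noise_bins"] = tuple(tuple(b) for b in d["noise_bins"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    vdp: VDPClassifier
    twin: VDPClassifier
    vdp_log: TrainLog
    twin_log: TrainLog
    bin_images: Dict[str, np.ndarray]
    vdp_records: Dict[str, list]
    twin_records: Dict[str, list]
    curves: pd.DataFrame
    attacks: pd.DataFrame
    thresholds: pd.DataFrame
    fixed_threshold: float


def load_dataset(config: ExperimentConfig) -> Splits:
    if config.dataset_path:
        return read_fixture(config.dataset_path)
    return generate_dataset(config.dataset)


def apply_noise_bin(
    images: np.ndarray, snr_db: Optional[float], base_seed: int
) -> np.ndarray:
    """Corrupt every image at the target SNR with per-image seed offsets."""
    if snr_db is None:
        return np.asarray(images, dtype=np.float32)
    out = np.stack(
        [
            add_gaussian_noise_at_snr(img, snr_db, seed=(base_seed + i) % 2**31)[0]
            for i, img in enumerate(images)
        ]
    )
    return out.astype(np.float32)


def evaluate_bins(config, vdp, twin, images, labels):
    bin_images, vdp_records, twin_records = {}, {}, {}
    for bi, (label, snr) in enumerate(config.noise_bins):
        xs = apply_noise_bin(images, snr, config.stage_seed(f"noise-{label}"))
        bin_images[label] = xs
        vdp_records[label] = predict_batch(vdp, xs, labels, noise_bin=label)
        twin_records[label] = predict_batch(twin, xs, labels, noise_bin=label)
    return bin_images, vdp_records, twin_records


def _medians_row(records):
    pv = np.array([r.predictive_variance for r in records])
    corr = np.array([bool(r.correctness) for r in records])
    return {
        "median_var_combined": float(np.median(pv)),
        "median_var_correct": float(np.median(pv[corr])) if corr.any() else np.nan,
        "median_var_incorrect": float(np.median(pv[~corr])) if (~corr).any() else np.nan,
    }


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Train both models and produce every report table."""
    dataset = load_dataset(config)
    net_spec = config.network
    vdp, twin = build_network(net_spec)
    n_train = len(dataset.train_labels)
    loss_cfg = LossConfig(N=n_train, H=net_spec.num_classes, jitter=config.jitter)
    train_seed = config.stage_seed("train")
    vdp_log = train(
        vdp, dataset, config.epochs, config.lr, config.batch_size,
        config=loss_cfg, seed=train_seed, clip_norm=config.clip_norm,
    )
    twin_log = train(
        twin, dataset, config.epochs, config.lr, config.batch_size,
        config=loss_cfg, seed=train_seed, clip_norm=config.clip_norm,
    )

    x_test, y_test = dataset.split("test")
    bin_images, vdp_records, twin_records = evaluate_bins(
        config, vdp, twin, x_test, y_test
    )

    # -- curves (variance medians + calibration gap per bin) ------------
    summaries = summarize_variance(vdp_records)
    gap = accuracy_probability_gap(twin_records).set_index("bin")
    rows = []
    for (label, snr), summary in zip(config.noise_bins, summaries):
        row = {
            "bin": label,
            "target_snr_db": snr,
            "vdp_accuracy_pct": summary.accuracy_pct,
            "median_var_correct": summary.median_correct,
            "median_var_incorrect": summary.median_incorrect,
            "median_var_combined": summary.median_combined,
            "twin_accuracy_pct": gap.loc[label, "accuracy_pct"],
            "twin_mean_max_probability_pct": gap.loc[label, "mean_max_probability_pct"],
            "twin_gap_pct": gap.loc[label, "gap_pct"],
            "n": summary.count,
        }
        rows.append(row)
    curves = pd.DataFrame(rows)

    # -- adversarial attacks --------------------------------------------
    atk = config.attack
    n_atk = min(atk.n_samples, len(y_test))
    sel = np.random.default_rng(config.stage_seed("attack-select")).choice(
        len(y_test), n_atk, replace=False
    )
    xa, ya = x_test[sel], y_test[sel]
    attack_rows = []
    attack_sets = {
        "fgsm": fgsm(vdp, xa, ya, atk.epsilon),
        "pgd": pgd(
            vdp, xa, ya, atk.epsilon, atk.alpha, atk.steps,
            seed=config.stage_seed("pgd-start"),
        ),
    }
    attack_records = {}
    for name, adv in attack_sets.items():
        rv = predict_batch(vdp, adv.astype(np.float32), ya, noise_bin=name)
        rt = predict_batch(twin, adv.astype(np.float32), ya, noise_bin=name)
        attack_records[name] = (adv, rv)
        row = {
            "attack": name,
            "epsilon": atk.epsilon,
            "vdp_accuracy_pct": 100.0 * float(np.mean([r.correctness for r in rv])),
            "twin_accuracy_pct": 100.0 * float(np.mean([r.correctness for r in rt])),
        }
        row.update(_medians_row(rv))
        attack_rows.append(row)
    attacks = pd.DataFrame(attack_rows)

    # -- thresholds ------------------------------------------------------
    tau = select_fixed_threshold(summaries, "correct-at-min-noise")
    tau_combined = select_fixed_threshold(summaries, "combined-at-min-noise")
    x_train = dataset.train_images
    regressor, _ = train_threshold_regressor(
        vdp, x_train, config.regressor, max_images=config.regressor_max_images
    )
    threshold_rows = []
    eval_sets = [(label, bin_images[label], vdp_records[label]) for label, _ in config.noise_bins]
    eval_sets += [(name, adv, rv) for name, (adv, rv) in attack_records.items()]
    for label, xs, recs in eval_sets:
        for desc, report in (
            ("fixed-correct", apply_threshold(recs, tau)),
            ("fixed-combined", apply_threshold(recs, tau_combined)),
            ("learned", apply_learned_threshold(recs, xs, regressor)),
        ):
            threshold_rows.append(
                {
                    "bin": label,
                    "threshold_type": desc,
                    "threshold_value": tau
                    if desc == "fixed-correct"
                    else (tau_combined if desc == "fixed-combined" else np.nan),
                    "pre_accuracy_pct": report.pre_accuracy_pct,
                    "abstained_pct": report.abstained_pct,
                    "post_accuracy_pct": report.post_accuracy_pct,
                }
            )
    thresholds = pd.DataFrame(threshold_rows)

    return ExperimentResult(
        config=config,
        vdp=vdp,
        twin=twin,
        vdp_log=vdp_log,
        twin_log=twin_log,
        bin_images=bin_images,
        vdp_records=vdp_records,
        twin_records=twin_records,
        curves=curves,
        attacks=attacks,
        thresholds=thresholds,
        fixed_threshold=tau,
    )
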