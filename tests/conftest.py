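"""Shared fixtures.

The trained-model fixtures are deliberately session-scoped: training the
variational classifier dominates the suite's runtime, so the multi-seed
trend tests and the acceptance tests all read from one set of runs.
"""

import gc
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from vdpnet.data import SyntheticSpec, generate_dataset
from vdpnet.experiment import ExperimentConfig, run_experiment
from vdpnet.losses import LossConfig
from vdpnet.network import NetworkSpec, build_network, train

N_SEEDS = 5


@dataclass
class SlimResult:
    """Report tables of one experiment run (models dropped to bound memory)."""

    curves: pd.DataFrame
    attacks: pd.DataFrame
    thresholds: pd.DataFrame
    val_accuracy: float


def compact_config(seed: int) -> ExperimentConfig:
    """Desk-scale experiment: 4-class synthetic data, small residual CNN."""
    return ExperimentConfig(
        dataset=SyntheticSpec(n_train=1200, n_val=300, n_test=600, seed=seed),
        network=NetworkSpec(seed=seed),
        epochs=5,
        seed=seed,
    )


@pytest.fixture(scope="session")
def multi_seed_results():
    """Full pipeline (train, noise bins, attacks, thresholds) over 5 seeds."""
    results = []
    for seed in range(N_SEEDS):
        full = run_experiment(compact_config(seed))
        results.append(
            SlimResult(
                curves=full.curves,
                attacks=full.attacks,
                thresholds=full.thresholds,
                val_accuracy=full.vdp_log.rows[-1]["val_accuracy"],
            )
        )
        del full
        gc.collect()
    return results


@pytest.fixture(scope="session")
def smoke_run():
    """One full-size training run: n=2000, 10 epochs, default generator."""
    dataset = generate_dataset(SyntheticSpec(seed=0))
    vdp, twin = build_network(NetworkSpec(seed=0))
    cfg = LossConfig(N=2000, H=4, jitter=1e-3)
    vdp_log = train(vdp, dataset, epochs=10, lr=0.05, batch_size=64, config=cfg, seed=0)
    twin_log = train(twin, dataset, epochs=10, lr=0.05, batch_size=64, config=cfg, seed=0)
    return dataset, vdp, twin, vdp_log, twin_log


@pytest.fixture(scope="session")
def reference_chain():
    """A 2-conv(+pool)+fc+softmax chain on an 8x8 input for oracle checks.

    Parameter variances are small enough that the first-order treatment of
    the ReLU and softmax is near-exact, and pre-activation means sit well
    away from the ReLU kink.
    """
    import vdpnet as v
    from vdpnet.moments import RELU

    rng = np.random.default_rng(42)
    x = rng.random((1, 8, 8)) * 0.8 + 0.2
    var = 2e-5
    k1 = v.RandomParameter(rng.random((3, 1, 3, 3)) * 0.4 + 0.1, np.full((3, 1, 3, 3), var))
    k2 = v.RandomParameter(rng.random((4, 3, 3, 3)) * 0.15 + 0.03, np.full((4, 3, 3, 3), var))
    w = v.RandomParameter(
        rng.standard_normal((3, 36)) * 0.3, np.full((3, 36), var), role="fc-weight"
    )
    layers = [
        {"type": "conv", "kernel": k1},
        {"type": "activation", "f": RELU},
        {"type": "maxpool", "window": 2},
        {"type": "conv", "kernel": k2, "padding": 1},
        {"type": "activation", "f": RELU},
        {"type": "flatten"},
        {"type": "fc", "weights": w},
        {"type": "softmax"},
    ]
    return layers, x


@pytest.fixture()
def tiny_model():
    """Small untrained classifier for structural (non-statistical) checks."""
    spec = NetworkSpec(input_shape=(1, 14, 14), num_classes=3, stem_channels=4,
                       stage_channels=(4,), seed=7)
    vdp, twin = build_network(spec)
    return vdp, twin


@pytest.fixture()
def tiny_dataset():
    return generate_dataset(
        SyntheticSpec(n_train=96, n_val=24, n_test=24, num_classes=3, side=14, seed=5)
    )
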