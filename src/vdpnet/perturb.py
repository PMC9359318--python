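"""Test-time corruptions: calibrated Gaussian noise, speckle, FGSM and PGD.

Noise strength is stated as a signal-to-noise ratio in decibels,
``SNR = 10 log10(sum(clean^2) / sum(noise^2))`` — the energy-ratio reading,
so each 20 dB corresponds to a tenfold amplitude ratio.  Noise is scaled
per image to hit the target SNR exactly before clipping to [0, 1]; the
achieved (pre-clip) value is returned alongside the corrupted image.

The adversarial attacks perturb inputs along the sign of the input gradient
of the cross-entropy on the model's predictive mean: FGSM in one step, PGD
iteratively with projection onto the epsilon-ball and an optional random
start.  PGD with one step, alpha = epsilon and no random start reduces to
FGSM exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "NoiseBin",
    "compute_snr",
    "add_gaussian_noise_at_snr",
    "add_speckle_noise",
    "fgsm",
    "pgd",
]


@dataclass
class NoiseBin:
    """One evaluation condition: a noise level or an attack setting."""

    label: str
    noise_kind: str = "gaussian"  # gaussian | speckle | fgsm | pgd
    target_snr_db: Optional[float] = None
    epsilon: Optional[float] = None
    alpha: Optional[float] = None
    steps: int = 1
    intensity: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if self.noise_kind == "gaussian" and self.label != "none" and self.target_snr_db is None:
            raise ValueError("gaussian bins need a target SNR")
        if self.noise_kind in ("fgsm", "pgd") and self.epsilon is None:
            raise ValueError("attack bins need an epsilon")


def compute_snr(clean: np.ndarray, noise: np.ndarray) -> float:
    """Energy-ratio SNR in dB between a clean image and its noise."""
    clean = np.asarray(clean, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if clean.shape != noise.shape:
        raise ValueError("clean and noise shapes differ")
    noise_energy = float(np.sum(noise * noise))
    if noise_energy == 0.0:
        raise ZeroDivisionError("noise has zero energy; SNR is infinite")
    return 10.0 * np.log10(float(np.sum(clean * clean)) / noise_energy)


def add_gaussian_noise_at_snr(image: np.ndarray, target_snr_db: float, seed: int):
    """Add i.i.d. Gaussian noise scaled so the pre-clip SNR hits the target.

    Returns ``(noisy, achieved_snr_db)``; the output is clipped to [0, 1]
    but the achieved SNR is reported before clipping.
    """
    if not np.isfinite(target_snr_db):
        raise ValueError("target SNR must be finite")
    image = np.asarray(image, dtype=float)
    signal_energy = float(np.sum(image * image))
    if signal_energy == 0.0:
        raise ValueError("cannot target an SNR on an all-zero image")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(image.shape)
    noise_energy = float(np.sum(noise * noise))
    scale = np.sqrt(signal_energy / (noise_energy * 10.0 ** (target_snr_db / 10.0)))
    noise *= scale
    achieved = compute_snr(image, noise)
    return np.clip(image + noise, 0.0, 1.0), achieved


def add_speckle_noise(image: np.ndarray, intensity: float, seed: int) -> np.ndarray:
    """Multiplicative speckle ``x * (1 + intensity * n)``, clipped to [0, 1]."""
    if intensity < 0:
        raise ValueError("speckle intensity must be non-negative")
    image = np.asarray(image, dtype=float)
    rng = np.random.default_rng(seed)
    noisy = image * (1.0 + intensity * rng.standard_normal(image.shape))
    return np.clip(noisy, 0.0, 1.0)


def _signed_step(model, images, labels):
    grad = model.input_gradient(images, labels)
    if not np.any(grad):
        import warnings

        warnings.warn("zero input gradient; adversarial step is a no-op", RuntimeWarning)
    return np.sign(grad).astype(float)  # float64: keeps epsilon*sign exact


def fgsm(model, images: np.ndarray, labels: np.ndarray, epsilon: float) -> np.ndarray:
    """One gradient-sign step of size epsilon, clipped to [0, 1]."""
    images = np.asarray(images, dtype=float)
    if epsilon == 0:
        return images.copy()
    adv = images + epsilon * _signed_step(model, images, labels)
    return np.clip(adv, 0.0, 1.0)


def pgd(
    model,
    images: np.ndarray,
    labels: np.ndarray,
    epsilon: float,
    alpha: float,
    steps: int,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Iterated projected gradient-sign ascent within the epsilon-ball.

    ``seed=None`` starts at the clean image; an integer seed draws a uniform
    random start inside the ball.  After each step the iterate is projected
    back onto the ball and clipped to [0, 1].
    """
    images = np.asarray(images, dtype=float)
    x = images.copy()
    if seed is not None:
        rng = np.random.default_rng(seed)
        x = np.clip(x + rng.uniform(-epsilon, epsilon, size=x.shape), 0.0, 1.0)
    for _ in range(steps):
        x = x + alpha * _signed_step(model, x, labels)
        x = np.clip(x, images - epsilon, images + epsilon)
        x = np.clip(x, 0.0, 1.0)
    return x
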