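"""Synthetic multi-class image datasets for exercising the pipeline.

The generator emulates the structure of small biomedical image-classification
benchmarks: K balanced classes (4-11) of 28x28 single- or three-channel
images with values in [0, 1], distributed as npz archives whose arrays are
named ``{train,val,test}_images`` / ``{train,val,test}_labels`` (the common
MedMNIST serialization, so externally produced archives load through the
same reader).

Each class is a parametric prototype — a positioned geometric shape drawn
over a class-specific intensity gradient — perturbed per sample by a small
position/scale jitter and i.i.d. Gaussian texture noise of standard
deviation ``1 / separability``.  Shape-plus-gradient prototypes (rather
than pure Gaussian blobs) make additive pixel noise degrade classifier
accuracy gradually, which is the regime the failure-detection analysis
assumes.  Images are quantized to the 8-bit grid at generation time so the
npz round trip is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = ["SyntheticSpec", "Splits", "generate_dataset", "write_fixture", "read_fixture"]

_SPLIT_KEYS = (
    "train_images",
    "train_labels",
    "val_images",
    "val_labels",
    "test_images",
    "test_labels",
)


@dataclass
class SyntheticSpec:
    n_train: int = 2000
    n_val: int = 500
    n_test: int = 1000
    num_classes: int = 4
    channels: int = 1
    side: int = 28
    separability: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")
        if self.separability <= 0:
            raise ValueError("separability must be positive")


@dataclass
class Splits:
    """Train/val/test arrays: images ``(N, C, H, W)`` float32 in [0, 1]."""

    train_images: np.ndarray
    train_labels: np.ndarray
    val_images: np.ndarray
    val_labels: np.ndarray
    test_images: np.ndarray
    test_labels: np.ndarray

    def split(self, name: str) -> Tuple[np.ndarray, np.ndarray]:
        return getattr(self, f"{name}_images"), getattr(self, f"{name}_labels")


# ----------------------------------------------------------------------
# class prototypes
# ----------------------------------------------------------------------


def _shape_mask(kind: int, side: int, cx: float, cy: float, scale: float) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    dx, dy = xx - cx, yy - cy
    r = 0.20 * side * scale
    kind = kind % 8
    if kind == 0:  # disk
        return dx * dx + dy * dy <= r * r
    if kind == 1:  # square
        return (np.abs(dx) <= r) & (np.abs(dy) <= r)
    if kind == 2:  # cross
        return ((np.abs(dx) <= r / 2.6) | (np.abs(dy) <= r / 2.6)) & (
            (np.abs(dx) <= r) & (np.abs(dy) <= r)
        )
    if kind == 3:  # ring
        rad2 = dx * dx + dy * dy
        return (rad2 <= r * r) & (rad2 >= (0.55 * r) ** 2)
    if kind == 4:  # triangle (lower half of the box)
        return (np.abs(dx) <= r) & (dy >= -r / 3) & (dy <= r) & (np.abs(dx) <= (dy + r) / 1.6)
    if kind == 5:  # X
        return ((np.abs(dx - dy) <= r / 2.6) | (np.abs(dx + dy) <= r / 2.6)) & (
            (np.abs(dx) <= r) & (np.abs(dy) <= r)
        )
    if kind == 6:  # frame
        inside = (np.abs(dx) <= r) & (np.abs(dy) <= r)
        hole = (np.abs(dx) <= 0.55 * r) & (np.abs(dy) <= 0.55 * r)
        return inside & ~hole
    # stripes clipped to the box
    box = (np.abs(dx) <= r) & (np.abs(dy) <= r)
    return box & (np.mod(np.floor(yy / 2.0), 2) == 0)


def _class_params(k: int, num_classes: int, side: int, channels: int):
    """Deterministic per-class prototype parameters."""
    rng = np.random.default_rng(977 + k)
    angle = 2.0 * np.pi * k / num_classes
    cx = side / 2.0 + 0.16 * side * np.cos(angle)
    cy = side / 2.0 + 0.16 * side * np.sin(angle)
    grad_theta = np.pi * k / num_classes + rng.uniform(0, 0.3)
    chan_w = 0.55 + 0.45 * rng.random(channels)
    return dict(kind=k, cx=cx, cy=cy, grad_theta=grad_theta, chan_w=chan_w)


def render_prototype(k: int, spec: SyntheticSpec, jitter_rng=None) -> np.ndarray:
    """One class image, optionally with per-sample position/scale jitter."""
    p = _class_params(k, spec.num_classes, spec.side, spec.channels)
    side = spec.side
    if jitter_rng is None:
        dx = dy = 0.0
        scale = 1.0
    else:
        dx, dy = jitter_rng.integers(-2, 3, size=2)
        scale = jitter_rng.uniform(0.85, 1.15)
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    proj = (np.cos(p["grad_theta"]) * xx + np.sin(p["grad_theta"]) * yy) / side
    gradient = 0.15 + 0.35 * (proj - proj.min()) / max(np.ptp(proj), 1e-12)
    mask = _shape_mask(p["kind"], side, p["cx"] + dx, p["cy"] + dy, scale)
    img = np.empty((spec.channels, side, side))
    for c in range(spec.channels):
        img[c] = gradient * p["chan_w"][c]
        img[c, mask] = 0.55 + 0.35 * p["chan_w"][c]
    return img


def _make_split(spec: SyntheticSpec, n: int, rng: np.random.Generator):
    labels = np.arange(n) % spec.num_classes
    rng.shuffle(labels)
    sigma = 1.0 / spec.separability
    images = np.empty((n, spec.channels, spec.side, spec.side), dtype=np.float32)
    for i in range(n):
        img = render_prototype(int(labels[i]), spec, jitter_rng=rng)
        img = img + sigma * rng.standard_normal(img.shape)
        np.clip(img, 0.0, 1.0, out=img)
        images[i] = np.round(img * 255.0) / 255.0
    return images, labels.astype(np.int64)


def generate_dataset(spec: SyntheticSpec) -> Splits:
    """Generate disjoint train/val/test splits, reproducible from the seed."""
    streams = np.random.SeedSequence(spec.seed).spawn(3)
    parts = {}
    for name, n, ss in zip(
        ("train", "val", "test"), (spec.n_train, spec.n_val, spec.n_test), streams
    ):
        rng = np.random.default_rng(ss)
        parts[f"{name}_images"], parts[f"{name}_labels"] = _make_split(spec, n, rng)
    return Splits(**parts)


# ----------------------------------------------------------------------
# npz fixtures (MedMNIST dialect)
# ----------------------------------------------------------------------


def write_fixture(dataset: Splits, path) -> None:
    """Serialize to npz: uint8 channels-last images, ``(N, 1)`` labels."""
    arrays = {}
    for name in ("train", "val", "test"):
        images, labels = dataset.split(name)
        u8 = np.round(np.asarray(images) * 255.0).astype(np.uint8)
        u8 = np.moveaxis(u8, 1, -1)  # NCHW -> NHWC
        if u8.shape[-1] == 1:
            u8 = u8[..., 0]
        arrays[f"{name}_images"] = u8
        arrays[f"{name}_labels"] = np.asarray(labels).reshape(-1, 1).astype(np.uint8)
    np.savez(path, **arrays)


def read_fixture(path) -> Splits:
    """Load an npz archive in the MedMNIST dialect (synthetic or real)."""
    with np.load(path) as npz:
        missing = [k for k in _SPLIT_KEYS if k not in npz.files]
        if missing:
            raise KeyError(f"archive is missing required array(s): {', '.join(missing)}")
        parts = {}
        for name in ("train", "val", "test"):
            u8 = npz[f"{name}_images"]
            if u8.ndim == 3:
                u8 = u8[..., None]
            images = (u8.astype(np.float32) / 255.0).transpose(0, 3, 1, 2)
            parts[f"{name}_images"] = images
            parts[f"{name}_labels"] = npz[f"{name}_labels"].reshape(-1).astype(np.int64)
    return Splits(**parts)
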