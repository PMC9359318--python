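"""Containers for Gaussian layer quantities.

A variational network carries two kinds of Gaussian objects: the
*parameters* (a mean tensor plus an elementwise variance of the factorized
variational posterior over weights) and the *activations* (the first two
moments of the signal flowing between layers).  The activation covariance is
either a full symmetric matrix over the flattened activation — the reference
representation in which the layer algebra is exact — or just its diagonal,
the scalable approximation used at training size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

DIAG_CLAMP = -1e-10  # diagonal entries more negative than this are an error
SYM_RTOL = 1e-8


class CovarianceMode(str, Enum):
    FULL = "full"
    DIAGONAL = "diagonal"


@dataclass
class RandomParameter:
    """Gaussian variational posterior over one layer parameter.

    ``mean`` and ``variance`` have identical shapes; ``variance`` is the
    elementwise (diagonal) covariance and must be non-negative.
    """

    mean: np.ndarray
    variance: np.ndarray
    role: str = "conv-kernel"  # conv-kernel | fc-weight | bias

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if self.mean.shape != self.variance.shape:
            raise ValueError(
                f"mean shape {self.mean.shape} != variance shape {self.variance.shape}"
            )
        if np.any(self.variance < 0):
            raise ValueError("parameter variance must be non-negative")
        if self.role not in ("conv-kernel", "fc-weight", "bias"):
            raise ValueError(f"unknown parameter role {self.role!r}")

    @property
    def size(self) -> int:
        return self.mean.size


@dataclass
class GaussianActivation:
    """Mean and covariance of an activation, with its spatial layout.

    ``layout`` records the logical shape of ``mean`` (e.g. ``(C, H, W)``);
    flattening is channel-major then row-major (C-order ravel of ``layout``),
    and ``cov`` is indexed in that flattened order.
    """

    mean: np.ndarray
    cov: np.ndarray
    mode: CovarianceMode
    layout: tuple = field(default=None)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        self.mode = CovarianceMode(self.mode)
        if self.layout is None:
            self.layout = self.mean.shape
        self.layout = tuple(self.layout)
        n = self.mean.size
        if self.mode is CovarianceMode.DIAGONAL:
            if self.cov.shape != (n,):
                raise ValueError(f"diagonal covariance must have shape ({n},)")
            self._clamp_diag_inplace(self.cov)
        else:
            if self.cov.shape != (n, n):
                raise ValueError(f"full covariance must have shape ({n}, {n})")
            scale = np.abs(self.cov).max() if n else 0.0
            if scale and np.abs(self.cov - self.cov.T).max() > SYM_RTOL * max(scale, 1.0):
                raise ValueError("full covariance is not symmetric")
            self.cov = 0.5 * (self.cov + self.cov.T)
            d = np.einsum("ii->i", self.cov)
            self._clamp_diag_inplace(d)

    @staticmethod
    def _clamp_diag_inplace(d: np.ndarray):
        if np.any(d < DIAG_CLAMP):
            raise ValueError("covariance diagonal has a significantly negative entry")
        np.maximum(d, 0.0, out=d)

    @property
    def n(self) -> int:
        return self.mean.size

    def flat_mean(self) -> np.ndarray:
        return self.mean.reshape(-1)

    def diag(self) -> np.ndarray:
        """The covariance diagonal regardless of mode."""
        if self.mode is CovarianceMode.DIAGONAL:
            return self.cov
        return np.diag(self.cov).copy()

    def full(self) -> np.ndarray:
        """The covariance as a full matrix regardless of mode."""
        if self.mode is CovarianceMode.FULL:
            return self.cov
        return np.diag(self.cov)

    @classmethod
    def deterministic(cls, mean: np.ndarray, mode=CovarianceMode.FULL):
        mean = np.asarray(mean, dtype=float)
        n = mean.size
        cov = np.zeros((n, n)) if CovarianceMode(mode) is CovarianceMode.FULL else np.zeros(n)
        return cls(mean, cov, mode)
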