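"""The variational training objective.

The loss is the negative evidence lower bound: an expected Gaussian
log-likelihood of the one-hot targets under the propagated predictive
distribution, plus the closed-form KL divergence between the factorized
Gaussian posterior over the weights and a factorized Gaussian prior.

Because the predictive moments are propagated analytically, the expectation
over the posterior requires no sampling: the single analytic evaluation
plays the role of the Monte-Carlo average (``M = 1``), and larger ``M``
would only matter if propagation were augmented with weight draws.

The diagonal-mode helpers at the bottom are written against the dispatched
operators in :mod:`vdpnet.autodiff` so the identical formulas serve both the
plain-array API and gradient-descent training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import solve_triangular

from . import autodiff as ad
from .gaussian import RandomParameter

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class LossConfig:
    """Configuration of the variational objective.

    ``N`` is the training-set size (the data sum in the likelihood is scaled
    by ``N / batch``), ``H`` the number of classes, ``M`` the number of
    Monte-Carlo draws for the expectation (the analytic path makes this
    moot), ``kl_weight`` the per-mini-batch scaling of the KL term
    (default ``1/N``), and ``jitter`` the diagonal boost used when a
    predictive covariance is numerically singular.
    """

    N: int
    H: int
    M: int = 1
    prior_mean: float = 0.0
    prior_variance: float = 1.0
    kl_weight: Optional[float] = None
    jitter: float = 1e-6

    def __post_init__(self):
        if self.N < 1 or self.H < 1 or self.M < 1:
            raise ValueError("N, H and M must all be >= 1")
        if self.prior_variance <= 0:
            raise ValueError("prior variance must be positive")
        if self.kl_weight is None:
            self.kl_weight = 1.0 / self.N
        if self.jitter <= 0:
            raise ValueError("jitter must be positive")


def _gauss_terms_full(resid: np.ndarray, cov: np.ndarray, jitter: float):
    """(log det, quadratic form) for one sample, with escalating jitter."""
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        boost = jitter * max(np.trace(cov) / cov.shape[0], 1.0)
        try:
            chol = np.linalg.cholesky(cov + boost * np.eye(cov.shape[0]))
        except np.linalg.LinAlgError:
            warnings.warn(
                "predictive covariance singular after jitter; using its diagonal",
                RuntimeWarning,
            )
            d = np.clip(np.diag(cov), jitter, None)
            return float(np.sum(np.log(d))), float(np.sum(resid * resid / d))
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    u = solve_triangular(chol, resid, lower=True)
    return logdet, float(u @ u)


def expected_log_likelihood(
    targets: np.ndarray,
    pred_mean: np.ndarray,
    pred_cov: np.ndarray,
    config: LossConfig,
) -> float:
    """Expected Gaussian log-likelihood of one-hot targets.

    ``pred_cov`` is either ``(B, H, H)`` full covariances or ``(B, H)``
    diagonals.  The data sum is scaled by ``N / B`` so a mini-batch
    estimates the full-dataset term.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    pred_mean = np.atleast_2d(np.asarray(pred_mean, dtype=float))
    pred_cov = np.asarray(pred_cov, dtype=float)
    batch, h = targets.shape
    if h != config.H:
        raise ValueError(f"targets have {h} classes, config says {config.H}")
    resid = targets - pred_mean
    total = 0.0
    if pred_cov.ndim == 2:  # diagonal
        d = pred_cov + config.jitter
        total = float(np.sum(np.log(d)) + np.sum(resid * resid / d))
    else:
        for i in range(batch):
            logdet, quad = _gauss_terms_full(resid[i], pred_cov[i], config.jitter)
            total += logdet + quad
    return float(
        -0.5 * config.N * config.H * LOG_2PI - 0.5 * (config.N / batch) * total
    )


def kl_gaussian_diag(q_mean, q_var, config: LossConfig) -> float:
    """Closed-form KL between factorized Gaussians and the prior, summed."""
    q_mean = np.asarray(q_mean, dtype=float)
    q_var = np.asarray(q_var, dtype=float)
    if np.any(q_var <= 0):
        raise ValueError("posterior variance must be strictly positive")
    pv = config.prior_variance
    pm = config.prior_mean
    terms = 0.5 * (
        q_var / pv + (q_mean - pm) ** 2 / pv - 1.0 + np.log(pv) - np.log(q_var)
    )
    return float(np.sum(terms))


def elbo_objective(
    targets: np.ndarray,
    pred_mean: np.ndarray,
    pred_cov: np.ndarray,
    params: Sequence[RandomParameter],
    config: LossConfig,
) -> float:
    """Negative ELBO: ``-E_q[log p] + kl_weight * KL(q || p)``."""
    ell = expected_log_likelihood(targets, pred_mean, pred_cov, config)
    kl = sum(kl_gaussian_diag(p.mean, p.variance, config) for p in params)
    return float(-ell + config.kl_weight * kl)


# ----------------------------------------------------------------------
# dispatched diagonal-mode formulas (ndarray or autodiff.Tensor)
# ----------------------------------------------------------------------


def ell_diag(targets, mean, var, n_total: int, jitter: float):
    """Diagonal-covariance expected log-likelihood, autodiff-compatible."""
    batch, h = np.shape(targets)
    v = var + jitter
    resid = targets - mean
    term = ad.tsum(ad.log(v)) + ad.tsum(resid * resid / v)
    return -0.5 * n_total * h * LOG_2PI - 0.5 * (n_total / batch) * term


def kl_diag(mean, logvar, prior_mean: float, prior_var: float):
    """KL to the prior with the posterior variance stored as log-variance."""
    var = ad.exp(logvar)
    d = mean - prior_mean
    terms = 0.5 * (
        var / prior_var + d * d / prior_var - 1.0 + float(np.log(prior_var)) - logvar
    )
    return ad.tsum(terms)
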