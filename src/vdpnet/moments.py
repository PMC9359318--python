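"""Analytic propagation of Gaussian moments through network layers.

Each function maps the first two moments of a Gaussian signal through one
layer transform of a convolutional classifier whose weights carry a
factorized Gaussian variational posterior:

* first convolution — input constant, weights random (exact);
* elementwise nonlinearity — first-order Taylor expansion about the mean;
* max-pool — mean pooled, covariance rows/columns gathered at the argmax
  indices of the mean ("co-pool");
* flatten — concatenation with block-diagonal covariance;
* fully-connected / inner convolution — product of two independent Gaussian
  vectors (exact second moments);
* softmax — linearization through the softmax Jacobian;
* batch normalization — affine map with a diagonal scale;
* residual block — mean passes through the skip sum, covariance through the
  Jacobian of the summed map.

All operations accept a full covariance (the exact reference representation)
or its diagonal (the scalable approximation).  Flattening order is
channel-major then row-major spatial throughout.  Convolutions use the
cross-correlation convention with zero padding and unit dilation; the output
side is ``floor((n + 2p - k)/s) + 1``.

:func:`mc_oracle` estimates the same moments by sampling weight (and input)
realizations and running the deterministic forward pass; it exists purely as
an independent check on the analytic path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.linalg import block_diag

from .gaussian import CovarianceMode, GaussianActivation, RandomParameter

__all__ = [
    "Nonlinearity",
    "RELU",
    "IDENTITY",
    "propagate_conv_first",
    "propagate_activation",
    "propagate_maxpool",
    "propagate_flatten",
    "propagate_fc",
    "propagate_conv_inner",
    "propagate_softmax",
    "propagate_batchnorm",
    "propagate_residual",
    "propagate_network",
    "deterministic_forward",
    "mc_oracle",
]


# ----------------------------------------------------------------------
# nonlinearities
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class Nonlinearity:
    name: str
    fn: Callable[[np.ndarray], np.ndarray]
    deriv: Callable[[np.ndarray], np.ndarray]


RELU = Nonlinearity("relu", lambda x: np.maximum(x, 0.0), lambda x: (x > 0).astype(float))
IDENTITY = Nonlinearity("identity", lambda x: x, lambda x: np.ones_like(x))


def stable_softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


# ----------------------------------------------------------------------
# convolution geometry
# ----------------------------------------------------------------------


def conv_out_side(n: int, k: int, stride: int, padding: int) -> int:
    side = (n + 2 * padding - k) // stride + 1
    if side <= 0:
        raise ValueError(f"kernel {k} with padding {padding} exceeds input side {n}")
    return side


def patch_index_map(layout, k: int, stride: int, padding: int):
    """Flat-index map for im2col extraction with a zero sentinel.

    Returns ``(idx, (Ho, Wo), n)`` where ``idx`` has shape
    ``(Ho*Wo, C*k*k)`` and indexes the input's C-order flattening augmented
    with a trailing zero at position ``n`` (used for padded cells).  Patch
    entries are ordered channel-major then row-major, matching a C-order
    reshape of a ``(C, k, k)`` kernel.
    """
    c, h, w = layout
    n = c * h * w
    grid = np.full((c, h + 2 * padding, w + 2 * padding), n, dtype=np.int64)
    grid[:, padding : padding + h, padding : padding + w] = np.arange(n).reshape(c, h, w)
    ho = conv_out_side(h, k, stride, padding)
    wo = conv_out_side(w, k, stride, padding)
    win = sliding_window_view(grid, (k, k), axis=(1, 2))[:, ::stride, ::stride]
    idx = win.transpose(1, 2, 0, 3, 4).reshape(ho * wo, c * k * k)
    return idx, (ho, wo), n


def _augment(v: np.ndarray) -> np.ndarray:
    return np.concatenate([v.reshape(-1), [0.0]])


def _kernel_matrices(kernel: RandomParameter, c_in: int, k: int):
    if kernel.mean.ndim != 4 or kernel.mean.shape[1:] != (c_in, k, k):
        raise ValueError(
            f"kernel shape {kernel.mean.shape} incompatible with input channels "
            f"{c_in} and window {k}"
        )
    c_out = kernel.mean.shape[0]
    m = kernel.mean.reshape(c_out, -1)
    v = kernel.variance.reshape(c_out, -1)
    return m, v, c_out


# ----------------------------------------------------------------------
# layer transforms
# ----------------------------------------------------------------------


def propagate_conv_first(
    x: np.ndarray,
    kernel: RandomParameter,
    stride: int = 1,
    padding: int = 0,
    mode: CovarianceMode = CovarianceMode.FULL,
) -> GaussianActivation:
    """Convolution of a constant input with a random kernel (exact)."""
    mode = CovarianceMode(mode)
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x[None]
    c_in, h, w = x.shape
    k = kernel.mean.shape[-1]
    m, v, c_out = _kernel_matrices(kernel, c_in, k)
    idx, (ho, wo), _ = patch_index_map((c_in, h, w), k, stride, padding)
    patches = _augment(x)[idx]  # (L, K)
    mean = (patches @ m.T).T.reshape(c_out, ho, wo)
    if mode is CovarianceMode.DIAGONAL:
        cov = ((patches * patches) @ v.T).T.reshape(-1)
    else:
        blocks = [(patches * v[c]) @ patches.T for c in range(c_out)]
        cov = block_diag(*blocks) if blocks else np.zeros((0, 0))
        cov = 0.5 * (cov + cov.T)
    return GaussianActivation(mean, cov, mode, layout=(c_out, ho, wo))


def propagate_activation(a: GaussianActivation, f: Nonlinearity) -> GaussianActivation:
    """First-order Taylor propagation through an elementwise nonlinearity."""
    mu = a.flat_mean()
    g = f.deriv(mu)
    mean = f.fn(a.mean)
    if a.mode is CovarianceMode.DIAGONAL:
        cov = a.cov * (g * g)  # bitwise-matches the diagonal of cov * outer(g, g)
    else:
        cov = a.cov * np.outer(g, g)
    return GaussianActivation(mean, cov, a.mode, layout=a.layout)


def propagate_maxpool(
    a: GaussianActivation, window: int, stride: Optional[int] = None
) -> GaussianActivation:
    """Max-pool the mean; gather covariance at the argmax indices (co-pool).

    Argmax ties are broken by the first index in row-major order.
    """
    if len(a.layout) != 3:
        raise ValueError("max-pool requires a (C, H, W) layout")
    c, h, w = a.layout
    wh, ww = (window, window) if np.isscalar(window) else tuple(window)
    if stride is None:
        sh, sw = wh, ww
    else:
        sh, sw = (stride, stride) if np.isscalar(stride) else tuple(stride)
    if wh > h or ww > w:
        raise ValueError(f"pool window ({wh}, {ww}) exceeds spatial extent ({h}, {w})")
    mean = a.mean.reshape(c, h, w)
    grid = np.arange(c * h * w).reshape(c, h, w)
    mwin = sliding_window_view(mean, (wh, ww), axis=(1, 2))[:, ::sh, ::sw]
    gwin = sliding_window_view(grid, (wh, ww), axis=(1, 2))[:, ::sh, ::sw]
    ho, wo = mwin.shape[1], mwin.shape[2]
    mflat = mwin.reshape(c, ho, wo, -1)
    gflat = gwin.reshape(c, ho, wo, -1)
    arg = mflat.argmax(axis=-1)  # first max wins
    chosen = np.take_along_axis(gflat, arg[..., None], axis=-1)[..., 0]
    sel = chosen.reshape(-1)
    out_mean = a.flat_mean()[sel].reshape(c, ho, wo)
    if a.mode is CovarianceMode.DIAGONAL:
        cov = a.cov[sel]
    else:
        cov = a.cov[np.ix_(sel, sel)]
    return GaussianActivation(out_mean, cov, a.mode, layout=(c, ho, wo))


def propagate_flatten(parts: Sequence[GaussianActivation]) -> GaussianActivation:
    """Concatenate activations; covariance becomes block-diagonal.

    Cross-part covariance blocks are zero: the parts (per-kernel feature
    maps) are treated as uncorrelated at this junction.
    """
    if not parts:
        raise ValueError("flatten requires at least one part")
    modes = {p.mode for p in parts}
    if len(modes) > 1:
        raise ValueError("cannot flatten parts with mixed covariance modes")
    mode = parts[0].mode
    mean = np.concatenate([p.flat_mean() for p in parts])
    if mode is CovarianceMode.DIAGONAL:
        cov = np.concatenate([p.cov for p in parts])
    else:
        cov = block_diag(*[p.cov for p in parts])
    return GaussianActivation(mean, cov, mode, layout=(mean.size,))


def _fc_matrices(weights) -> tuple:
    if isinstance(weights, RandomParameter):
        m = np.atleast_2d(weights.mean)
        v = np.atleast_2d(weights.variance)
    else:
        m = np.stack([w.mean.reshape(-1) for w in weights])
        v = np.stack([w.variance.reshape(-1) for w in weights])
    return m, v


def propagate_fc(
    b: GaussianActivation,
    weights: Union[RandomParameter, Sequence[RandomParameter]],
    mode: Optional[CovarianceMode] = None,
) -> GaussianActivation:
    """Product of two independent Gaussian vectors (exact second moments).

    Output unit ``i``: mean ``m_i'mu``; variance
    ``tr(S_i S_b) + m_i'S_b m_i + mu'S_i mu``; cross terms ``m_i'S_b m_j``
    in full mode (distinct units have independent weights).
    """
    mode = b.mode if mode is None else CovarianceMode(mode)
    m, v = _fc_matrices(weights)
    mu = b.flat_mean()
    if m.shape[1] != mu.size:
        raise ValueError(f"weight length {m.shape[1]} != input length {mu.size}")
    mean = m @ mu
    db = b.diag()
    extra = v @ (db + mu * mu)  # tr(S_i S_b) + mu' S_i mu, per unit
    if mode is CovarianceMode.DIAGONAL:
        sb = b.diag()
        quad = (m * m) @ sb
        cov = quad + extra
    else:
        sb = b.full()
        cov = m @ sb @ m.T
        cov[np.diag_indices_from(cov)] += extra
        cov = 0.5 * (cov + cov.T)
    return GaussianActivation(mean, cov, mode, layout=(mean.size,))


def propagate_conv_inner(
    a: GaussianActivation,
    kernel: RandomParameter,
    stride: int = 1,
    padding: int = 0,
    mode: Optional[CovarianceMode] = None,
) -> GaussianActivation:
    """Convolution where both the input and the kernel are random.

    Per output location this is the random-times-random product of
    :func:`propagate_fc` applied between the local input-patch moments and
    the kernel moments; full mode also carries the exact cross-location and
    cross-channel covariance induced by overlapping patches.
    """
    mode = a.mode if mode is None else CovarianceMode(mode)
    if len(a.layout) != 3:
        raise ValueError("inner convolution requires a (C, H, W) layout")
    c_in, h, w = a.layout
    k = kernel.mean.shape[-1]
    m, v, c_out = _kernel_matrices(kernel, c_in, k)
    idx, (ho, wo), _ = patch_index_map((c_in, h, w), k, stride, padding)
    length = ho * wo
    mu_p = _augment(a.flat_mean())[idx]  # (L, K)
    mean = (mu_p @ m.T).T.reshape(c_out, ho, wo)
    if mode is CovarianceMode.DIAGONAL:
        v_p = _augment(a.diag())[idx]
        var = (v_p @ (m * m + v).T + (mu_p * mu_p) @ v.T).T.reshape(-1)
        return GaussianActivation(mean, var, mode, layout=(c_out, ho, wo))
    sigma = np.pad(a.full(), ((0, 1), (0, 1)))
    flat_idx = idx.reshape(-1)
    cpp = sigma[np.ix_(flat_idx, flat_idx)].reshape(length, idx.shape[1], length, idx.shape[1])
    a_term = np.einsum("cj,ljmk,dk->cldm", m, cpp, m, optimize=True)
    d_term = np.einsum("ljmj->ljm", cpp)
    t1 = np.einsum("cj,mjl->clm", v, d_term, optimize=True)
    t2 = np.einsum("cj,lj,mj->clm", v, mu_p, mu_p, optimize=True)
    cov = a_term
    for c in range(c_out):
        cov[c, :, c, :] += t1[c] + t2[c]
    cov = cov.reshape(c_out * length, c_out * length)
    cov = 0.5 * (cov + cov.T)
    return GaussianActivation(mean, cov, mode, layout=(c_out, ho, wo))


def propagate_softmax(d: GaussianActivation) -> GaussianActivation:
    """Linearize the softmax: covariance maps through its Jacobian."""
    mu = d.flat_mean()
    g = stable_softmax(mu)
    jac = np.diag(g) - np.outer(g, g)
    if d.mode is CovarianceMode.DIAGONAL:
        cov = (jac * jac) @ d.cov
    else:
        cov = jac @ d.cov @ jac.T
        cov = 0.5 * (cov + cov.T)
    return GaussianActivation(g, cov, d.mode, layout=(g.size,))


def _broadcast_stat(p, layout) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    full = np.empty(layout)
    if p.ndim == 0 or p.shape == tuple(layout):
        full[...] = p
    elif len(layout) == 3 and p.shape == (layout[0],):
        full[...] = p.reshape(-1, 1, 1)
    elif len(layout) == 1 and p.shape == tuple(layout):
        full[...] = p
    else:
        raise ValueError(f"statistic shape {p.shape} incompatible with layout {layout}")
    return full.reshape(-1)


def propagate_batchnorm(
    x: GaussianActivation,
    batch_mean,
    batch_var,
    gamma,
    beta,
    eps: float = 1e-5,
) -> GaussianActivation:
    """Affine normalization: scale ``gamma / sqrt(batch_var + eps)``, shift ``beta``.

    Statistics and affine parameters may be scalars, per-channel vectors
    (for a ``(C, H, W)`` layout), or full-shape arrays.
    """
    bv = _broadcast_stat(batch_var, x.layout)
    if np.any(bv + eps <= 0):
        raise FloatingPointError("batch variance plus eps must be positive")
    bm = _broadcast_stat(batch_mean, x.layout)
    ga = _broadcast_stat(gamma, x.layout)
    be = _broadcast_stat(beta, x.layout)
    scale = ga / np.sqrt(bv + eps)
    mean = (scale * (x.flat_mean() - bm) + be).reshape(x.mean.shape)
    if x.mode is CovarianceMode.DIAGONAL:
        cov = x.cov * (scale * scale)
    else:
        cov = x.cov * np.outer(scale, scale)
    return GaussianActivation(mean, cov, x.mode, layout=x.layout)


def propagate_residual(
    x: GaussianActivation,
    block: Callable[[GaussianActivation], GaussianActivation],
    jacobian: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    fd_step: float = 1e-5,
) -> GaussianActivation:
    """Skip connection ``y = x + F(x)``.

    The mean passes through the sum; the covariance maps through the
    Jacobian ``J`` of the summed map evaluated at the mean.  ``J`` is taken
    from ``jacobian`` when supplied, otherwise estimated by central finite
    differences with step ``fd_step * max(1, |mu_i|)`` per coordinate.
    """
    mu = x.flat_mean()

    def h(flat: np.ndarray) -> np.ndarray:
        act = GaussianActivation.deterministic(flat.reshape(x.mean.shape), mode=x.mode)
        act.layout = x.layout
        return flat + block(act).flat_mean()

    mean = h(mu)
    if jacobian is not None:
        jac = np.asarray(jacobian(mu), dtype=float)
    else:
        n = mu.size
        jac = np.empty((n, n))
        for i in range(n):
            step = fd_step * max(1.0, abs(mu[i]))
            up, dn = mu.copy(), mu.copy()
            up[i] += step
            dn[i] -= step
            jac[:, i] = (h(up) - h(dn)) / (2 * step)
    if x.mode is CovarianceMode.DIAGONAL:
        cov = (jac * jac) @ x.cov
    else:
        cov = jac @ x.full() @ jac.T
        cov = 0.5 * (cov + cov.T)
    return GaussianActivation(
        mean.reshape(x.mean.shape), cov, x.mode, layout=x.layout
    )


# ----------------------------------------------------------------------
# whole-network propagation, deterministic forward, and the sampling oracle
# ----------------------------------------------------------------------


def propagate_network(
    layers: Sequence[dict], x: np.ndarray, mode: CovarianceMode = CovarianceMode.FULL
) -> GaussianActivation:
    """Run the analytic propagation through a layer-spec list.

    Layer dicts: ``{"type": "conv", "kernel": RandomParameter, "stride", "padding"}``,
    ``{"type": "activation", "f": Nonlinearity}``, ``{"type": "maxpool", "window"}``,
    ``{"type": "flatten"}``, ``{"type": "fc", "weights": RandomParameter}``,
    ``{"type": "softmax"}``, ``{"type": "batchnorm", ...}``.
    """
    mode = CovarianceMode(mode)
    act: Optional[GaussianActivation] = None
    for layer in layers:
        kind = layer["type"]
        if kind == "conv":
            kw = dict(stride=layer.get("stride", 1), padding=layer.get("padding", 0))
            if act is None:
                act = propagate_conv_first(x, layer["kernel"], mode=mode, **kw)
            else:
                act = propagate_conv_inner(act, layer["kernel"], mode=mode, **kw)
        elif kind == "activation":
            act = propagate_activation(act, layer.get("f", RELU))
        elif kind == "maxpool":
            act = propagate_maxpool(act, layer["window"], layer.get("stride"))
        elif kind == "flatten":
            act = GaussianActivation(act.flat_mean(), act.cov, act.mode, layout=(act.n,))
        elif kind == "fc":
            act = propagate_fc(act, layer["weights"], mode=mode)
        elif kind == "softmax":
            act = propagate_softmax(act)
        elif kind == "batchnorm":
            act = propagate_batchnorm(
                act,
                layer["batch_mean"],
                layer["batch_var"],
                layer["gamma"],
                layer["beta"],
                layer.get("eps", 1e-5),
            )
        else:
            raise ValueError(f"unknown layer type {kind!r}")
    return act


def deterministic_forward(
    layers: Sequence[dict], x: np.ndarray, draws: Optional[dict] = None
) -> np.ndarray:
    """Forward pass using parameter means (or supplied weight draws).

    Shares the exact arithmetic of the analytic mean path so that the
    zero-variance limit agrees bit for bit.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x[None]
    act = x
    layout = x.shape
    for pos, layer in enumerate(layers):
        kind = layer["type"]
        if kind == "conv":
            param = layer["kernel"]
            w = draws[pos] if draws is not None and pos in draws else param.mean
            c_in, h, wdt = layout
            k = w.shape[-1]
            m = w.reshape(w.shape[0], -1)
            idx, (ho, wo), _ = patch_index_map(
                (c_in, h, wdt), k, layer.get("stride", 1), layer.get("padding", 0)
            )
            patches = _augment(act)[idx]
            act = (patches @ m.T).T.reshape(w.shape[0], ho, wo)
            layout = act.shape
        elif kind == "activation":
            act = layer.get("f", RELU).fn(act)
        elif kind == "maxpool":
            ga = GaussianActivation.deterministic(act, mode=CovarianceMode.DIAGONAL)
            ga.layout = layout
            pooled = propagate_maxpool(ga, layer["window"], layer.get("stride"))
            act, layout = pooled.mean, pooled.layout
        elif kind == "flatten":
            act = act.reshape(-1)
            layout = act.shape
        elif kind == "fc":
            param = layer["weights"]
            w = draws[pos] if draws is not None and pos in draws else param.mean
            m = np.atleast_2d(w)
            act = m @ act.reshape(-1)
            layout = act.shape
        elif kind == "softmax":
            act = stable_softmax(act.reshape(-1))
            layout = act.shape
        elif kind == "batchnorm":
            ga = GaussianActivation.deterministic(act, mode=CovarianceMode.DIAGONAL)
            ga.layout = layout
            out = propagate_batchnorm(
                ga,
                layer["batch_mean"],
                layer["batch_var"],
                layer["gamma"],
                layer["beta"],
                layer.get("eps", 1e-5),
            )
            act, layout = out.mean, out.layout
        else:
            raise ValueError(f"unknown layer type {kind!r}")
    return act


def mc_oracle(
    layers: Sequence[dict],
    x: Union[np.ndarray, GaussianActivation],
    n_samples: int,
    seed: int,
):
    """Monte-Carlo estimate of the network-output moments.

    Draws weight realizations (and input realizations when ``x`` is a
    :class:`GaussianActivation` with nonzero covariance), runs the
    deterministic forward pass per draw, and returns the sample mean vector
    and sample covariance matrix of the flattened outputs.
    """
    if n_samples < 2:
        raise ValueError("mc_oracle needs at least 2 samples")
    rng = np.random.default_rng(seed)
    param_slots = []
    for pos, layer in enumerate(layers):
        if layer["type"] == "conv":
            param_slots.append((pos, layer["kernel"]))
        elif layer["type"] == "fc":
            param_slots.append((pos, layer["weights"]))

    input_random = isinstance(x, GaussianActivation)
    if input_random:
        mu_x = x.flat_mean()
        cov_x = x.full()
        chol = None
        if np.any(cov_x):
            # eigen-based factor tolerates semidefinite covariances
            vals, vecs = np.linalg.eigh(cov_x)
            vals = np.clip(vals, 0.0, None)
            chol = vecs * np.sqrt(vals)
        shape_x = x.mean.shape
        layout_x = x.layout

    outs = []
    for _ in range(n_samples):
        draws = {}
        for pos, param in param_slots:
            noise = rng.standard_normal(param.mean.shape)
            draws[pos] = param.mean + np.sqrt(param.variance) * noise
        if input_random:
            xi = mu_x.copy()
            if chol is not None:
                xi = xi + chol @ rng.standard_normal(mu_x.size)
            xi = xi.reshape(layout_x)
        else:
            xi = x
        outs.append(deterministic_forward(layers, xi, draws).reshape(-1))
    outs = np.stack(outs)
    emp_mean = outs.mean(axis=0)
    centered = outs - emp_mean
    emp_cov = centered.T @ centered / (n_samples - 1)
    return emp_mean, emp_cov
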