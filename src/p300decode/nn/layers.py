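"""Functional NumPy layers (forward + analytic backward) for the compact CNN.

Every forward returns ``(out, cache)``; the matching backward consumes the
upstream gradient and the cache and returns input/parameter gradients. All
arrays are float64 so gradients can be checked against central finite
differences at tight tolerance.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft as sfft


def _same_pad(k: int) -> tuple[int, int]:
    """TF-style 'same' padding split for kernel length k (extra on the right)."""
    left = (k - 1) // 2
    return left, k - 1 - left


# ----------------------------------------------------- temporal convolution --
def conv_temporal_forward(x: np.ndarray, w: np.ndarray):
    """1D temporal conv shared across electrodes, 'same' padding, no bias.

    x: (N, C, T); w: (F, K). out: (N, F, C, T). Computed as an FFT-based
    linear correlation (exact up to float rounding, far faster than im2col
    at these sizes).
    """
    _, _, t = x.shape
    _, k = w.shape
    pl, pr = _same_pad(k)
    xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
    L = sfft.next_fast_len(xp.shape[2])
    xf = sfft.rfft(xp, L, axis=2)  # (N, C, Lf)
    wf = sfft.rfft(w, L, axis=1)  # (F, Lf)
    # out[n,f,c,t] = sum_k xp[n,c,t+k] * w[f,k]  (linear correlation)
    prod = xf[:, None, :, :] * np.conj(wf)[None, :, None, :]
    out = sfft.irfft(prod, L, axis=3)[..., :t]
    return np.ascontiguousarray(out), (xp, xf, w, t, pl, L)


def conv_temporal_backward(dout: np.ndarray, cache):
    xp, xf, w, t, pl, L = cache
    _, k = w.shape
    tp = xp.shape[2]
    df = sfft.rfft(dout, L, axis=3)  # (N, F, C, Lf)
    # dw[f,k] = sum_{n,c,t} dout[n,f,c,t] * xp[n,c,t+k]  (correlation)
    corr = np.einsum("nfcl,ncl->fl", np.conj(df), xf, optimize=True)
    dw = sfft.irfft(corr, L, axis=1)[:, :k]
    # dxp[n,c,s] = sum_{f,t} dout[n,f,c,t] * w[f,s-t]  (convolution)
    wf = sfft.rfft(w, L, axis=1)
    conv = np.einsum("nfcl,fl->ncl", df, wf, optimize=True)
    dxp = sfft.irfft(conv, L, axis=2)[..., :tp]
    return dxp[:, :, pl : pl + t], dw


# ---------------------------------------------------- depthwise spatial conv --
def depthwise_spatial_forward(x: np.ndarray, w: np.ndarray):
    """Collapse the electrode axis per temporal filter with D spatial filters.

    x: (N, F1, C, T); w: (F1, D, C). out: (N, F1*D, T).
    """
    n, f1, c, t = x.shape
    d = w.shape[1]
    out = np.einsum("nfct,fdc->nfdt", x, w, optimize=True).reshape(n, f1 * d, t)
    return out, (x, w)


def depthwise_spatial_backward(dout: np.ndarray, cache):
    x, w = cache
    n, f1, c, t = x.shape
    d = w.shape[1]
    dr = dout.reshape(n, f1, d, t)
    dw = np.einsum("nfdt,nfct->fdc", dr, x, optimize=True)
    dx = np.einsum("nfdt,fdc->nfct", dr, w, optimize=True)
    return dx, dw


# -------------------------------------------------------------- batch norm --
def batchnorm_forward(x: np.ndarray, gamma, beta, running, training: bool, momentum=0.99, eps=1e-3):
    """Per-feature-map batch norm over all non-channel axes.

    x: (N, C, ...) with channel axis 1. ``running`` is a dict holding
    'mean'/'var' updated in-place during training.
    """
    axes = (0,) + tuple(range(2, x.ndim))
    shape = (1, x.shape[1]) + (1,) * (x.ndim - 2)
    if training:
        mean = x.mean(axis=axes)
        var = x.var(axis=axes)
        running["mean"] = momentum * running["mean"] + (1 - momentum) * mean
        running["var"] = momentum * running["var"] + (1 - momentum) * var
    else:
        mean, var = running["mean"], running["var"]
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x - mean.reshape(shape)) * invstd.reshape(shape)
    out = gamma.reshape(shape) * xhat + beta.reshape(shape)
    m = x.size // x.shape[1]
    return out, (xhat, invstd, gamma, shape, m, training)


def batchnorm_backward(dout: np.ndarray, cache):
    xhat, invstd, gamma, shape, m, training = cache
    axes = (0,) + tuple(range(2, dout.ndim))
    dgamma = (dout * xhat).sum(axis=axes)
    dbeta = dout.sum(axis=axes)
    g = (gamma * invstd).reshape(shape)
    if training:
        dx = g / m * (m * dout - dbeta.reshape(shape) - xhat * dgamma.reshape(shape))
    else:
        dx = g * dout  # eval mode: running stats are constants
    return dx, dgamma, dbeta


# ------------------------------------------------------------- average pool --
def avgpool_forward(x: np.ndarray, pool: int):
    """Non-overlapping mean pool along the last axis (floor division)."""
    t = x.shape[-1]
    t2 = t // pool
    if t2 == 0:
        raise ValueError(f"pool size {pool} longer than axis length {t}")
    out = x[..., : t2 * pool].reshape(*x.shape[:-1], t2, pool).mean(axis=-1)
    return out, (x.shape, pool)


def avgpool_backward(dout: np.ndarray, cache):
    shape, pool = cache
    dx = np.zeros(shape, dtype=dout.dtype)
    t2 = dout.shape[-1]
    dx[..., : t2 * pool] = np.repeat(dout / pool, pool, axis=-1)
    return dx


# ------------------------------------------------------------------ dropout --
def dropout_forward(x: np.ndarray, rate: float, training: bool, rng: np.random.Generator | None):
    if not training or rate == 0.0:
        return x, None
    mask = ((rng.random(x.shape) >= rate) / (1.0 - rate)).astype(x.dtype)
    return x * mask, mask


def dropout_backward(dout: np.ndarray, mask):
    return dout if mask is None else dout * mask


# ------------------------------------------- separable (depthwise temporal) --
def separable_forward(x: np.ndarray, wt: np.ndarray, wp: np.ndarray):
    """Depthwise temporal conv ('same') followed by 1x1 pointwise mixing.

    x: (N, C, T); wt: (C, Kt); wp: (C_out, C). out: (N, C_out, T).
    """
    _, c, t = x.shape
    kt = wt.shape[1]
    pl, pr = _same_pad(kt)
    xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
    win = sliding_window_view(xp, kt, axis=2)  # (N, C, T, Kt)
    mid = np.einsum("nctk,ck->nct", win, wt, optimize=True)
    out = np.einsum("nct,oc->not", mid, wp, optimize=True)
    return out, (xp, wt, wp, mid, t, pl)


def separable_backward(dout: np.ndarray, cache):
    xp, wt, wp, mid, t, pl = cache
    kt = wt.shape[1]
    win = sliding_window_view(xp, kt, axis=2)
    dwp = np.einsum("not,nct->oc", dout, mid, optimize=True)
    dmid = np.einsum("not,oc->nct", dout, wp, optimize=True)
    dwt = np.einsum("nctk,nct->ck", win, dmid, optimize=True)
    v = dmid[:, :, :, None] * wt[None, :, None, :]  # (N, C, T, Kt)
    dxp = np.zeros_like(xp)
    for kk in range(kt):
        dxp[:, :, kk : kk + t] += v[:, :, :, kk]
    return dxp[:, :, pl : pl + t], dwt, dwp


# -------------------------------------------------------------------- dense --
def dense_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    return x @ w + b, x


def dense_backward(dout: np.ndarray, cache, w: np.ndarray):
    x = cache
    return dout @ w.T, x.T @ dout, dout.sum(axis=0)
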