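"""Elementary network operations: ELU, softmax, focal loss (and gradients)."""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

_EPS = 1e-12


def elu(x: np.ndarray | float) -> np.ndarray | float:
    """Exponential linear unit: x for x >= 0, e^x - 1 otherwise."""
    x = np.asarray(x)
    if x.dtype.kind != "f":
        x = x.astype(float)
    out = np.where(x >= 0, x, np.expm1(np.minimum(x, 0.0)))
    return out if out.ndim else float(out)


def elu_grad(x: np.ndarray) -> np.ndarray:
    """d elu / dx: 1 for x >= 0, e^x otherwise."""
    x = np.asarray(x)
    if x.dtype.kind != "f":
        x = x.astype(float)
    return np.where(x >= 0, x.dtype.type(1.0), np.exp(np.minimum(x, 0.0)))


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shift-invariant softmax along *axis*; rejects non-finite input."""
    z = np.asarray(logits, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("softmax input must be finite")
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def focal_loss(p_t: np.ndarray | float, gamma: float = 2.0) -> np.ndarray | float:
    """FL(p_t) = -(1 - p_t)^gamma * log(p_t); gamma = 0 is cross-entropy.

    p_t is the predicted probability of the *true* class. p_t = 0 is clamped
    to a tiny epsilon (and logged) so the loss stays finite.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p = np.asarray(p_t, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p_t must lie in [0, 1]")
    if (p == 0).any():
        logger.warning("focal_loss: clamping p_t = 0 to %.0e", _EPS)
        p = np.maximum(p, _EPS)
    out = -((1.0 - p) ** gamma) * np.log(p)
    return out if out.ndim else float(out)


def focal_loss_grad_logits(
    logits: np.ndarray, labels: np.ndarray, gamma: float = 2.0
) -> tuple[float, np.ndarray]:
    """Mean focal loss over a batch and its gradient w.r.t. the logits.

    logits: (n, 2); labels: (n,) in {0, 1}. Returns (loss, dlogits) with
    dlogits already divided by the batch size.
    """
    n = len(labels)
    q = softmax(logits, axis=1)  # (n, 2)
    p_t = np.maximum(q[np.arange(n), labels], _EPS)
    loss = float(np.mean(focal_loss(p_t, gamma)))
    # dFL/dp_t, with the gamma=0 branch reducing to -1/p_t (plain CE).
    one_minus = 1.0 - p_t
    if gamma == 0:
        dl_dpt = -1.0 / p_t
    else:
        dl_dpt = gamma * one_minus ** (gamma - 1.0) * np.log(p_t) - one_minus**gamma / p_t
    # dp_t/dlogits = p_t * (onehot - q)
    onehot = np.zeros_like(q)
    onehot[np.arange(n), labels] = 1.0
    dlogits = dl_dpt[:, None] * (p_t[:, None] * (onehot - q)) / n
    return loss, dlogits.astype(np.asarray(logits).dtype)
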