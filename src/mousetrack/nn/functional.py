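"""Softmax and cross-entropy with analytic gradients."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                          axis: int = -1):
    """Mean softmax cross entropy over all positions.

    ``labels`` holds integer class indices with the shape of ``logits``
    minus the class axis.  Returns ``(loss, dloss/dlogits)``; the gradient
    is already divided by the number of positions, so summing losses of
    independent heads sums their gradients.
    """
    logits = np.asarray(logits, dtype=np.float32)
    ax = axis % logits.ndim
    moved = np.moveaxis(logits, ax, -1)
    flat = moved.reshape(-1, moved.shape[-1])
    lab = np.asarray(labels).reshape(-1)
    if lab.shape[0] != flat.shape[0]:
        raise ValueError("labels shape does not match logits")
    if lab.min() < 0 or lab.max() >= flat.shape[1]:
        raise ValueError("label index out of class range")
    z = flat - flat.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1))
    n = flat.shape[0]
    loss = float((logsumexp - z[np.arange(n), lab]).mean())
    p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    p[np.arange(n), lab] -= 1.0
    grad = np.moveaxis((p / n).reshape(moved.shape), -1, ax)
    return loss, grad.astype(np.float32)
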