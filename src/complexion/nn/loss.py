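"""Softmax cross-entropy with a numerically stable log-sum-exp."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits.

    ``targets`` are integer class indices in [0, K).
    """
    b = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -float(logp[np.arange(b), targets].mean())
    grad = np.exp(logp)
    grad[np.arange(b), targets] -= 1.0
    return loss, (grad / b).astype(logits.dtype)
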