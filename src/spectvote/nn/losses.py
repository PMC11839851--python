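"""Losses on the single-logit output.

The classifier head is a linear layer producing one logit z per image; the
sigmoid s = 1/(1+exp(-z)) is the reported output.  Binary cross-entropy is
evaluated in logit space for numerical stability; the squared-error loss is
taken on the sigmoid itself (targets may be fractional vote proportions).
Both return (mean loss, d loss / d logit).
"""

from __future__ import annotations

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    z = logits.astype(np.float64)
    t = targets.astype(np.float64)
    loss = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - t) / z.size
    return float(loss.mean()), grad.astype(np.float32)


def mse_on_sigmoid(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    z = logits.astype(np.float64)
    t = targets.astype(np.float64)
    s = sigmoid(z)
    loss = float(((s - t) ** 2).mean())
    grad = 2.0 * (s - t) * s * (1.0 - s) / z.size
    return loss, grad.astype(np.float32)
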