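"""Ordinal classification mechanics for the four critical values.

The four-level ordinal target (0 no-risk < 1 < 2 < 3 high-risk) is
decomposed into three cumulative binary tasks ("is the value greater than
no / low / medium risk?"), the Frank-Hall construction. The network emits
three logits z; sigmoid gives the cumulative probabilities p, training
minimizes the mean binary cross-entropy over the three tasks, and class
probabilities are recovered as differences of consecutive cumulative
probabilities:

    q = (1 - p0,  p0 - p1,  p1 - p2,  p2)

which sums to 1 for any p and reproduces the reference rows
(0,0,0) -> class 0, (1,0,0) -> 1, (1,1,0) -> 2, (1,1,1) -> 3.

A literal variant of the middle differences (subtracting from the previous
*class* probability rather than the previous *cumulative* probability) is
kept behind ``literal=True`` for comparison; it does not normalize and is
never used by the model.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "N_TASKS",
    "encode_cumulative",
    "decode_value",
    "cumulative_probs",
    "ordinal_loss",
    "class_probs",
    "predict",
    "LOSS_EPS",
]

N_TASKS = 3
LOSS_EPS = 1e-7


def encode_cumulative(value) -> np.ndarray:
    """Cumulative binary target(s) for critical value(s) in {0,1,2,3}.

    Scalar -> shape (3,); array of shape (...,) -> shape (..., 3).
    y[k] = 1 iff value > k.
    """
    v = np.asarray(value)
    if np.any((v < 0) | (v > 3) | (v != np.floor(v))):
        raise ValueError(f"critical values must be integers in 0..3, got {value!r}")
    return (v[..., None] > np.arange(N_TASKS)).astype(np.float64)


def decode_value(y) -> np.ndarray | int:
    """Inverse of :func:`encode_cumulative`: sum of indicators.

    Rejects non-monotone indicator vectors (e.g. (0,1,0)), which encode no
    critical value.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.shape[-1] != N_TASKS:
        raise ValueError(f"expected {N_TASKS} cumulative indicators")
    if np.any(np.diff(y, axis=-1) > 0):
        raise ValueError(f"non-monotone cumulative indicators: {y!r}")
    out = y.sum(axis=-1).astype(int)
    return int(out) if out.ndim == 0 else out


def cumulative_probs(z) -> np.ndarray:
    """p = sigmoid(z): probabilities of exceeding no/low/medium risk."""
    z = np.asarray(z, dtype=np.float64)
    if z.shape[-1] != N_TASKS:
        raise ValueError(f"expected {N_TASKS} logits, got shape {z.shape}")
    return 1.0 / (1.0 + np.exp(-z))


def ordinal_loss(p, y, eps: float = LOSS_EPS) -> float:
    """Mean over the three tasks (and any batch axes) of binary cross-entropy
    -[y log p + (1-y) log(1-p)], with p clipped to [eps, 1-eps]."""
    p = np.clip(np.asarray(p, dtype=np.float64), eps, 1.0 - eps)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs y {y.shape}")
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log1p(-p))))


def class_probs(p, literal: bool = False) -> np.ndarray:
    """Per-class probabilities from cumulative probabilities.

    Default (normalizing) form: q = (1-p0, p0-p1, p1-p2, p2); sums to 1 for
    every p in [0,1]^3. When the three sigmoids are non-monotone, middle
    entries may be negative; they are returned as-is (a negative entry never
    wins the argmax in :func:`predict`).

    ``literal=True`` chains the differences through the class probabilities
    instead (q1 = q0 - p1, q2 = q1 - p2); this variant does NOT normalize and
    exists only for comparison.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.shape[-1] != N_TASKS:
        raise ValueError(f"expected {N_TASKS} cumulative probabilities")
    p0, p1, p2 = p[..., 0], p[..., 1], p[..., 2]
    q0 = 1.0 - p0
    if literal:
        q1 = q0 - p1
        q2 = q1 - p2
    else:
        q1 = p0 - p1
        q2 = p1 - p2
    return np.stack([q0, q1, q2, p2], axis=-1)


def predict(z) -> np.ndarray | int:
    """Critical value prediction: argmax of the class probabilities derived
    from the logits; exact ties resolve to the lower class."""
    q = class_probs(cumulative_probs(z))
    out = np.argmax(q, axis=-1)  # argmax returns the first (lowest) maximizer
    return int(out) if out.ndim == 0 else out
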