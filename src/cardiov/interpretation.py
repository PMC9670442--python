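"""Grad-CAM saliency for the 1D network.

For a chosen layer (a stage output) and target class, the gradient of the
target score with respect to the layer's activation is averaged over time to
give one weight per channel; the rectified, weight-summed activation is the
temporal saliency map, linearly interpolated to the input's sample count for
overlay. The target score defaults to the derived class probability; a
single cumulative logit can be targeted instead.

The map is shared across leads (the network mixes leads in its first
convolution); the per-stage profile combines the per-lead overlays —
mean by default, sum optionally — and min-max normalizes each stage row
for visual comparability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CardioVNet
from .nn import Tensor, sigmoid
from .ordinal import class_probs

__all__ = ["SaliencyMap", "StageProfile", "grad_cam", "stage_profile"]


@dataclass
class SaliencyMap:
    layer_id: str
    target_class: int
    weights: np.ndarray        # (layer_time,) nonnegative, pre-upsampling
    overlay: np.ndarray        # (leads, input_time) nonnegative

    def __post_init__(self):
        assert np.all(self.weights >= 0) and np.all(self.overlay >= 0)


@dataclass
class StageProfile:
    """One combined, [0,1]-normalized weight row per stage (stage 1 first)."""
    target_class: int
    rows: np.ndarray           # (n_stages, input_time)


def _target_score(logits: Tensor, target_class: int, target: str) -> Tensor:
    if target == "logit":
        return logits[0, min(target_class, 2)]
    if target != "class_prob":
        raise ValueError(f"target must be 'class_prob' or 'logit', "
                         f"got {target!r}")
    p = sigmoid(logits)  # cumulative probabilities, autodiff-tracked
    p0, p1, p2 = p[0, 0], p[0, 1], p[0, 2]
    if target_class == 0:
        return 1.0 - p0
    if target_class == 1:
        return p0 - p1
    if target_class == 2:
        return p1 - p2
    if target_class == 3:
        return p2
    raise ValueError(f"target_class must be in 0..3, got {target_class}")


def grad_cam(network: CardioVNet, signal: np.ndarray, layer_id: str,
             target_class: int, target: str = "class_prob") -> SaliencyMap:
    """Saliency map of one record for one layer and target class.

    ``signal`` is (leads, samples); ``layer_id`` is ``'stage1'``..``'stageS'``.
    The network is evaluated in inference mode (dropout off, running batch
    statistics); gradients flow only through the autodiff tape.
    """
    x = np.asarray(signal, dtype=np.float64)[None]
    network.eval()
    capture: dict[str, Tensor] = {}
    logits = network.forward(x, capture=capture)
    if layer_id not in capture or layer_id == "pooled":
        valid = [k for k in capture if k != "pooled"]
        raise KeyError(f"unknown layer {layer_id!r}; available: {valid}")
    activation = capture[layer_id]
    if network.config.head != "ordinal":
        raise ValueError("saliency targets the ordinal head; "
                         f"network head is {network.config.head!r}")
    score = _target_score(logits, target_class, target)
    score.backward()
    grad = activation.grad[0]          # (C, T)
    act = activation.data[0]
    alpha = grad.mean(axis=1)          # temporal-average gradient per channel
    raw = alpha @ act                  # weighted channel sum, (T,)
    weights = np.maximum(raw, 0.0)
    n_in = x.shape[2]
    positions = np.linspace(0, n_in - 1, num=weights.size)
    upsampled = np.interp(np.arange(n_in), positions, weights)
    overlay = np.broadcast_to(upsampled, (x.shape[1], n_in)).copy()
    return SaliencyMap(layer_id=layer_id, target_class=target_class,
                       weights=weights, overlay=overlay)


def stage_profile(network: CardioVNet, signal: np.ndarray, target_class: int,
                  combine: str = "mean",
                  target: str = "class_prob") -> StageProfile:
    """Per-stage combined saliency rows (Grad-CAM at each stage's output).

    Each row is the across-lead combination (mean or sum) of the stage's
    overlay, min-max normalized to [0, 1]; an all-zero map stays all-zero.
    """
    if combine not in ("mean", "sum"):
        raise ValueError("combine must be 'mean' or 'sum'")
    n_stages = network.config.n_stages
    rows = []
    for s in range(1, n_stages + 1):
        m = grad_cam(network, signal, f"stage{s}", target_class, target=target)
        row = m.overlay.mean(axis=0) if combine == "mean" \
            else m.overlay.sum(axis=0)
        span = row.max() - row.min()
        rows.append((row - row.min()) / span if span > 0
                    else np.zeros_like(row))
    return StageProfile(target_class=target_class, rows=np.stack(rows))
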