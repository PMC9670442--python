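"""The 61-layer, 7-stage grouped-convolution residual network.

Architecture (default configuration, input (N, 12, 5000)):

========  ==========================  ==============
stage     layers                      output
========  ==========================  ==============
1         (Conv1, ConvK, Conv1) x 2   (N,   64, 2500)
2         (Conv1, ConvK, Conv1) x 2   (N,  160, 1250)
3         (Conv1, ConvK, Conv1) x 2   (N,  160,  625)
4         (Conv1, ConvK, Conv1) x 3   (N,  400,  312)
5         (Conv1, ConvK, Conv1) x 3   (N,  400,  156)
6         (Conv1, ConvK, Conv1) x 4   (N, 1024,   78)
7         (Conv1, ConvK, Conv1) x 4   (N, 1024,   39)
pooling   global average over time    (N, 1024)
head      dense                       (N, 3)
========  ==========================  ==============

Each block is pre-activation — batch norm, swish and dropout precede every
convolution — with a squeeze-excitation gate before the residual addition.
ConvK is an aggregated (grouped) convolution, kernel 16 in 16 groups. The
first block of each stage halves the temporal length (stride-2 ConvK,
symmetric padding 7/7, so lengths follow floor(L/2)); its shortcut
max-pools the identity by 2 and, when the channel width changes, applies a
kernel-1 linear projection. The counted depth — main-path convolutions plus
the prediction dense layer — is (2+2+2+3+3+4+4) x 3 + 1 = 61.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["ModelConfig", "ResidualBlock", "CardioVNet", "build_model",
           "count_layers", "save_checkpoint", "load_checkpoint",
           "CHECKPOINT_VERSION"]

CHECKPOINT_VERSION = 1

HEAD_DIMS = {"ordinal": 3, "classification": 4, "regression": 1}


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the network topology."""

    stage_channels: tuple[int, ...] = (64, 160, 160, 400, 400, 1024, 1024)
    stage_blocks: tuple[int, ...] = (2, 2, 2, 3, 3, 4, 4)
    kernel_size: int = 16
    groups: int = 16
    dropout_rate: float = 0.2
    se_reduction: int = 16
    head: str = "ordinal"
    input_leads: int = 12

    def __post_init__(self):
        if len(self.stage_channels) != len(self.stage_blocks):
            raise ValueError("stage_channels and stage_blocks lengths differ")
        if any(b < 1 for b in self.stage_blocks):
            raise ValueError("stage_blocks must be positive")
        bad = [c for c in self.stage_channels if c % self.groups]
        if bad:
            raise ValueError(f"stage channels {bad} not divisible by "
                             f"groups={self.groups}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.head not in HEAD_DIMS:
            raise ValueError(f"head must be one of {sorted(HEAD_DIMS)}")

    @property
    def n_stages(self) -> int:
        return len(self.stage_blocks)

    @property
    def output_dim(self) -> int:
        return HEAD_DIMS[self.head]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_channels"] = list(self.stage_channels)
        d["stage_blocks"] = list(self.stage_blocks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["stage_channels"] = tuple(d["stage_channels"])
        d["stage_blocks"] = tuple(d["stage_blocks"])
        return cls(**d)


class ResidualBlock(nn.Module):
    """Pre-activation bottleneck: (BN-Swish-DO-Conv1, BN-Swish-DO-ConvK,
    BN-Swish-DO-Conv1), SE gate, residual shortcut."""

    def __init__(self, in_channels: int, width: int, config: ModelConfig,
                 downsample: bool, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        k = config.kernel_size
        self.downsample = downsample
        self.bn1 = nn.BatchNorm1d(in_channels, dtype=dtype)
        self.do1 = nn.Dropout(config.dropout_rate, rng)
        self.conv1 = nn.Conv1d(in_channels, width, 1, rng, dtype=dtype)
        self.bn2 = nn.BatchNorm1d(width, dtype=dtype)
        self.do2 = nn.Dropout(config.dropout_rate, rng)
        if downsample:
            # symmetric pad (k//2-1 each side) gives Lout = floor(L/2)
            self.convk = nn.Conv1d(width, width, k, rng, stride=2,
                                   padding=(k // 2 - 1, k // 2 - 1),
                                   groups=config.groups, dtype=dtype)
        else:
            self.convk = nn.Conv1d(width, width, k, rng, stride=1,
                                   padding=(k // 2 - 1, k // 2),
                                   groups=config.groups, dtype=dtype)
        self.bn3 = nn.BatchNorm1d(width, dtype=dtype)
        self.do3 = nn.Dropout(config.dropout_rate, rng)
        self.conv3 = nn.Conv1d(width, width, 1, rng, dtype=dtype)
        self.se = nn.SqueezeExcite(width, config.se_reduction, rng, dtype=dtype)
        if downsample:
            self.pool = nn.MaxPool1d(2, 2)
        self.project = (nn.Conv1d(in_channels, width, 1, rng, dtype=dtype)
                        if in_channels != width else None)

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv1(self.do1(nn.swish(self.bn1(x))))
        h = self.convk(self.do2(nn.swish(self.bn2(h))))
        h = self.conv3(self.do3(nn.swish(self.bn3(h))))
        h = self.se(h)
        shortcut = self.pool(x) if self.downsample else x
        if self.project is not None:
            shortcut = self.project(shortcut)
        return h + shortcut


class CardioVNet(nn.Module):
    """The full network; stages of residual blocks, global average pooling,
    one dense prediction layer whose width depends on the head."""

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        super().__init__()
        self.config = config
        self.dtype = np.dtype(dtype).type
        rng = np.random.default_rng(seed)
        self.stages: list[list[ResidualBlock]] = []
        in_ch = config.input_leads
        for width, n_blocks in zip(config.stage_channels, config.stage_blocks):
            stage = []
            for b in range(n_blocks):
                stage.append(ResidualBlock(in_ch, width, config,
                                           downsample=(b == 0), rng=rng,
                                           dtype=self.dtype))
                in_ch = width
            self.stages.append(stage)
        self.bn_final = nn.BatchNorm1d(in_ch, dtype=self.dtype)
        self.head = nn.Dense(in_ch, config.output_dim, rng, dtype=self.dtype)
        self._head_rng = rng

    # self.stages is a list of lists, which the base Module walkers do not
    # descend into; override discovery explicitly.
    def children(self):
        for stage in self.stages:
            yield from stage
        yield self.bn_final
        yield self.head

    def named_parameters(self, prefix: str = ""):
        for s, stage in enumerate(self.stages):
            for b, block in enumerate(stage):
                yield from block.named_parameters(f"{prefix}stage{s + 1}.{b}.")
        yield from self.bn_final.named_parameters(f"{prefix}bn_final.")
        yield from self.head.named_parameters(f"{prefix}head.")

    def buffers(self, prefix: str = ""):
        for s, stage in enumerate(self.stages):
            for b, block in enumerate(stage):
                yield from block.buffers(f"{prefix}stage{s + 1}.{b}.")
        yield from self.bn_final.buffers(f"{prefix}bn_final.")

    def set_head(self, head: str, seed: int | None = None):
        """Swap the prediction layer (re-initialized: its width changes with
        the head, so weights cannot carry over). The backbone is untouched."""
        if head not in HEAD_DIMS:
            raise ValueError(f"unknown head {head!r}")
        self.config = ModelConfig.from_dict({**self.config.to_dict(),
                                             "head": head})
        rng = np.random.default_rng(seed) if seed is not None else self._head_rng
        width = self.config.stage_channels[-1]
        self.head = nn.Dense(width, HEAD_DIMS[head], rng, dtype=self.dtype)
        self.head.train(self.training)
        return self

    def forward(self, x, capture: dict | None = None) -> Tensor:
        """Forward pass. ``x`` is (N, leads, L) array or Tensor; ``capture``,
        if given, is filled with the stage-output Tensors keyed 'stage1'... —
        the hooks the saliency code differentiates through."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.dtype))
        if x.ndim != 3 or x.shape[1] != self.config.input_leads:
            raise ValueError(f"expected (N, {self.config.input_leads}, L) "
                             f"input, got {x.shape}")
        if x.shape[2] < 2 ** self.config.n_stages:
            raise ValueError(f"input length {x.shape[2]} shorter than the "
                             f"receptive minimum 2^{self.config.n_stages}")
        h = x
        for s, stage in enumerate(self.stages):
            for block in stage:
                h = block(h)
            if capture is not None:
                capture[f"stage{s + 1}"] = h
        h = nn.swish(self.bn_final(h))
        pooled = h.mean(axis=2)
        if capture is not None:
            capture["pooled"] = pooled
        return self.head(pooled)

    def predict_logits(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Eval-mode logits for an array of records, batched."""
        was_training = self.training
        self.eval()
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(self.forward(np.asarray(x[i:i + batch_size],
                                                dtype=self.dtype)).data)
        if was_training:
            self.train()
        return np.concatenate(outs, axis=0)


def build_model(config: ModelConfig | None = None, seed: int = 0) -> CardioVNet:
    return CardioVNet(config or ModelConfig(), seed=seed)


def count_layers(network: CardioVNet) -> int:
    """Counted depth: main-path convolutions plus dense prediction layers.

    Shortcut projections, SE dense layers, batch norms and pooling are not
    counted — the convention under which the default topology is 61 layers.
    """
    n = 0
    for stage in network.stages:
        for _ in stage:
            n += 3  # conv1, convk, conv3
    return n + 1  # prediction dense


def save_checkpoint(network: CardioVNet, path) -> Path:
    """Serialize config + parameters + buffers to an .npz with a version tag."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = network.state_dict()
    np.savez(path, __config__=json.dumps(network.config.to_dict()),
             __version__=CHECKPOINT_VERSION, **state)
    return path


def load_checkpoint(path) -> CardioVNet:
    with np.load(Path(path), allow_pickle=False) as data:
        version = int(data["__version__"])
        if version != CHECKPOINT_VERSION:
            raise ValueError(f"checkpoint version {version} unsupported")
        config = ModelConfig.from_dict(json.loads(str(data["__config__"])))
        net = CardioVNet(config)
        state = {k: data[k] for k in data.files
                 if k not in ("__config__", "__version__")}
    net.load_state_dict(state)
    return net
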