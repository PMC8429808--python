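"""The self-supervised subject-identification encoder.

A stack of 3D convolutional blocks is trained to classify *which subject* a
single rs-fMRI timepoint belongs to, with softmax cross-entropy against the
one-hot subject id — a pretext task whose labels come for free with the
scans. The reference architecture takes an (80, 96, 80) volume through four
blocks of [conv(c→c), conv(c→2c), avg-pool 2x2x2], starting at 8 channels
and doubling before each pooling so 128 channels remain before the dense
layer; two further convolutions at constant width precede the dense layer
that maps onto the training subjects (105 in the reference setup).
Convolutions use kernel 3, stride 1 and symmetric padding 1 so spatial size
is preserved; only pooling (kernel 2, stride 2) downsamples, halving every
axis per block. ReLU follows every convolution. Optimization is Adam under a
piecewise-constant learning-rate schedule (reference: 1e-4 for 17,000
iterations then 1e-5 for 110,000, batch 32), sampling batches of single
timepoints uniformly with replacement over all (subject, timepoint) pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .io_cohort import Volume4D

__all__ = [
    "EncoderConfig",
    "TrainConfig",
    "LayerDescriptor",
    "EncoderSpec",
    "TrainedEncoder",
    "build_encoder",
    "build_network",
    "train_encoder",
    "classify_timepoint",
    "training_accuracy",
    "stack_timepoints",
    "PAPER_ENCODER",
    "PAPER_TRAIN",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters; defaults give the reference network."""

    input_shape: tuple[int, int, int] = (80, 96, 80)
    n_subjects: int = 105
    n_blocks: int = 4
    base_channels: int = 8
    conv_kernel: int = 3
    conv_stride: int = 1
    pool_kernel: int = 2
    pool_stride: int = 2
    n_tail_convs: int = 2
    double_at_entry: bool = False  # alternative: double channels at block entry
    dense_input: str = "flatten"  # or "global_pool"

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.conv_stride != 1:
            raise ValueError("only stride-1 convolutions are supported")
        if self.pool_kernel != self.pool_stride:
            raise ValueError("pooling must be non-overlapping (kernel == stride)")
        if self.dense_input not in ("flatten", "global_pool"):
            raise ValueError("dense_input must be 'flatten' or 'global_pool'")
        factor = self.pool_stride**self.n_blocks
        for axis, dim in enumerate(self.input_shape):
            if dim % factor:
                raise ValueError(
                    f"input axis {axis} (size {dim}) not divisible by "
                    f"pool_stride^n_blocks = {factor}"
                )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule; defaults give the reference run."""

    lr_schedule: tuple[tuple[float, int], ...] = ((1e-4, 17_000), (1e-5, 110_000))
    batch_size: int = 32
    seed: int = 0
    eval_every: int = 100

    def __post_init__(self) -> None:
        if not self.lr_schedule or any(lr <= 0 for lr, _ in self.lr_schedule):
            raise ValueError("all learning rates must be > 0")
        if self.total_iterations < 1:
            raise ValueError("total iterations must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @property
    def total_iterations(self) -> int:
        return sum(n for _, n in self.lr_schedule)

    def lr_at(self, iteration: int) -> float:
        """Learning rate in effect at 0-based iteration index."""
        done = 0
        for lr, n in self.lr_schedule:
            done += n
            if iteration < done:
                return lr
        return self.lr_schedule[-1][0]


PAPER_ENCODER = EncoderConfig()
PAPER_TRAIN = TrainConfig()


@dataclass(frozen=True)
class LayerDescriptor:
    kind: str  # conv / relu / pool / flatten / global_pool / dense
    in_channels: int
    out_channels: int
    out_shape: tuple[int, ...]
    n_params: int


@dataclass
class EncoderSpec:
    """Layer-by-layer description of the built architecture."""

    config: EncoderConfig
    layers: list[LayerDescriptor]

    @property
    def total_parameters(self) -> int:
        return sum(d.n_params for d in self.layers)

    @property
    def channels_before_dense(self) -> int:
        convs = [d for d in self.layers if d.kind == "conv"]
        return convs[-1].out_channels

    @property
    def dense_output_dim(self) -> int:
        return self.layers[-1].out_shape[0]

    @property
    def shape_before_flatten(self) -> tuple[int, int, int]:
        pools = [d for d in self.layers if d.kind == "pool"]
        return tuple(pools[-1].out_shape[1:])

    def summary(self) -> str:
        lines = [
            f"{i:2d}  {d.kind:<12} {d.in_channels:>4} -> {d.out_channels:<4} "
            f"out={d.out_shape}  params={d.n_params}"
            for i, d in enumerate(self.layers)
        ]
        lines.append(f"total parameters: {self.total_parameters}")
        return "\n".join(lines)


def _channel_plan(cfg: EncoderConfig) -> list[tuple[str, int, int]]:
    """(kind, in_c, out_c) for every weighted/structural layer in order."""
    plan: list[tuple[str, int, int]] = []
    c = cfg.base_channels
    in_c = 1
    for _ in range(cfg.n_blocks):
        if cfg.double_at_entry:
            plan += [("conv", in_c, 2 * c), ("conv", 2 * c, 2 * c)]
            in_c = 2 * c
            c = 2 * c
        else:
            plan += [("conv", in_c, c), ("conv", c, 2 * c)]
            in_c = 2 * c
            c = 2 * c
        plan.append(("pool", in_c, in_c))
    for _ in range(cfg.n_tail_convs):
        plan.append(("conv", in_c, in_c))
    return plan


def build_encoder(cfg: EncoderConfig) -> EncoderSpec:
    """Resolve the architecture: every layer's shape and parameter count."""
    shape = tuple(cfg.input_shape)
    k = cfg.conv_kernel
    descriptors: list[LayerDescriptor] = []
    for kind, in_c, out_c in _channel_plan(cfg):
        if kind == "conv":
            n_params = out_c * (in_c * k**3 + 1)
            descriptors.append(
                LayerDescriptor("conv", in_c, out_c, (out_c,) + shape, n_params)
            )
            descriptors.append(
                LayerDescriptor("relu", out_c, out_c, (out_c,) + shape, 0)
            )
        else:
            shape = tuple(d // cfg.pool_stride for d in shape)
            descriptors.append(
                LayerDescriptor("pool", in_c, out_c, (out_c,) + shape, 0)
            )
    c = descriptors[-1].out_channels
    if cfg.dense_input == "flatten":
        flat = c * int(np.prod(shape))
        descriptors.append(LayerDescriptor("flatten", c, c, (flat,), 0))
    else:
        flat = c
        descriptors.append(LayerDescriptor("global_pool", c, c, (flat,), 0))
    descriptors.append(
        LayerDescriptor(
            "dense", c, cfg.n_subjects, (cfg.n_subjects,),
            (flat + 1) * cfg.n_subjects,
        )
    )
    return EncoderSpec(config=cfg, layers=descriptors)


def build_network(cfg: EncoderConfig, seed: int = 0, dtype=np.float32) -> nn.Network:
    """Instantiate weights for the architecture (fan-in-scaled init, seeded)."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    first = True
    for kind, in_c, out_c in _channel_plan(cfg):
        if kind == "conv":
            layers.append(
                nn.Conv3D(in_c, out_c, cfg.conv_kernel, rng, dtype,
                          compute_dx=not first)
            )
            first = False
            layers.append(nn.ReLU())
        else:
            layers.append(nn.AvgPool3D(cfg.pool_kernel))
    spec = build_encoder(cfg)
    if cfg.dense_input == "flatten":
        layers.append(nn.Flatten())
    else:
        layers.append(nn.GlobalAvgPool())
    flat = spec.layers[-2].out_shape[0]
    layers.append(nn.Dense(flat, cfg.n_subjects, rng, dtype))
    return nn.Network(layers)


@dataclass
class TrainedEncoder:
    """Built architecture + fitted weights + training log."""

    spec: EncoderSpec
    network: nn.Network
    log: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def config(self) -> EncoderConfig:
        return self.spec.config

    def _check_shape(self, x: np.ndarray) -> None:
        if x.shape[-3:] != tuple(self.config.input_shape):
            raise ValueError(
                f"timepoint shape {x.shape[-3:]} != encoder input "
                f"{tuple(self.config.input_shape)}"
            )

    def logits(self, timepoints: np.ndarray, batch: int = 16) -> np.ndarray:
        """Dense-layer (pre-softmax) outputs for (n, X, Y, Z) timepoints."""
        x = np.asarray(timepoints, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        self._check_shape(x)
        outs = [
            self.network.forward(x[i : i + batch][..., None])
            for i in range(0, len(x), batch)
        ]
        return np.concatenate(outs, axis=0)

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(json.dumps(asdict(self.config), indent=2))
        np.savez(out / "weights.npz", **self.network.state_dict())
        self.log.to_csv(out / "training_log.csv", index=False)
        return out

    @classmethod
    def load(cls, checkpoint_dir: str | Path) -> "TrainedEncoder":
        ckpt = Path(checkpoint_dir)
        raw = json.loads((ckpt / "config.json").read_text())
        raw["input_shape"] = tuple(raw["input_shape"])
        cfg = EncoderConfig(**raw)
        net = build_network(cfg, seed=0)
        with np.load(ckpt / "weights.npz") as state:
            net.load_state_dict(dict(state))
        log_path = ckpt / "training_log.csv"
        log = pd.read_csv(log_path) if log_path.exists() else pd.DataFrame()
        return cls(spec=build_encoder(cfg), network=net, log=log)


def stack_timepoints(
    scans: Sequence[Volume4D], labels: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Flatten scans into (n_total_timepoints, X, Y, Z) with per-timepoint labels."""
    if len(scans) != len(labels):
        raise ValueError("one label per scan required")
    xs, ys = [], []
    for vol, lab in zip(scans, labels):
        xs.append(np.moveaxis(vol.data, -1, 0))
        ys.append(np.full(vol.n_timepoints, int(lab)))
    return (
        np.concatenate(xs, axis=0).astype(np.float32),
        np.concatenate(ys, axis=0),
    )


def train_encoder(
    scans: Sequence[Volume4D],
    labels: Sequence[int],
    enc: EncoderConfig,
    tr: TrainConfig,
) -> TrainedEncoder:
    """Train the subject-identification network on single timepoints.

    Every iteration draws ``batch_size`` (subject, timepoint) pairs uniformly
    with replacement (seeded), computes softmax cross-entropy against the
    owners' one-hot ids, and applies one Adam step at the scheduled learning
    rate. The log records (iteration, loss, accuracy) every ``eval_every``
    iterations, accuracy being the running batch accuracy. A non-finite loss
    aborts with a diagnostic rather than training on.
    """
    if len(scans) == 0:
        raise ValueError("empty training set")
    x, y = stack_timepoints(scans, labels)
    if y.min() < 0 or y.max() >= enc.n_subjects:
        raise ValueError(
            f"labels must lie in [0, {enc.n_subjects - 1}], got "
            f"[{y.min()}, {y.max()}]"
        )
    if x.shape[1:] != tuple(enc.input_shape):
        raise ValueError(
            f"scan spatial shape {x.shape[1:]} != encoder input {enc.input_shape}"
        )
    net = build_network(enc, seed=tr.seed)
    opt = nn.Adam(net, lr=tr.lr_schedule[0][0])
    rng = np.random.default_rng(tr.seed)
    n = len(x)
    records = []
    for it in range(tr.total_iterations):
        idx = rng.integers(0, n, size=tr.batch_size)
        batch = x[idx][..., None]
        logits = net.forward(batch)
        loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged: non-finite loss at iteration {it} "
                f"(lr={tr.lr_at(it)}); lower the learning rate"
            )
        net.backward(dlogits.astype(np.float32))
        opt.lr = tr.lr_at(it)
        opt.step()
        if (it + 1) % tr.eval_every == 0 or it == tr.total_iterations - 1:
            acc = float(np.mean(np.argmax(logits, axis=1) == y[idx]))
            records.append({"iteration": it + 1, "loss": loss, "accuracy": acc})
    log = pd.DataFrame.from_records(records)
    return TrainedEncoder(spec=build_encoder(enc), network=net, log=log)


def classify_timepoint(enc: TrainedEncoder, vol: np.ndarray) -> np.ndarray:
    """Posterior over training subjects for a single 3D timepoint."""
    logits = enc.logits(np.asarray(vol))
    return nn.softmax(logits, axis=1)[0]


def training_accuracy(
    enc: TrainedEncoder, scans: Sequence[Volume4D], labels: Sequence[int]
) -> float:
    """Fraction of timepoints whose argmax posterior is the true subject.

    ``np.argmax`` breaks ties toward the lowest subject index.
    """
    x, y = stack_timepoints(scans, labels)
    logits = enc.logits(x)
    return float(np.mean(np.argmax(logits, axis=1) == y))
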