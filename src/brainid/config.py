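"""Structured run configuration: YAML round-trip with strict key checking.

A RunConfig nests the simulation, split, encoder, training, baseline and
evaluation settings plus one global seed; per-stage sub-seeds are derived
deterministically from the global seed and the stage name so stages can be
rerun independently without sharing RNG state.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .encoder import EncoderConfig, TrainConfig
from .synth import SimConfig

__all__ = ["RunConfig", "load_config", "save_config", "stage_seed", "desk_config"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed: sha256("<seed>:<stage>") mod 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _plain(obj):
    """Tuples -> lists recursively, so configs serialize as plain YAML."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def _from_dict(cls, raw: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**raw)


@dataclass(frozen=True)
class SimulateSection:
    grid_shape: tuple[int, int, int] = (24, 28, 24)
    n_timepoints: int = 40
    signature_amplitude: float = 5.0
    group_amplitude: float = 3.0
    age_amplitude: float = 1.0
    noise_sd: float = 1.0
    smoothing_sigma_vox: float = 1.5
    n_patients: int = 24
    n_controls: int = 24
    age_range: tuple[float, float] = (18.0, 65.0)

    def sim_config(self, seed: int) -> SimConfig:
        return SimConfig(
            grid_shape=tuple(self.grid_shape),
            n_timepoints=self.n_timepoints,
            signature_amplitude=self.signature_amplitude,
            group_amplitude=self.group_amplitude,
            age_amplitude=self.age_amplitude,
            noise_sd=self.noise_sd,
            smoothing_sigma_vox=self.smoothing_sigma_vox,
            seed=seed,
        )


@dataclass(frozen=True)
class SplitSection:
    counts: dict = field(
        default_factory=lambda: {
            "train1": (6, 6),
            "train2": (9, 9),
            "test": (9, 9),
        }
    )


@dataclass(frozen=True)
class EncoderSection:
    crop_shape: tuple[int, int, int] = (24, 28, 24)
    n_blocks: int = 2
    base_channels: int = 4
    n_tail_convs: int = 2
    dense_input: str = "flatten"
    double_at_entry: bool = False

    def encoder_config(self, n_subjects: int) -> EncoderConfig:
        return EncoderConfig(
            input_shape=tuple(self.crop_shape),
            n_subjects=n_subjects,
            n_blocks=self.n_blocks,
            base_channels=self.base_channels,
            n_tail_convs=self.n_tail_convs,
            dense_input=self.dense_input,
            double_at_entry=self.double_at_entry,
        )


@dataclass(frozen=True)
class TrainSection:
    lr_schedule: tuple[tuple[float, int], ...] = ((1e-3, 250), (1e-4, 100))
    batch_size: int = 8
    eval_every: int = 50

    def train_config(self, seed: int) -> TrainConfig:
        return TrainConfig(
            lr_schedule=tuple((float(lr), int(n)) for lr, n in self.lr_schedule),
            batch_size=self.batch_size,
            seed=seed,
            eval_every=self.eval_every,
        )


@dataclass(frozen=True)
class BaselineSection:
    atlas_blocks: tuple[int, int, int] = (3, 3, 3)
    pca_components: int = 3


@dataclass(frozen=True)
class EvaluateSection:
    precision_k: int = 40
    eval_splits: tuple[str, ...] = ("train2", "test")
    logistic_c: float = 1.0
    ridge_alpha: float = 1.0


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/desk"
    simulate: SimulateSection = field(default_factory=SimulateSection)
    split: SplitSection = field(default_factory=SplitSection)
    encoder: EncoderSection = field(default_factory=EncoderSection)
    train: TrainSection = field(default_factory=TrainSection)
    baselines: BaselineSection = field(default_factory=BaselineSection)
    evaluate: EvaluateSection = field(default_factory=EvaluateSection)

    def to_dict(self) -> dict:
        return _plain(asdict(self))

    def content_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def validate(self) -> None:
        """Fail fast on settings that would only error mid-pipeline."""
        n_train1 = sum(self.split.counts["train1"])
        self.encoder.encoder_config(max(n_train1, 2))  # raises on bad grid
        self.simulate.sim_config(0)
        for name in ("train1", "train2", "test"):
            if name not in self.split.counts:
                raise ValueError(f"split.counts missing {name!r}")


_SECTIONS = {
    "simulate": SimulateSection,
    "split": SplitSection,
    "encoder": EncoderSection,
    "train": TrainSection,
    "baselines": BaselineSection,
    "evaluate": EvaluateSection,
}


def config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw)
    known = {"seed", "out_dir", *_SECTIONS}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs: dict = {}
    for key in ("seed", "out_dir"):
        if key in raw:
            kwargs[key] = raw[key]
    for name, cls in _SECTIONS.items():
        if name in raw:
            section = dict(raw[name])
            for f in fields(cls):  # YAML lists -> tuples for frozen configs
                if f.name in section and isinstance(section[f.name], list):
                    val = section[f.name]
                    if val and isinstance(val[0], list):
                        val = tuple(tuple(v) for v in val)
                    else:
                        val = tuple(val)
                    section[f.name] = val
            if name == "split" and "counts" in section:
                section["counts"] = {
                    k: tuple(v) for k, v in section["counts"].items()
                }
            kwargs[name] = _from_dict(cls, section, f"config section {name!r}")
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config_from_dict(raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def desk_config(seed: int = 0, out_dir: str = "runs/desk") -> RunConfig:
    """The bundled desk-scale demo configuration (defaults of each section)."""
    return RunConfig(seed=seed, out_dir=out_dir)
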