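"""Pipeline configuration: every stage's parameters in one nested,
YAML-round-trippable structure with `reference` (full-scale) and `desk`
(single-CPU, minutes-scale) presets."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class SynthSection:
    n_syllable_types: int = 3
    n_songs: int = 8
    song_duration_s: float = 5.0
    snr_db: float = 30.0


@dataclass
class ModelSection:
    conv_channels: list = field(default_factory=lambda: [32, 64, 64, 64])
    d_model: int = 196
    n_heads: int = 4
    ffn_dim: int = 768
    n_blocks: int = 4
    context: int = 1000
    relpos_clip: int = 512
    latent_block: int = 3


@dataclass
class TrainSection:
    learning_rate: float = 3e-4
    batch_size: int = 42
    val_interval: int = 500
    max_steps: int = 26_500
    patience: int = 8
    train_fraction: float = 0.8
    max_shift: int = 50


@dataclass
class ClusterSection:
    latent_tap: str = "block3.attn"
    n_neighbors: int = 200
    min_dist: float = 0.1
    umap_seed: int = 42
    min_cluster_size: int = 5_000
    min_samples: int = 1
    smoothing_window: int = 200
    latent_cap: int = 1_000_000


@dataclass
class ProbeSection:
    learning_rate: float = 1e-2
    batch_size: int = 42
    eval_interval: int = 25
    patience: int = 6
    max_batches: int = 5_000


@dataclass
class SeasonalSection:
    bins: int = 300
    turnover: float = 0.5


@dataclass
class PipelineConfig:
    seed: int = 0
    scale: str = "reference"
    synth: SynthSection = field(default_factory=SynthSection)
    model: ModelSection = field(default_factory=ModelSection)
    train: TrainSection = field(default_factory=TrainSection)
    cluster: ClusterSection = field(default_factory=ClusterSection)
    probe: ProbeSection = field(default_factory=ProbeSection)
    seasonal: SeasonalSection = field(default_factory=SeasonalSection)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        section_types = {f.name: f.type for f in fields(cls)}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for f in fields(cls):
            if f.name not in data:
                continue
            v = data[f.name]
            if isinstance(v, dict):
                section_cls = f.default_factory().__class__
                bad = set(v) - {sf.name for sf in fields(section_cls)}
                if bad:
                    raise ValueError(
                        f"unknown keys in [{f.name}]: {sorted(bad)}")
                kwargs[f.name] = section_cls(**v)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text) or {})


def desk_preset(seed: int = 0) -> PipelineConfig:
    """Tiny configuration that exercises the whole pipeline on one CPU."""
    return PipelineConfig(
        seed=seed, scale="desk",
        synth=SynthSection(n_syllable_types=3, n_songs=8,
                           song_duration_s=5.0),
        model=ModelSection(conv_channels=[4, 8, 8, 8], d_model=64,
                           n_heads=4, ffn_dim=128, n_blocks=2, context=250,
                           relpos_clip=256, latent_block=2),
        train=TrainSection(learning_rate=1e-3, batch_size=4,
                           val_interval=50, max_steps=1_000, patience=8,
                           max_shift=10),
        cluster=ClusterSection(latent_tap="final_ln", n_neighbors=15,
                               min_cluster_size=50, smoothing_window=300,
                               latent_cap=100_000),
        probe=ProbeSection(),
        seasonal=SeasonalSection(bins=50),
    )


def reference_preset(seed: int = 0) -> PipelineConfig:
    """Full-scale configuration with every reference constant as default."""
    return PipelineConfig(seed=seed, scale="reference")
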