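"""Run configuration: nested parameter blocks with defaults and YAML loading.

Every default equals the method's reference value where one exists
(resampling target 1 mm, percentile ranks 2/98, flip probability 0.5,
contrast interval [0.75, 1.25), shift s.d. 0.25, batch size 2, validation
interval 500, tumor-patch fraction 0.9, halving schedule
16@5k/8@10k/4@20k/2@40k/1@80k, threshold 0.5, kernels 7x7 and 3x3,
score weight alpha 0.1, correspondence Dice threshold 0.2). Unknown keys in
a YAML file are rejected to catch typos.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Any

import yaml

log = logging.getLogger("hepaseg")


@dataclass
class PreprocessConfig:
    target_mm: float = 1.0          # in-plane resampling target
    low_rank: float = 2.0           # percentile ranks measured in the liver
    high_rank: float = 98.0

    def __post_init__(self) -> None:
        if self.target_mm <= 0:
            raise ValueError("target_mm must be positive")
        if not (0 < self.low_rank < self.high_rank < 100):
            raise ValueError("percentile ranks must satisfy 0 < low < high < 100")


@dataclass
class AugmentConfig:
    flip_prob: float = 0.5
    contrast_low: float = 0.75      # contrast factor a ~ U[contrast_low, contrast_high)
    contrast_high: float = 1.25
    shift_std: float = 0.25         # additive shift b ~ N(0, shift_std)
    enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")
        if not self.contrast_low < self.contrast_high:
            raise ValueError("contrast interval must have lower < upper")
        if self.shift_std < 0:
            raise ValueError("shift_std must be non-negative")


@dataclass
class NetworkConfig:
    """Architecture of the anisotropic U-Net.

    ``zconv_levels`` are 1-based resolution levels (1 = full resolution) whose
    blocks carry through-plane 1x1x3 convolutions; the default is the three
    lowest-resolution levels of a five-level net. ``zconvs_per_conv`` is the
    number of consecutive 1x1x3 convolutions appended after each in-plane
    3x3x1 convolution at those levels; the default of 2 makes the default
    geometry consume 20 slices of margin per side (72 -> 32 in z).
    """

    levels: int = 5
    base_features: int = 32
    max_features: int = 512
    features_override: tuple[int, ...] | None = None  # explicit per-level widths
    dropout: float = 0.1
    zconv_levels: tuple[int, ...] | None = None   # default: three lowest levels
    zconvs_per_conv: int = 2

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least two resolution levels")
        if self.base_features < 1 or self.max_features < self.base_features:
            raise ValueError("invalid feature counts")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.zconv_levels is None:
            lo = max(1, self.levels - 2)
            self.zconv_levels = tuple(range(lo, self.levels + 1))
        else:
            self.zconv_levels = tuple(int(v) for v in self.zconv_levels)
            if any(not 1 <= v <= self.levels for v in self.zconv_levels):
                raise ValueError("zconv_levels outside the level range")
        if self.zconvs_per_conv < 0:
            raise ValueError("zconvs_per_conv must be >= 0")
        if self.features_override is not None:
            self.features_override = tuple(int(v) for v in self.features_override)
            if len(self.features_override) != self.levels:
                raise ValueError("features_override must list one width per level")
            if any(v < 1 for v in self.features_override):
                raise ValueError("feature counts must be positive")

    def features(self, level: int) -> int:
        """Feature count at a 1-based resolution level (doubling, capped)."""
        if self.features_override is not None:
            return self.features_override[level - 1]
        return min(self.base_features * 2 ** (level - 1), self.max_features)


@dataclass
class TrainConfig:
    batch_size: int = 2
    learning_rate: float = 1e-4
    total_iterations: int = 80_000
    val_interval: int = 500
    tumor_fraction: float = 0.9     # fraction of patches required to contain tumor
    liver_dilate_inplane: int = 5   # loss-mask dilation radius (voxels, per slice)
    liver_dilate_z: int = 1         # extra slices of dilation
    dice_smooth: float = 1.0
    input_patch: tuple[int, int, int] = (236, 236, 72)

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must be in [0, 1]")
        if self.val_interval < 1:
            raise ValueError("val_interval must be >= 1")
        self.input_patch = tuple(int(v) for v in self.input_patch)


@dataclass
class ScheduleConfig:
    # (surviving runs, cumulative iteration milestone) per stage
    stages: tuple[tuple[int, int], ...] = (
        (16, 5_000), (8, 10_000), (4, 20_000), (2, 40_000), (1, 80_000))

    def __post_init__(self) -> None:
        self.stages = tuple((int(n), int(m)) for n, m in self.stages)


@dataclass
class PostprocessConfig:
    threshold: float = 0.5
    erosion_kernel: int = 7         # per-slice square, liver border extraction
    opening_kernel: int = 3         # per-slice square, thin-structure removal

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        for k in (self.erosion_kernel, self.opening_kernel):
            if k < 1 or k % 2 == 0:
                raise ValueError("kernel extents must be odd and >= 1")


@dataclass
class ScoreConfig:
    alpha: float = 0.1              # weight of the uncertainty-aware score
    dice_threshold: float = 0.2     # per-correspondence Dice acceptance level
    significance: float = 0.05      # Wilcoxon signed-rank level
    fdr: float = 0.05               # Benjamini-Hochberg false discovery rate

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0.0 < self.dice_threshold < 1.0:
            raise ValueError("dice_threshold must be in (0, 1)")


@dataclass
class RunConfig:
    """Top-level configuration for a full pipeline run."""

    cases_dir: str | None = None
    val_cases_dir: str | None = None
    output_dir: str | None = None
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    evaluate: ScoreConfig = field(default_factory=ScoreConfig)


_BLOCKS = {f.name: f for f in dataclasses.fields(RunConfig)}


def _build(cls: type, values: dict[str, Any], where: str) -> Any:
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(values) - set(known)
    if unknown:
        raise KeyError(f"unknown configuration key(s) {sorted(unknown)} in '{where}'")
    return cls(**values)


def config_from_dict(d: dict[str, Any]) -> RunConfig:
    """Resolve a (possibly partial) nested dict into a full RunConfig.

    Absent keys fall back to defaults; unknown keys raise ``KeyError`` naming
    the key. Resolution is deterministic and independent of key order.
    """
    unknown = set(d) - set(_BLOCKS)
    if unknown:
        raise KeyError(f"unknown configuration key(s) {sorted(unknown)} at top level")
    kwargs: dict[str, Any] = {}
    for name, f in _BLOCKS.items():
        if name not in d:
            continue
        value = d[name]
        if dataclasses.is_dataclass(f.type) or name in (
            "preprocess", "augment", "network", "train",
            "schedule", "postprocess", "evaluate",
        ):
            if not isinstance(value, dict):
                raise TypeError(f"config block '{name}' must be a mapping")
            cls = type(getattr(RunConfig(), name))
            kwargs[name] = _build(cls, value, name)
        else:
            kwargs[name] = value
    return RunConfig(**kwargs)


def load_config(path: str) -> RunConfig:
    """Load a YAML run configuration, filling defaults for absent keys.

    The fully resolved configuration is echoed to the package logger so that
    every run records the exact parameters it used.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise TypeError(f"{path}: top level of the config must be a mapping")
    cfg = config_from_dict(raw)
    log.info("resolved configuration: %s", dataclasses.asdict(cfg))
    return cfg
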