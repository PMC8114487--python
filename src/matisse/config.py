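"""Run configuration.

One structured config object carries every tunable parameter of the
pipeline, grouped per stage.  Defaults reflect the published protocol
where it states a value (IMC pitch 1 um/px, IOU recall thresholds
0.5..1.0 step 0.05, 20% overlap rule for split events, 10 um density
radius) and this package's own documented choices elsewhere.

Config files are YAML; unknown keys are rejected by name so that typos
("raduis") fail loudly instead of silently running with defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = [
    "RegistrationParams",
    "ClassificationParams",
    "SegmentationParams",
    "ScoreConfig",
    "QuantConfig",
    "RunConfig",
    "load_config",
    "save_config",
]


@dataclass
class RegistrationParams:
    n_pyramid_levels: int = 4
    max_points: int = 500
    descriptor_size: int = 8          # 8x8 patch -> length-64 descriptor
    ratio_threshold: float = 0.8      # Lowe-style nearest/second-nearest cutoff
    outlier_reject_px: float = 3.0    # residual cap (IMC px) under global similarity
    mls_alpha: float = 1.0

    def validate(self) -> None:
        if self.n_pyramid_levels < 1:
            raise ValueError("n_pyramid_levels must be >= 1")
        if self.max_points < 1:
            raise ValueError("max_points must be >= 1")
        if not (0 < self.ratio_threshold <= 1):
            raise ValueError("ratio_threshold must be in (0, 1]")
        if self.outlier_reject_px <= 0:
            raise ValueError("outlier_reject_px must be positive")
        if self.mls_alpha <= 0:
            raise ValueError("mls_alpha must be positive")


@dataclass
class ClassificationParams:
    n_trees: int = 100
    imc_sigmas: list[float] = field(default_factory=lambda: [0.3, 0.7, 1.0, 1.6])
    if_post_smoothing_sigma: float = 1.0
    imc_scale_percentiles: tuple[float, float] = (0.1, 99.9)

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if any(s <= 0 for s in self.imc_sigmas):
            raise ValueError("imc_sigmas must be positive")
        if self.if_post_smoothing_sigma < 0:
            raise ValueError("if_post_smoothing_sigma must be >= 0")


@dataclass
class SegmentationParams:
    nucleus_prob_threshold: float = 0.35
    min_nucleus_area_um2: float = 2.0
    declump: str = "intensity-valley"  # seeds from probability maxima
    smoothing_sigma_um: float = 0.5
    maxima_suppression_um: float = 2.5  # min distance between declump seeds
    max_expansion_um: float = 5.0

    def validate(self) -> None:
        if not (0 < self.nucleus_prob_threshold < 1):
            raise ValueError("nucleus_prob_threshold must be in (0, 1)")
        if self.min_nucleus_area_um2 <= 0:
            raise ValueError("min_nucleus_area_um2 must be positive")
        if self.declump not in ("shape", "intensity-valley"):
            raise ValueError(f"unknown declump method {self.declump!r}")
        if self.smoothing_sigma_um < 0:
            raise ValueError("smoothing_sigma_um must be >= 0")
        if self.maxima_suppression_um <= 0:
            raise ValueError("maxima_suppression_um must be positive")
        if self.max_expansion_um <= 0:
            raise ValueError("max_expansion_um must be positive")


@dataclass
class ScoreConfig:
    iou_thresholds: list[float] = field(
        default_factory=lambda: [round(t, 2) for t in np.arange(0.5, 1.0 + 1e-9, 0.05)]
    )
    overlap_fraction: float = 0.2
    edge_score_definition: str = "gt_interior"  # or "gt_area" / "boundary_length"

    def validate(self) -> None:
        t = np.asarray(self.iou_thresholds, dtype=float)
        if t.size == 0 or np.any(t < 0) or np.any(t > 1) or np.any(np.diff(t) <= 0):
            raise ValueError("iou_thresholds must be strictly increasing within [0, 1]")
        if not (0 < self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in (0, 1)")
        if self.edge_score_definition not in ("gt_interior", "gt_area", "boundary_length"):
            raise ValueError(
                f"unknown edge_score_definition {self.edge_score_definition!r}"
            )


@dataclass
class QuantConfig:
    density_radius_um: float = 10.0
    transform: str = "log1p"

    def validate(self) -> None:
        if self.density_radius_um <= 0:
            raise ValueError(
                f"density_radius_um must be positive, got {self.density_radius_um}"
            )
        if self.transform != "log1p":
            raise ValueError("only the log1p export transform is supported")


@dataclass
class RunConfig:
    imc_pixel_size_um: float = 1.0
    if_pixel_size_um: float = 0.325   # 20x objective + listed camera; config, not constant
    random_seed: int = 0
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    classification: ClassificationParams = field(default_factory=ClassificationParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    scoring: ScoreConfig = field(default_factory=ScoreConfig)
    quantification: QuantConfig = field(default_factory=QuantConfig)

    def validate(self) -> None:
        if self.imc_pixel_size_um <= 0 or self.if_pixel_size_um <= 0:
            raise ValueError("pixel sizes must be positive")
        if self.if_pixel_size_um > self.imc_pixel_size_um:
            raise ValueError(
                "if_pixel_size_um must not exceed imc_pixel_size_um "
                "(fluorescence is the high-resolution modality)"
            )
        for block in (
            self.registration,
            self.classification,
            self.segmentation,
            self.scoring,
            self.quantification,
        ):
            block.validate()


_BLOCKS = {
    "registration": RegistrationParams,
    "classification": ClassificationParams,
    "segmentation": SegmentationParams,
    "scoring": ScoreConfig,
    "quantification": QuantConfig,
}


def _build(cls, data: dict[str, Any], context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config key(s) in {context}: {unknown}")
    kwargs = dict(data)
    if cls is ClassificationParams and "imc_scale_percentiles" in kwargs:
        kwargs["imc_scale_percentiles"] = tuple(kwargs["imc_scale_percentiles"])
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration, filling defaults for absent keys.

    ``path=None`` (or an empty file) yields the all-default configuration.
    Unknown keys raise; out-of-range values raise.
    """
    data: dict[str, Any] = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is not None:
            if not isinstance(raw, dict):
                raise ValueError(f"config file {path} must contain a mapping")
            data = raw

    top_known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - top_known)
    if unknown:
        raise ValueError(f"unknown config key(s): {unknown}")

    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in _BLOCKS:
            if not isinstance(value, dict):
                raise ValueError(f"config block {key!r} must be a mapping")
            kwargs[key] = _build(_BLOCKS[key], value, context=key)
        else:
            kwargs[key] = value
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    def as_plain(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: as_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (list, tuple)):
            return [as_plain(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    Path(path).write_text(yaml.safe_dump(as_plain(cfg), sort_keys=False))
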