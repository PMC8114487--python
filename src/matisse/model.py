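"""Core data model shared by every pipeline stage.

The pipeline's universal currency is the :class:`Raster`: a 2-D scalar
image plane tagged with its physical pixel size in micrometres per pixel.
Imaging mass cytometry (IMC) data lives at a fixed 1 um/px pitch; the
fluorescence nuclear channel is acquired at sub-micron pitch.  All spatial
conventions are fixed here once:

* pixel coordinates are 0-based ``(row, col)``, row 0 at the top;
* pixel centres sit at integer coordinates;
* physical position in um = index * pixel_size_um.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Raster",
    "ChannelStack",
    "LabelMap",
    "ProbabilityMap",
    "SparseAnnotation",
    "PanelEntry",
    "PanelConfig",
    "PANEL_ROLES",
]

PANEL_ROLES = ("nuclear", "membrane_cytoplasm", "lineage", "other")


@dataclass
class Raster:
    """A single 2-D image plane with physical pixel size.

    Parameters
    ----------
    values
        2-D array of finite scalars (any numeric dtype).
    pixel_size_um
        Edge length of one (square) pixel in micrometres; must be > 0.
    name
        Free-text identifier (channel or marker name).
    """

    values: np.ndarray
    pixel_size_um: float
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError(
                f"Raster values must be 2-D with at least one pixel, got shape {self.values.shape}"
            )
        if not np.issubdtype(self.values.dtype, np.number):
            raise ValueError(f"Raster values must be numeric, got dtype {self.values.dtype}")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(np.isfinite(self.values)):
            raise ValueError("Raster values must be finite")
        if not (float(self.pixel_size_um) > 0):
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        self.pixel_size_um = float(self.pixel_size_um)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def extent_um(self) -> tuple[float, float]:
        """Physical field size (height, width) in micrometres."""
        h, w = self.values.shape
        return h * self.pixel_size_um, w * self.pixel_size_um

    def astype(self, dtype) -> "Raster":
        return Raster(self.values.astype(dtype), self.pixel_size_um, self.name)


@dataclass
class ChannelStack:
    """An ordered set of congruent rasters (same grid, same pixel size)."""

    channels: list[Raster]
    channel_names: list[str]

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.channel_names):
            raise ValueError("channels and channel_names must have equal length")
        if len(set(self.channel_names)) != len(self.channel_names):
            dupes = sorted({n for n in self.channel_names if self.channel_names.count(n) > 1})
            raise ValueError(f"duplicate channel names: {dupes}")
        if self.channels:
            ref = self.channels[0]
            for ch, name in zip(self.channels, self.channel_names):
                if ch.shape != ref.shape:
                    raise ValueError(
                        f"channel {name!r} shape {ch.shape} does not match {ref.shape}"
                    )
                if ch.pixel_size_um != ref.pixel_size_um:
                    raise ValueError(
                        f"channel {name!r} pixel size {ch.pixel_size_um} does not match "
                        f"{ref.pixel_size_um}"
                    )

    def __len__(self) -> int:
        return len(self.channels)

    def __getitem__(self, name: str) -> Raster:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in stack; available: {self.channel_names}"
            ) from None
        return self.channels[idx]

    def __contains__(self, name: str) -> bool:
        return name in self.channel_names

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape

    @property
    def pixel_size_um(self) -> float:
        return self.channels[0].pixel_size_um

    def as_array(self) -> np.ndarray:
        """Stack channels into a (n_channels, H, W) float array."""
        return np.stack([c.values.astype(np.float64, copy=False) for c in self.channels])

    def subset(self, names: Sequence[str]) -> "ChannelStack":
        return ChannelStack([self[n] for n in names], list(names))


@dataclass
class LabelMap:
    """Non-negative integer raster; 0 is background, each positive id one object.

    In memory labels are unconstrained integers; serialization to 16-bit
    TIFF enforces max label <= 65535 (see :func:`matisse.io.write_label_map`).
    """

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"labels must be 2-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"labels must be integer, got dtype {self.labels.dtype}")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if not (float(self.pixel_size_um) > 0):
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        self.pixel_size_um = float(self.pixel_size_um)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def n_objects(self) -> int:
        return int(np.unique(self.labels[self.labels > 0]).size)

    def label_ids(self) -> np.ndarray:
        return np.unique(self.labels[self.labels > 0])


@dataclass
class ProbabilityMap:
    """Per-class posterior rasters from a pixel classifier.

    Per pixel the class probabilities lie in [0, 1] and sum to 1 (within
    1e-6); the IMC classifier uses 5 classes, the fluorescence classifier 3.
    """

    class_probs: list[Raster]
    class_names: list[str]

    def __post_init__(self) -> None:
        if len(self.class_probs) != len(self.class_names):
            raise ValueError("class_probs and class_names must have equal length")
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class names must be unique")
        ref = self.class_probs[0]
        total = np.zeros(ref.shape, dtype=np.float64)
        for r, name in zip(self.class_probs, self.class_names):
            if r.shape != ref.shape or r.pixel_size_um != ref.pixel_size_um:
                raise ValueError(f"class {name!r} raster not congruent with the others")
            v = r.values
            if v.min() < -1e-6 or v.max() > 1 + 1e-6:
                raise ValueError(f"class {name!r} probabilities outside [0, 1]")
            total += v
        if np.abs(total - 1.0).max() > 1e-6:
            raise ValueError("per-pixel class probabilities must sum to 1 within 1e-6")

    def __getitem__(self, name: str) -> Raster:
        try:
            idx = self.class_names.index(name)
        except ValueError:
            raise KeyError(f"class {name!r} not present; have {self.class_names}") from None
        return self.class_probs[idx]

    @property
    def shape(self) -> tuple[int, int]:
        return self.class_probs[0].shape

    @property
    def pixel_size_um(self) -> float:
        return self.class_probs[0].pixel_size_um

    def as_array(self) -> np.ndarray:
        return np.stack([r.values.astype(np.float64, copy=False) for r in self.class_probs])


@dataclass
class SparseAnnotation:
    """Sparse scribble labels for classifier training.

    ``scribbles`` is congruent with the training image: 0 = unlabeled,
    value k (1-based) = class ``class_names[k-1]``.
    """

    scribbles: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.scribbles = np.asarray(self.scribbles)
        if self.scribbles.ndim != 2:
            raise ValueError("scribbles must be 2-D")
        if not np.issubdtype(self.scribbles.dtype, np.integer):
            raise ValueError("scribbles must be integer-valued")
        if self.scribbles.size and self.scribbles.max(initial=0) > len(self.class_names):
            raise ValueError(
                f"scribble value {int(self.scribbles.max())} exceeds number of classes "
                f"({len(self.class_names)})"
            )
        if self.scribbles.size and self.scribbles.min() < 0:
            raise ValueError("scribble values must be non-negative")

    def pixels_per_class(self) -> dict[str, int]:
        counts = np.bincount(self.scribbles.ravel(), minlength=len(self.class_names) + 1)
        return {name: int(counts[k + 1]) for k, name in enumerate(self.class_names)}


@dataclass
class PanelEntry:
    channel_name: str
    metal_tag: str = ""
    role: str = "other"
    use_for_training: bool = False
    use_for_clustering_export: bool = False

    def __post_init__(self) -> None:
        if self.role not in PANEL_ROLES:
            raise ValueError(f"unknown panel role {self.role!r}; valid roles: {PANEL_ROLES}")


@dataclass
class PanelConfig:
    """Maps IMC channels to marker roles and pipeline usage flags."""

    entries: list[PanelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.channel_name for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate panel channel names: {dupes}")

    def __getitem__(self, channel_name: str) -> PanelEntry:
        for e in self.entries:
            if e.channel_name == channel_name:
                return e
        raise KeyError(f"channel {channel_name!r} not in panel")

    def __contains__(self, channel_name: str) -> bool:
        return any(e.channel_name == channel_name for e in self.entries)

    def training_channels(self) -> list[str]:
        return [e.channel_name for e in self.entries if e.use_for_training]

    def clustering_channels(self) -> list[str]:
        return [e.channel_name for e in self.entries if e.use_for_clustering_export]
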