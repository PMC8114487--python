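"""TIFF / CSV input-output.

All file access in the pipeline goes through this module.  Rasters are
single-plane grayscale TIFFs (8/16/32-bit integer or 32-bit float); label
maps serialize as 16-bit unsigned TIFF, which caps the label range at
65535 on disk.  Pixel size is always supplied by the caller — resolution
tags in TIFFs exported by IMC converters are unreliable and are ignored.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .model import ChannelStack, LabelMap, PanelConfig, PanelEntry, Raster

__all__ = [
    "read_raster",
    "write_raster",
    "read_stack",
    "read_label_map",
    "write_label_map",
    "read_panel",
    "write_panel",
]


def _load_single_plane(path: str | os.PathLike) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        axes = series.axes
        data = series.asarray()
    if data.ndim != 2:
        # Name the offending axis so the user can fix the export.
        bad = next((ax for ax, n in zip(axes, data.shape) if ax not in "YX" and n > 1), axes[0])
        raise ValueError(
            f"{path}: expected a single-plane grayscale TIFF, got axes {axes!r} with shape "
            f"{data.shape} (offending axis {bad!r}); split planes/samples before loading"
        )
    return data


def read_raster(path: str | os.PathLike, pixel_size_um: float, name: str = "") -> Raster:
    """Read a single-plane grayscale TIFF as a :class:`Raster`.

    Integer planes (8/16/32-bit) and 32-bit float planes are preserved
    bit-exactly.  ``pixel_size_um`` is attached from the argument; TIFF
    resolution metadata is not trusted.
    """
    data = _load_single_plane(path)
    return Raster(data, pixel_size_um, name or Path(path).stem)


def write_raster(raster: Raster, path: str | os.PathLike) -> None:
    """Write a raster as an uncompressed single-plane TIFF (dtype preserved)."""
    tifffile.imwrite(Path(path), np.ascontiguousarray(raster.values))


def read_stack(
    paths: Sequence[str | os.PathLike],
    channel_names: Sequence[str],
    pixel_size_um: float,
) -> ChannelStack:
    """Read one single-plane TIFF per channel into a :class:`ChannelStack`.

    Channel order follows ``channel_names``; all planes must be congruent.
    """
    if len(paths) != len(channel_names):
        raise ValueError("paths and channel_names must have equal length")
    channels = [read_raster(p, pixel_size_um, name=n) for p, n in zip(paths, channel_names)]
    return ChannelStack(channels, list(channel_names))


def read_label_map(path: str | os.PathLike, pixel_size_um: float) -> LabelMap:
    data = _load_single_plane(path)
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(f"{path}: label maps must be integer TIFFs, got dtype {data.dtype}")
    return LabelMap(data.astype(np.int64), pixel_size_um)


def write_label_map(label_map: LabelMap, path: str | os.PathLike) -> None:
    """Write a label map as 16-bit unsigned single-plane TIFF.

    Raises on label overflow: a map with more than 65535 objects must be
    relabeled (e.g. tiled or renumbered) before writing.
    """
    max_label = int(label_map.labels.max(initial=0))
    if max_label > np.iinfo(np.uint16).max:
        raise OverflowError(
            f"max label {max_label} exceeds the 16-bit TIFF range (65535); "
            "relabel objects to a dense 1..N numbering before writing"
        )
    tifffile.imwrite(Path(path), np.ascontiguousarray(label_map.labels.astype(np.uint16)))


_PANEL_COLUMNS = [
    "channel_name",
    "metal_tag",
    "role",
    "use_for_training",
    "use_for_clustering_export",
]


def read_panel(path: str | os.PathLike) -> PanelConfig:
    """Read a panel table (CSV with channel_name, metal_tag, role, flags)."""
    df = pd.read_csv(path)
    missing = [c for c in ("channel_name",) if c not in df.columns]
    if missing:
        raise ValueError(f"panel file {path} lacks required columns: {missing}")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            PanelEntry(
                channel_name=str(row["channel_name"]),
                metal_tag=str(row.get("metal_tag", "") or ""),
                role=str(row.get("role", "other") or "other"),
                use_for_training=bool(row.get("use_for_training", False)),
                use_for_clustering_export=bool(row.get("use_for_clustering_export", False)),
            )
        )
    return PanelConfig(entries)


def write_panel(panel: PanelConfig, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "channel_name": e.channel_name,
                "metal_tag": e.metal_tag,
                "role": e.role,
                "use_for_training": e.use_for_training,
                "use_for_clustering_export": e.use_for_clustering_export,
            }
            for e in panel.entries
        ],
        columns=_PANEL_COLUMNS,
    )
    df.to_csv(path, index=False)
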