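"""Per-cell data extraction, local density, line profiles and export.

Mean marker intensities are taken from the *unscaled* channel values
over each cell's pixels; the scaled copies used for classifier training
never enter quantification.  Density is the number of other cells whose
centroid lies within a fixed radius (default 10 um, closed ball).  The
clustering export applies log1p to the mean intensities of the panel's
flagged channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .config import QuantConfig
from .model import ChannelStack, LabelMap, PanelConfig, Raster

__all__ = [
    "CellRecord",
    "extract_cell_table",
    "compute_density",
    "line_profile",
    "export_clustering_table",
    "records_to_frame",
]


@dataclass
class CellRecord:
    cell_label: int
    centroid_um: tuple[float, float]       # (y, x)
    area_um2: float
    mean_intensity: dict[str, float] = field(default_factory=dict)
    n_neighbors_10um: int | None = None
    group: object | None = None


def extract_cell_table(
    cells_label_map: LabelMap, channel_stack: ChannelStack
) -> list[CellRecord]:
    """One record per cell: pixel-centroid, area and per-channel mean of the
    unscaled values over the cell's pixels."""
    if cells_label_map.shape != channel_stack.shape:
        raise ValueError(
            f"label map {cells_label_map.shape} and stack {channel_stack.shape} not congruent"
        )
    if abs(cells_label_map.pixel_size_um - channel_stack.pixel_size_um) > 1e-9:
        raise ValueError("label map and stack pixel sizes differ")
    lab = cells_label_map.labels
    ids = cells_label_map.label_ids()
    if ids.size == 0:
        return []
    px = cells_label_map.pixel_size_um
    counts = np.bincount(lab.ravel(), minlength=int(ids.max()) + 1)
    cy, cx = np.mgrid[0 : lab.shape[0], 0 : lab.shape[1]]
    sum_y = np.bincount(lab.ravel(), weights=cy.ravel(), minlength=counts.size)
    sum_x = np.bincount(lab.ravel(), weights=cx.ravel(), minlength=counts.size)
    means = {
        name: ndimage.mean(raster.values.astype(np.float64), labels=lab, index=ids)
        for name, raster in zip(channel_stack.channel_names, channel_stack.channels)
    }
    records = []
    for k, i in enumerate(ids):
        i = int(i)
        n = counts[i]
        records.append(
            CellRecord(
                cell_label=i,
                centroid_um=(float(sum_y[i] / n * px), float(sum_x[i] / n * px)),
                area_um2=float(n * px * px),
                mean_intensity={name: float(means[name][k]) for name in means},
            )
        )
    return records


def compute_density(
    records: Sequence[CellRecord], quant_config: QuantConfig | None = None
) -> list[CellRecord]:
    """Count, for each cell, the other cells with centroid distance <= the
    density radius (self excluded; boundary included).  Fills
    ``n_neighbors_10um`` in place and returns the records."""
    cfg = quant_config or QuantConfig()
    cfg.validate()
    pts = np.asarray([r.centroid_um for r in records], dtype=float)
    if pts.shape[0] == 0:
        return list(records)
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, r=cfg.density_radius_um, return_length=True)
    for r, c in zip(records, counts):
        r.n_neighbors_10um = int(c) - 1  # query includes the cell itself
    return list(records)


def line_profile(
    rasters: Sequence[Raster],
    polyline_um: np.ndarray,
    normalize_per_line: bool = True,
) -> dict[str, np.ndarray]:
    """Sample each raster along a polyline given in physical um coordinates.

    Sampling is bilinear at one sample per source pixel along the line, so
    rasters of different pitch are compared on their own native density.
    With normalisation each series is min-max scaled to [0, 1].
    """
    pts = np.atleast_2d(np.asarray(polyline_um, dtype=float))
    if pts.shape[0] < 2:
        raise ValueError("polyline needs at least two vertices")
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    total = float(seg_len.sum())
    if total <= 0:
        raise ValueError("degenerate (zero-length) line")
    cum = np.r_[0.0, np.cumsum(seg_len)]

    out: dict[str, np.ndarray] = {}
    for raster in rasters:
        step = raster.pixel_size_um
        n = max(2, int(np.floor(total / step)) + 1)
        s = np.linspace(0.0, total, n)
        # arc length -> (y, x) in um
        idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
        frac = (s - cum[idx]) / np.where(seg_len[idx] > 0, seg_len[idx], 1.0)
        pos = pts[idx] + seg[idx] * frac[:, None]
        coords = (pos / raster.pixel_size_um).T  # (2, n) in pixel units
        vals = ndimage.map_coordinates(
            np.asarray(raster.values, dtype=np.float64), coords, order=1, mode="nearest"
        )
        if normalize_per_line:
            lo, hi = vals.min(), vals.max()
            vals = (vals - lo) / (hi - lo) if hi > lo else np.zeros_like(vals)
        out[raster.name or f"raster_{len(out)}"] = vals
    return out


def records_to_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "cell_label": r.cell_label,
            "centroid_y_um": r.centroid_um[0],
            "centroid_x_um": r.centroid_um[1],
            "area_um2": r.area_um2,
            "n_neighbors_10um": r.n_neighbors_10um,
            "group": r.group,
        }
        row.update({f"mean_{k}": v for k, v in r.mean_intensity.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def export_clustering_table(
    records: Sequence[CellRecord],
    panel_config: PanelConfig,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Clustering-ready table: id, centroid, area, density and log1p of the
    mean intensity for the panel's clustering-flagged channels only."""
    channels = panel_config.clustering_channels()
    if records:
        have = set(records[0].mean_intensity)
        missing = [c for c in channels if c not in have]
        if missing:
            raise ValueError(f"clustering channel(s) absent from cell records: {missing}")
    rows = []
    for r in records:
        row = {
            "cell_label": r.cell_label,
            "centroid_y_um": r.centroid_um[0],
            "centroid_x_um": r.centroid_um[1],
            "area_um2": r.area_um2,
            "n_neighbors_10um": r.n_neighbors_10um,
        }
        for c in channels:
            row[c] = float(np.log1p(r.mean_intensity[c]))
        rows.append(row)
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
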