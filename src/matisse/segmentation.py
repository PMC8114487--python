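"""Nucleus detection and cell expansion (primary/secondary objects).

Cells are found in two stages: individual nuclei first, then outward
expansion of each nucleus to the full cell extent by a seeded watershed
on the IMC membrane probability.  Two pipelines share this machinery:

* **dual-modality ("matisse")** — nuclei detected on the high-resolution
  fluorescence nuclear probability map, downscaled to the IMC grid by
  per-pixel majority vote, then expanded on the IMC membrane class;
* **imc-only** — nuclei detected directly on the (reduced) IMC nuclear
  probability at 1 um pitch, then expanded the same way.

Labels are always renumbered 1..N in raster-scan order of each object's
first pixel so outputs are comparable across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import local_maxima
from skimage.segmentation import watershed

from .config import SegmentationParams
from .model import LabelMap, ProbabilityMap, Raster
from .pixel_classification import imc_class_reduce
from .registration import MLSTransform, warp_raster

__all__ = [
    "detect_nuclei",
    "downscale_labels",
    "expand_cells",
    "run_matisse",
    "run_imc_only",
    "relabel_sequential_raster_order",
]

log = logging.getLogger(__name__)


def relabel_sequential_raster_order(labels: np.ndarray) -> np.ndarray:
    """Renumber positive labels 1..N by raster-scan order of first pixel."""
    flat = labels.ravel()
    uniq, first = np.unique(flat, return_index=True)
    pos = uniq > 0
    uniq, first = uniq[pos], first[pos]
    order = np.argsort(first, kind="stable")
    mapping = np.zeros(int(uniq.max()) + 1 if uniq.size else 1, dtype=labels.dtype)
    mapping[uniq[order]] = np.arange(1, uniq.size + 1, dtype=labels.dtype)
    return mapping[labels]


def detect_nuclei(nuclear_prob: Raster, params: SegmentationParams | None = None) -> LabelMap:
    """Detect individual nuclei from a nuclear probability raster.

    Smooth -> threshold -> fill holes -> seeded watershed declumping
    (regional-maximum plateau seeds thinned by a maxima-suppression
    distance) -> drop objects below the minimum area.  An empty label map
    is a valid result.
    """
    params = params or SegmentationParams()
    params.validate()
    prob = np.asarray(nuclear_prob.values, dtype=np.float64)
    if params.smoothing_sigma_um > 0:
        # physical smoothing so both resolutions see the same scale
        prob = ndimage.gaussian_filter(
            prob, params.smoothing_sigma_um / nuclear_prob.pixel_size_um
        )
    mask = prob > params.nucleus_prob_threshold
    if not mask.any():
        return LabelMap(np.zeros(prob.shape, dtype=np.int32), nuclear_prob.pixel_size_um)
    mask = ndimage.binary_fill_holes(mask)

    if params.declump == "shape":
        # distance in um so declumping strength is resolution-independent;
        # smoothing the distance map suppresses spurious ridge maxima from
        # boundary wiggles (CellProfiler does the same before seeding)
        topo = ndimage.distance_transform_edt(mask, sampling=nuclear_prob.pixel_size_um)
        topo = ndimage.gaussian_filter(topo, 1.0 / nuclear_prob.pixel_size_um)
    else:  # intensity-valley: flood from probability maxima
        topo = np.where(mask, prob, 0.0)
    # declump seeds: regional-maximum plateaus (a flat plateau is one seed,
    # not a field of tied peaks), greedily suppressed so surviving seeds sit
    # at least maxima_suppression_um apart — CellProfiler's
    # maxima-suppression-distance semantics
    sup_px = params.maxima_suppression_um / nuclear_prob.pixel_size_um
    plateaus = local_maxima(topo, connectivity=2) & mask
    pcomp, n_plateaus = ndimage.label(plateaus, structure=np.ones((3, 3)))
    peaks = np.zeros(mask.shape, dtype=bool)
    if n_plateaus:
        idx = np.arange(1, n_plateaus + 1)
        cents = np.asarray(ndimage.center_of_mass(plateaus, pcomp, idx))
        heights = ndimage.maximum(topo, pcomp, idx)
        order = np.lexsort((cents[:, 1], cents[:, 0], -heights))
        accepted: list[int] = []
        for j in order:
            if accepted:
                d2 = np.sum((cents[accepted] - cents[j]) ** 2, axis=1)
                if d2.min() < sup_px**2:
                    continue
            accepted.append(j)
        keep = np.zeros(n_plateaus + 1, dtype=bool)
        keep[idx[accepted]] = True
        peaks = keep[pcomp]
    # every connected mask component keeps at least one seed: suppression
    # must declump, never delete, small objects
    comps, n_comps = ndimage.label(mask)
    seeded = np.unique(comps[peaks])
    unseeded = np.setdiff1d(np.arange(1, n_comps + 1), seeded)
    if unseeded.size:
        pos = ndimage.maximum_position(topo, labels=comps, index=unseeded)
        for r, c in np.atleast_2d(pos):
            peaks[int(r), int(c)] = True
    markers, n_seeds = ndimage.label(peaks)
    labels = watershed(-topo, markers=markers, mask=mask)

    # minimum object area in target-grid pixels (at least one pixel)
    px_area = nuclear_prob.pixel_size_um**2
    min_px = max(1, int(np.ceil(params.min_nucleus_area_um2 / px_area)))
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_px)
    if small.size:
        kill = np.isin(labels, small[small > 0])
        labels = np.where(kill, 0, labels)
    return LabelMap(
        relabel_sequential_raster_order(labels.astype(np.int32)),
        nuclear_prob.pixel_size_um,
    )


def _axis_coverage(n_src: int, src_pitch: float, n_tgt: int, tgt_pitch: float):
    """Per source index along one axis: the (at most two) covered target
    indices and the length of overlap with each, in source-pitch units.

    Pixel centres sit at integer coordinates (position_um = index * pitch),
    so pixel i spans [i*p - p/2, i*p + p/2); source and target grids share
    the physical origin.
    """
    lo_um = np.arange(n_src) * src_pitch - src_pitch / 2
    hi_um = lo_um + src_pitch
    t0 = np.floor(lo_um / tgt_pitch + 0.5 + 1e-12).astype(np.int64)
    t1 = np.floor((hi_um - 1e-9) / tgt_pitch + 0.5).astype(np.int64)
    t0 = np.clip(t0, 0, n_tgt - 1)
    t1 = np.clip(t1, 0, n_tgt - 1)
    boundary = (t0 + 0.5) * tgt_pitch
    w0 = np.where(t1 > t0, np.minimum(boundary, hi_um) - lo_um, src_pitch)
    w1 = np.where(t1 > t0, hi_um - boundary, 0.0)
    return t0, w0 / src_pitch, t1, w1 / src_pitch


def _label_coverage(src: np.ndarray, sp: float, tp: float):
    """Area-weighted coverage of every (target pixel, label) pair.

    Returns (out_shape, tgt_of, lab_of, agg): flat target index, label id
    and total covered source area (in source-pixel units) per pair, sorted
    by (target, label)."""
    H, W = src.shape
    out_h = max(1, int(round(H * sp / tp)))
    out_w = max(1, int(round(W * sp / tp)))
    r0, wr0, r1, wr1 = _axis_coverage(H, sp, out_h, tp)
    c0, wc0, c1, wc1 = _axis_coverage(W, sp, out_w, tp)
    lab = src.astype(np.int64)
    n_lab = int(lab.max()) + 1
    tgt_keys = []
    weights = []
    for tr, wr in ((r0, wr0), (r1, wr1)):
        if not np.any(wr > 0):
            continue
        for tc, wc in ((c0, wc0), (c1, wc1)):
            w2 = wr[:, None] * wc[None, :]
            nz = w2 > 0
            if not nz.any():
                continue
            tflat = tr[:, None] * out_w + tc[None, :]
            key = np.broadcast_to(tflat, (H, W))[nz] * n_lab + lab[nz]
            tgt_keys.append(key)
            weights.append(w2[nz])
    keys = np.concatenate(tgt_keys)
    wts = np.concatenate(weights)
    uk, inv = np.unique(keys, return_inverse=True)
    agg = np.bincount(inv, weights=wts, minlength=uk.size)
    return (out_h, out_w), uk // n_lab, uk % n_lab, agg


def downscale_labels(high_res_labels: LabelMap, target_pixel_size_um: float) -> LabelMap:
    """Downscale a label map to a coarser grid by per-target-pixel majority.

    Each target pixel takes the label with the largest covered source area;
    background (0) competes like any label; ties break to the lowest label
    id.  Non-integer pitch ratios are handled by area-weighted coverage.
    Labels that vanish entirely are dropped (and logged).
    """
    sp = high_res_labels.pixel_size_um
    tp = float(target_pixel_size_um)
    if tp < sp - 1e-12:
        raise ValueError(f"target pitch {tp} must be >= source pitch {sp}")
    src = high_res_labels.labels
    (out_h, out_w), tgt_of, lab_of, agg = _label_coverage(src, sp, tp)

    # group per target pixel: pairs are sorted, so labels ascend per group
    starts = np.flatnonzero(np.r_[True, np.diff(tgt_of) > 0])
    ends = np.r_[starts[1:], tgt_of.size]
    out = np.zeros(out_h * out_w, dtype=np.int32)
    tol = 1e-9
    for s, e in zip(starts, ends):
        grp = agg[s:e]
        wmax = grp.max()
        # lowest label among (near-)tied maxima
        idx = s + int(np.argmax(grp >= wmax - tol))
        out[tgt_of[s]] = lab_of[idx]
    out = out.reshape(out_h, out_w)

    survivors = set(np.unique(out[out > 0]).tolist())
    original = set(np.unique(src[src > 0]).tolist())
    dropped = sorted(original - survivors)
    if dropped:
        log.warning("downscale_labels: %d label(s) vanished: %s", len(dropped), dropped[:20])
    return LabelMap(relabel_sequential_raster_order(out), tp)


def expand_cells(
    nuclei_labels: LabelMap,
    membrane_prob: Raster,
    params: SegmentationParams | None = None,
) -> LabelMap:
    """Expand nuclei to whole cells by seeded watershed on membrane probability.

    Flooding ascends the membrane probability from the nucleus seeds; growth
    is capped at ``max_expansion_um`` from the nearest seed.  Every cell
    contains its entire seed and the cell label set equals the nucleus label
    set; unreached pixels stay background.
    """
    params = params or SegmentationParams()
    if nuclei_labels.shape != membrane_prob.shape:
        raise ValueError(
            f"nuclei {nuclei_labels.shape} and membrane {membrane_prob.shape} shapes differ"
        )
    seeds = nuclei_labels.labels
    if not (seeds > 0).any():
        return LabelMap(np.zeros_like(seeds, dtype=np.int32), nuclei_labels.pixel_size_um)
    max_px = params.max_expansion_um / nuclei_labels.pixel_size_um
    dist = ndimage.distance_transform_edt(seeds == 0)
    allowed = dist <= max_px
    cells = watershed(
        np.asarray(membrane_prob.values, dtype=np.float64), markers=seeds, mask=allowed
    )
    return LabelMap(cells.astype(np.int32), nuclei_labels.pixel_size_um)


@dataclass
class SegmentationResult:
    nuclei: LabelMap        # at IMC pitch
    cells: LabelMap         # at IMC pitch
    nuclei_highres: LabelMap | None = None

    def __getitem__(self, key: str) -> LabelMap:
        return {"nuclei": self.nuclei, "cells": self.cells}[key]


def run_matisse(
    if_nuclear_prob_highres: Raster,
    imc_prob_5class: ProbabilityMap,
    transform: MLSTransform | None = None,
    params: SegmentationParams | None = None,
) -> SegmentationResult:
    """Dual-modality segmentation: high-resolution nuclei, IMC-grid cells.

    Nuclei are detected on the fluorescence nuclear probability at full
    resolution (warped into the IMC frame first if a transform is given),
    downscaled to the IMC pitch by majority vote, and expanded on the IMC
    membrane probability.
    """
    params = params or SegmentationParams()
    prob = if_nuclear_prob_highres
    if transform is not None:
        prob = warp_raster(
            prob, transform, imc_prob_5class.shape, imc_prob_5class.pixel_size_um,
            keep_moving_resolution=True,
        )
    nuclei_hr = detect_nuclei(prob, params)
    nuclei_imc = downscale_labels(nuclei_hr, imc_prob_5class.pixel_size_um)
    reduced = imc_class_reduce(imc_prob_5class)
    cells = expand_cells(nuclei_imc, reduced["membrane"], params)
    return SegmentationResult(nuclei=nuclei_imc, cells=cells, nuclei_highres=nuclei_hr)


def run_imc_only(
    imc_prob_5class: ProbabilityMap,
    params: SegmentationParams | None = None,
) -> SegmentationResult:
    """IMC-only segmentation: nuclei and cells both from the 1 um IMC maps.

    Shares the full parameter surface with the dual-modality path so the
    two pipelines differ only in the nuclear input resolution.
    """
    params = params or SegmentationParams()
    reduced = imc_class_reduce(imc_prob_5class)
    nuclei = detect_nuclei(reduced["nuclear"], params)
    cells = expand_cells(nuclei, reduced["membrane"], params)
    return SegmentationResult(nuclei=nuclei, cells=cells)
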