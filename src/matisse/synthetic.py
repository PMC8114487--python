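"""Synthetic dual-resolution tissue scenes with exact ground truth.

Each scene emulates the imaging model of the dual-modality experiment:
crowded elliptical nuclei visible in both modalities (DAPI at sub-micron
pitch, DNA intercalator at the fixed 1 um IMC pitch), membrane/cytoplasm
signal only in the IMC channels, a known similarity misalignment between
the fluorescence frame and the IMC frame, camera-style additive Gaussian
noise on the fluorescence image and ion-count (Poisson) noise on the IMC
channels.  Ground-truth nucleus and cell label maps are exact by
construction, which makes the scenes usable as oracles for registration,
classification, segmentation and scoring.

Conventions: the IMC grid is the world frame (position_um = index * 1 um);
the fluorescence grid is related to it by the scene spec's similarity
(world = scale * R(rotation) * if_position_um + translation_um).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
from scipy import ndimage
from skimage.segmentation import find_boundaries, watershed

from .model import ChannelStack, LabelMap, PanelConfig, PanelEntry, Raster, SparseAnnotation
from .pixel_classification import IF_CLASSES, IMC_CLASSES
from .registration import MatchSet, MLSTransform
from .scoring import boundary_pixels

__all__ = [
    "Misalignment",
    "NoiseSpec",
    "SceneSpec",
    "SimilarityGroundTruth",
    "Scene",
    "generate_scene",
    "generate_scribbles",
    "make_ground_truth_annotations",
    "scene_probability_maps",
    "scene_panel",
]


@dataclass
class Misalignment:
    scale: float = 1.0
    rotation_deg: float = 0.0
    translation_um: tuple[float, float] = (0.0, 0.0)  # (y, x)


@dataclass
class NoiseSpec:
    if_gaussian_sd: float = 0.03     # additive, relative to unit nuclear peak
    imc_poisson_scale: float = 6.0   # expected ion counts at unit signal


@dataclass
class SceneSpec:
    field_size_um: tuple[float, float] = (250.0, 250.0)
    n_nuclei: int = 300
    nucleus_radius_um: float = 2.6
    nucleus_radius_sd_um: float = 0.4
    min_center_spacing_um: float = 2.0
    crowding_profile: str = "crowded"  # sparse | crowded | epithelial-ribbon
    if_pixel_size_um: float = 0.25
    imc_pixel_size_um: float = 1.0
    misalignment: Misalignment = field(default_factory=Misalignment)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    n_membrane_channels: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_center_spacing_um < 0:
            raise ValueError("min_center_spacing_um must be >= 0")
        if self.if_pixel_size_um <= 0 or self.imc_pixel_size_um <= 0:
            raise ValueError("pixel pitches must be positive")
        if self.crowding_profile not in ("sparse", "crowded", "epithelial-ribbon"):
            raise ValueError(f"unknown crowding profile {self.crowding_profile!r}")


@dataclass
class SimilarityGroundTruth:
    """The exact similarity linking IF pixel coords to IMC pixel coords."""

    scale: float
    rotation_rad: float
    translation_um: tuple[float, float]
    if_pixel_size_um: float
    imc_pixel_size_um: float

    def _rot(self) -> np.ndarray:
        c, s = np.cos(self.rotation_rad), np.sin(self.rotation_rad)
        return np.array([[c, -s], [s, c]])

    def if_px_to_world_um(self, pts: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(pts, dtype=float)) * self.if_pixel_size_um
        return (self.scale * p @ self._rot().T) + np.asarray(self.translation_um)

    def world_um_to_if_px(self, pts: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(pts, dtype=float)) - np.asarray(self.translation_um)
        return (p @ self._rot()) / self.scale / self.if_pixel_size_um

    def if_px_to_imc_px(self, pts: np.ndarray) -> np.ndarray:
        return self.if_px_to_world_um(pts) / self.imc_pixel_size_um

    def as_mls(self, extent_if_px: tuple[float, float]) -> MLSTransform:
        """An MLS transform exactly equivalent to this similarity (controls
        on a 3x3 lattice all consistent with one similarity)."""
        h, w = extent_if_px
        rr, cc = np.meshgrid(np.linspace(0, h, 3), np.linspace(0, w, 3), indexing="ij")
        src = np.stack([rr.ravel(), cc.ravel()], axis=1)
        dst = self.if_px_to_imc_px(src)
        return MLSTransform(
            MatchSet(src, dst, np.zeros(len(src)),
                     self.if_pixel_size_um, self.imc_pixel_size_um)
        )


@dataclass
class Scene:
    if_nuclear: Raster
    imc_stack: ChannelStack
    gt_nuclei_highres: LabelMap          # IF frame, IF pitch
    gt_nuclei_imc: LabelMap              # world frame, IMC pitch
    gt_cells_imc: LabelMap               # world frame, IMC pitch
    true_transform: SimilarityGroundTruth
    epithelial_mask_imc: np.ndarray
    centers_um: np.ndarray               # (n, 2) world (y, x)
    radii_um: np.ndarray                 # (n, 2) ellipse semi-axes
    orientations_rad: np.ndarray
    spec: SceneSpec


def _ribbon_distance(y: np.ndarray, x: np.ndarray, field: tuple[float, float]) -> np.ndarray:
    """Distance (um) to a curved band through the field (a sine-wave
    mid-line), used for the epithelial-ribbon crowding profile."""
    h, w = field
    curve_y = h / 2 + 0.2 * h * np.sin(2 * np.pi * x / w * 1.5)
    return np.abs(y - curve_y)


def _place_centers(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.field_size_um
    margin = spec.nucleus_radius_um + spec.nucleus_radius_sd_um
    spacing2 = spec.min_center_spacing_um**2
    accepted: list[np.ndarray] = []
    max_attempts = 10 * spec.n_nuclei * 10
    attempts = 0
    ribbon = spec.crowding_profile == "epithelial-ribbon"
    clustered = spec.crowding_profile == "crowded"
    # crowded tissue is contiguous chains/clumps of touching nuclei, not a
    # uniform sprinkle: most nuclei attach next to an existing one
    n_dense = int(0.7 * spec.n_nuclei) if (ribbon or clustered) else 0
    step_lo = max(spec.min_center_spacing_um, 1e-6)
    while len(accepted) < spec.n_nuclei and attempts < max_attempts:
        attempts += 1
        k = len(accepted)
        if ribbon and k < n_dense:
            x = rng.uniform(margin, w - margin)
            yc = h / 2 + 0.2 * h * np.sin(2 * np.pi * x / w * 1.5)
            y = np.clip(yc + rng.normal(0, 3.0), margin, h - margin)
            cand = np.array([y, x])
        elif clustered and k < n_dense:
            # bounded clumps (~cluster_size nuclei) grown by local attachment,
            # like crypt cross-sections: dense inside, separated from others
            cluster_size = 12
            cluster_id = k // cluster_size
            base = cluster_id * cluster_size
            if k == base:  # new cluster seed
                cand = rng.uniform([margin, margin], [h - margin, w - margin])
            else:
                anchor = accepted[base + int(rng.integers(k - base))]
                ang = rng.uniform(0, 2 * np.pi)
                # neighbours sit one nucleus diameter + a thin (0.4-2.2 um)
                # cytoplasmic sliver apart: unresolvable at 1 um pitch
                lo = max(step_lo, 2 * spec.nucleus_radius_um + 0.4)
                d = rng.uniform(lo, lo + 1.8)
                cand = anchor + d * np.array([np.sin(ang), np.cos(ang)])
                if not (margin <= cand[0] <= h - margin and margin <= cand[1] <= w - margin):
                    continue
        else:
            cand = rng.uniform([margin, margin], [h - margin, w - margin])
        if accepted:
            d2 = np.sum((np.asarray(accepted) - cand) ** 2, axis=1)
            if d2.min() < spacing2:
                continue
        accepted.append(cand)
    if len(accepted) < spec.n_nuclei:
        raise RuntimeError(
            f"packing infeasible: placed {len(accepted)} of {spec.n_nuclei} nuclei at "
            f"spacing {spec.min_center_spacing_um} um in {spec.field_size_um} um"
        )
    return np.asarray(accepted)


def _render_labels_and_intensity(
    centers: np.ndarray,
    radii: np.ndarray,
    orients: np.ndarray,
    grid_world_fn,
    shape: tuple[int, int],
    bbox_px_fn,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise ellipses (nearest normalized-distance wins on overlap) on an
    arbitrary grid described by a pixel->world mapping."""
    labels = np.zeros(shape, dtype=np.int32)
    best = np.full(shape, np.inf)
    intensity = np.zeros(shape)
    for k in range(centers.shape[0]):
        (r0, r1), (c0, c1) = bbox_px_fn(k)
        if r1 <= r0 or c1 <= c0:
            continue
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        wpts = grid_world_fn(np.stack([rr.ravel(), cc.ravel()], axis=1))
        rel = wpts - centers[k]
        ct, st = np.cos(orients[k]), np.sin(orients[k])
        u = rel[:, 0] * ct + rel[:, 1] * st
        v = -rel[:, 0] * st + rel[:, 1] * ct
        d = (u / radii[k, 0]) ** 2 + (v / radii[k, 1]) ** 2
        d = d.reshape(rr.shape)
        inside = d <= 1.0
        win = inside & (d < best[r0:r1, c0:c1])
        sub_lab = labels[r0:r1, c0:c1]
        sub_best = best[r0:r1, c0:c1]
        sub_int = intensity[r0:r1, c0:c1]
        sub_lab[win] = k + 1
        sub_best[win] = d[win]
        sub_int[win] = 1.0 - 0.45 * d[win]  # brighter core, dimmer rim
    return labels, intensity


def generate_scene(spec: SceneSpec) -> Scene:
    """Generate a complete dual-resolution scene from a :class:`SceneSpec`.

    Same seed, same spec => byte-identical scene.  Raises when the
    requested packing is infeasible.
    """
    rng = np.random.default_rng(spec.seed)
    h_um, w_um = spec.field_size_um
    centers = _place_centers(spec, rng)
    n = centers.shape[0]
    base_r = np.clip(
        rng.normal(spec.nucleus_radius_um, spec.nucleus_radius_sd_um, size=n), 1.0, None
    )
    # nuclei pack without interpenetrating: each nucleus shrinks to leave a
    # thin cytoplasmic gap (~1 um) to its nearest neighbour, as in tissue
    if n > 1:
        from scipy.spatial import cKDTree

        nn_dist = cKDTree(centers).query(centers, k=2)[0][:, 1]
        cap = np.maximum(1.5, 0.5 * (nn_dist - 1.0))
        base_r = np.minimum(base_r, cap)
    ecc = rng.uniform(0.0, 0.3, size=n)
    radii = np.stack([base_r * (1 + ecc), base_r / (1 + ecc)], axis=1)
    if n > 1:
        radii[:, 0] = np.minimum(radii[:, 0], cap)  # major axis respects the gap too
    orients = rng.uniform(0, np.pi, size=n)
    # per-cell staining heterogeneity (chromatin state / stain uptake),
    # shared by DAPI and the DNA intercalator
    cell_gain = np.r_[1.0, np.exp(rng.normal(0.0, 0.25, size=n))]

    tf = SimilarityGroundTruth(
        scale=spec.misalignment.scale,
        rotation_rad=np.deg2rad(spec.misalignment.rotation_deg),
        translation_um=tuple(spec.misalignment.translation_um),
        if_pixel_size_um=spec.if_pixel_size_um,
        imc_pixel_size_um=spec.imc_pixel_size_um,
    )

    # --- fluorescence frame (misaligned, high-res) ---
    if_shape = (
        int(round(h_um / spec.if_pixel_size_um)),
        int(round(w_um / spec.if_pixel_size_um)),
    )

    def if_bbox(k: int):
        cpx = tf.world_um_to_if_px(centers[k][None, :])[0]
        half = (radii[k].max() / (tf.scale * spec.if_pixel_size_um)) + 3
        return (
            (max(0, int(cpx[0] - half)), min(if_shape[0], int(cpx[0] + half) + 1)),
            (max(0, int(cpx[1] - half)), min(if_shape[1], int(cpx[1] + half) + 1)),
        )

    if_labels, if_intensity = _render_labels_and_intensity(
        centers, radii, orients, tf.if_px_to_world_um, if_shape, if_bbox
    )
    # camera model: smooth multiplicative illumination gain, PSF blur,
    # additive read noise
    gfield = ndimage.gaussian_filter(rng.standard_normal(if_shape), 40.0)
    gsd = gfield.std()
    gain = 1.0 + (0.1 * gfield / gsd if gsd > 0 else 0.0)
    # PSF of a 0.75 NA dry objective: sigma ~0.2 um
    if_img = ndimage.gaussian_filter(
        if_intensity * cell_gain[if_labels], 0.2 / spec.if_pixel_size_um
    )
    if_img = if_img * gain + 0.02
    if_img = if_img + rng.normal(0, spec.noise.if_gaussian_sd, size=if_shape)
    if_img = np.clip(if_img, 0, None)

    # --- IMC (world) frame, 1 um pitch ---
    imc_shape = (
        int(round(h_um / spec.imc_pixel_size_um)),
        int(round(w_um / spec.imc_pixel_size_um)),
    )

    def world_grid(pts_px: np.ndarray) -> np.ndarray:
        return pts_px * spec.imc_pixel_size_um

    def imc_bbox(k: int):
        cpx = centers[k] / spec.imc_pixel_size_um
        half = radii[k].max() / spec.imc_pixel_size_um + 2
        return (
            (max(0, int(cpx[0] - half)), min(imc_shape[0], int(cpx[0] + half) + 1)),
            (max(0, int(cpx[1] - half)), min(imc_shape[1], int(cpx[1] + half) + 1)),
        )

    imc_labels, imc_intensity = _render_labels_and_intensity(
        centers, radii, orients, world_grid, imc_shape, imc_bbox
    )

    # cell territories: bounded Voronoi-style growth around each nucleus
    dist_out = ndimage.distance_transform_edt(imc_labels == 0, sampling=spec.imc_pixel_size_um)
    cell_reach_um = 3.0
    cells = watershed(dist_out, markers=imc_labels, mask=dist_out <= cell_reach_um)

    # epithelial region: the curved band (ribbon profile) or a central band
    yy, xx = np.meshgrid(
        np.arange(imc_shape[0]) * spec.imc_pixel_size_um,
        np.arange(imc_shape[1]) * spec.imc_pixel_size_um,
        indexing="ij",
    )
    if spec.crowding_profile == "epithelial-ribbon":
        epi_mask = _ribbon_distance(yy, xx, spec.field_size_um) <= 8.0
    else:
        epi_mask = np.abs(yy - h_um / 2) <= 0.2 * h_um

    # membrane ridge on territory boundaries
    ridge = boundary_pixels(cells).astype(float)
    ridge = ndimage.gaussian_filter(ridge, 0.7)
    ridge /= max(ridge.max(), 1e-9)

    channels: list[Raster] = []
    names: list[str] = []
    # chromatin-scale texture: intercalator uptake is granular within nuclei
    tex = np.exp(1.5 * ndimage.gaussian_filter(rng.standard_normal(imc_shape), 1.2))
    dna_expect = np.clip(
        ndimage.gaussian_filter(imc_intensity * cell_gain[imc_labels], 0.6) * tex, 0, None
    )
    dna = rng.poisson(dna_expect * spec.noise.imc_poisson_scale).astype(np.float64)
    channels.append(Raster(dna, spec.imc_pixel_size_um, name="DNA-Ir193"))
    names.append("DNA-Ir193")
    # membranes wrap the whole cell in 3-D, so in a thick section their
    # projected signal also bleeds over the nucleus footprint
    cell_body = (cells > 0).astype(float)
    for m in range(spec.n_membrane_channels):
        # channel-specific regional gain mimics marker heterogeneity
        region_gain = np.where(epi_mask, 1.0 if m % 2 == 0 else 0.4,
                               0.4 if m % 2 == 0 else 1.0)
        expect = (ridge + 0.4 * cell_body) * region_gain
        vals = rng.poisson(expect * spec.noise.imc_poisson_scale).astype(np.float64)
        cname = f"membrane_{m + 1}"
        channels.append(Raster(vals, spec.imc_pixel_size_um, name=cname))
        names.append(cname)

    return Scene(
        if_nuclear=Raster(if_img, spec.if_pixel_size_um, name="DAPI"),
        imc_stack=ChannelStack(channels, names),
        gt_nuclei_highres=LabelMap(if_labels, spec.if_pixel_size_um),
        gt_nuclei_imc=LabelMap(imc_labels, spec.imc_pixel_size_um),
        gt_cells_imc=LabelMap(cells.astype(np.int32), spec.imc_pixel_size_um),
        true_transform=tf,
        epithelial_mask_imc=epi_mask,
        centers_um=centers,
        radii_um=radii,
        orientations_rad=orients,
        spec=spec,
    )


def scene_panel(scene: Scene) -> PanelConfig:
    """Panel table matching the scene's IMC channels."""
    entries = [PanelEntry("DNA-Ir193", metal_tag="Ir193", role="nuclear",
                          use_for_training=True)]
    for name in scene.imc_stack.channel_names:
        if name.startswith("membrane_"):
            entries.append(
                PanelEntry(name, role="membrane_cytoplasm", use_for_training=True,
                           use_for_clustering_export=True)
            )
    return PanelConfig(entries)


# ---------------------------------------------------------------------------
# class-region helpers

def _if_class_regions(scene: Scene) -> np.ndarray:
    """Class index map (1=nuclei, 2=nucleus edges, 3=background) at IF pitch."""
    lab = scene.gt_nuclei_highres.labels
    # 1-px rim inside each nucleus: a 2-px wall between touching nuclei,
    # matching the annotation scheme of thin nucleus-edge scribbles
    rim = find_boundaries(lab, mode="inner")
    out = np.full(lab.shape, 3, dtype=np.int32)
    out[lab > 0] = 1
    out[rim & (lab > 0)] = 2
    return out


def _imc_class_regions(scene: Scene) -> np.ndarray:
    """Class index map (1..5 in the canonical IMC class order) at IMC pitch."""
    nuc = scene.gt_nuclei_imc.labels > 0
    cells = scene.gt_cells_imc.labels > 0
    epi = scene.epithelial_mask_imc
    out = np.full(nuc.shape, 5, dtype=np.int32)  # background
    memb = cells & ~nuc
    out[memb & ~epi] = 1   # non-epithelial membrane
    out[nuc & ~epi] = 2    # non-epithelial nuclei
    out[memb & epi] = 3    # epithelial cytoplasm/membrane
    out[nuc & epi] = 4     # epithelial nuclei
    return out


def generate_scribbles(
    scene: Scene,
    n_pixels_per_class: int,
    seed: int,
    modality: str = "if",
) -> SparseAnnotation:
    """Sparse training scribbles sampled from the true class regions.

    Emulates expert annotations: for the fluorescence scheme the classes
    are nuclei / nucleus edges / background; for the IMC scheme the five
    canonical classes.  If a class region holds fewer pixels than
    requested, all of them are used (with a warning).
    """
    if modality == "if":
        regions = _if_class_regions(scene)
        class_names = list(IF_CLASSES)
    elif modality == "imc":
        regions = _imc_class_regions(scene)
        class_names = list(IMC_CLASSES)
    else:
        raise ValueError(f"unknown modality {modality!r}")
    rng = np.random.default_rng(seed)
    scrib = np.zeros(regions.shape, dtype=np.int32)
    for k, name in enumerate(class_names, start=1):
        idx = np.flatnonzero(regions.ravel() == k)
        if idx.size == 0:
            continue
        take = n_pixels_per_class
        if idx.size < take:
            warnings.warn(
                f"class {name!r} region has only {idx.size} pixels "
                f"(requested {take}); using all of them"
            )
            take = idx.size
        chosen = rng.choice(idx, size=take, replace=False)
        scrib.ravel()[chosen] = k
    return SparseAnnotation(scrib, class_names)


def make_ground_truth_annotations(
    scene: Scene, subregion_um: tuple[float, float, float, float]
) -> LabelMap:
    """Emulate expert nucleus annotation of a subregion.

    ``subregion_um`` is (y0, x0, height, width) in the world frame.  The
    high-resolution truth is cropped and downscaled to the IMC pitch by
    the majority rule; objects clipped by the crop boundary are kept only
    when at least half of their area lies inside.
    """
    from .segmentation import relabel_sequential_raster_order

    y0, x0, hh, ww = subregion_um
    h_um, w_um = scene.spec.field_size_um
    if y0 < 0 or x0 < 0 or y0 + hh > h_um + 1e-9 or x0 + ww > w_um + 1e-9:
        raise ValueError(f"subregion {subregion_um} outside field {scene.spec.field_size_um}")

    # render the crop's high-resolution truth on a world-aligned grid
    pitch = scene.spec.if_pixel_size_um
    shape = (int(round(hh / pitch)), int(round(ww / pitch)))
    centers = scene.centers_um
    radii = scene.radii_um
    orients = scene.orientations_rad

    def grid_world(pts_px: np.ndarray) -> np.ndarray:
        return pts_px * pitch + np.array([y0, x0])

    def bbox(k: int):
        cpx = (centers[k] - np.array([y0, x0])) / pitch
        half = radii[k].max() / pitch + 3
        return (
            (max(0, int(cpx[0] - half)), min(shape[0], int(cpx[0] + half) + 1)),
            (max(0, int(cpx[1] - half)), min(shape[1], int(cpx[1] + half) + 1)),
        )

    labels, _ = _render_labels_and_intensity(centers, radii, orients, grid_world, shape, bbox)

    # >= 50%-inside rule against each nucleus's full analytic area
    full_area = np.pi * radii[:, 0] * radii[:, 1] / pitch**2
    inside = np.bincount(labels.ravel(), minlength=centers.shape[0] + 1)
    for k in range(1, centers.shape[0] + 1):
        if inside[k] and inside[k] < 0.5 * full_area[k - 1]:
            labels[labels == k] = 0
    labels = relabel_sequential_raster_order(labels)

    # binary-mask downscale: an IMC pixel is annotated nucleus only when
    # more than half of its area is covered by nuclei; the label is the
    # plurality nucleus among the covering ones.  This keeps sub-micron
    # gaps between annotated nuclei open at the coarse pitch.
    from .segmentation import _label_coverage

    tp = scene.spec.imc_pixel_size_um
    (oh, ow), tgt_of, lab_of, agg = _label_coverage(labels, pitch, tp)
    area_units = (tp / pitch) ** 2  # total source area per target pixel
    out = np.zeros(oh * ow, dtype=np.int32)
    covered = np.zeros(oh * ow)
    best_w = np.zeros(oh * ow)
    pos = lab_of > 0
    np.add.at(covered, tgt_of[pos], agg[pos])
    # plurality among positive labels (pairs sorted => lowest label on ties)
    for t, l, w in zip(tgt_of[pos], lab_of[pos], agg[pos]):
        if w > best_w[t]:
            best_w[t] = w
            out[t] = l
    out[covered <= 0.5 * area_units] = 0
    return LabelMap(
        relabel_sequential_raster_order(out.reshape(oh, ow)), tp
    )


def scene_probability_maps(scene: Scene):
    """Idealised per-modality probability maps derived from ground truth.

    Emulates the output of a well-trained pixel classifier: one-hot class
    regions softened with a 1-px Gaussian and renormalised.  Deterministic
    given the scene.  Returns ``(if_probmap, imc_probmap)``.
    """
    from .model import ProbabilityMap

    def soften(regions: np.ndarray, n_classes: int, pitch: float, names: list[str]):
        planes = []
        for k in range(1, n_classes + 1):
            planes.append(ndimage.gaussian_filter((regions == k).astype(np.float64), 1.0))
        arr = np.stack(planes)
        arr /= np.clip(arr.sum(axis=0, keepdims=True), 1e-12, None)
        return ProbabilityMap(
            [Raster(a, pitch, name=n) for a, n in zip(arr, names)], list(names)
        )

    if_pm = soften(
        _if_class_regions(scene), 3, scene.spec.if_pixel_size_um, list(IF_CLASSES)
    )
    imc_pm = soften(
        _imc_class_regions(scene), 5, scene.spec.imc_pixel_size_um, list(IMC_CLASSES)
    )
    return if_pm, imc_pm
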