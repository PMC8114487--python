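"""Multimodal registration of the fluorescence nuclear image onto the IMC grid.

The high-resolution fluorescence (IF) DAPI image is aligned to the IMC
DNA-intercalator channel while keeping the IF pixel pitch.  The chain is:

1. multi-scale oriented-patch (MOPS-style) keypoint detection on both
   nuclear images — Harris-type corner strength per pyramid level,
   adaptive non-maximal suppression, an 8x8 bias/gain-normalised
   descriptor sampled from a blurred patch, and a gradient orientation;
2. ratio-test + cross-checked descriptor matching;
3. robust global similarity fit (RANSAC) to reject outlier matches;
4. a moving-least-squares (MLS) warp of similarity class built on the
   surviving control points.

The scale gap between modalities is bridged by detecting on the IF image
downsampled to the IMC pitch, then rescaling control points back into IF
pixel coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max, structure_tensor
from skimage.transform import SimilarityTransform, resize

from .config import RegistrationParams
from .model import Raster

__all__ = [
    "DegenerateGeometryError",
    "Keypoint",
    "MatchSet",
    "MLSTransform",
    "RegistrationResult",
    "detect_keypoints",
    "match_keypoints",
    "fit_mls_similarity",
    "warp_raster",
    "register_modalities",
]


class DegenerateGeometryError(RuntimeError):
    """Raised when too few/degenerate correspondences remain to fit a transform."""


@dataclass
class Keypoint:
    position: tuple[float, float]       # (row, col) in source-image pixels, level 0
    scale_level: int
    orientation_rad: float
    descriptor: np.ndarray              # length descriptor_size**2, zero mean / unit sd
    strength: float = 0.0


@dataclass
class MatchSet:
    """Point correspondences moving -> fixed, in each image's own pixel units."""

    src: np.ndarray                     # (N, 2) (row, col) in moving image
    dst: np.ndarray                     # (N, 2) (row, col) in fixed image
    descriptor_distance: np.ndarray     # (N,)
    moving_pixel_size_um: float = 1.0
    fixed_pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.src = np.atleast_2d(np.asarray(self.src, dtype=float))
        self.dst = np.atleast_2d(np.asarray(self.dst, dtype=float))
        self.descriptor_distance = np.asarray(self.descriptor_distance, dtype=float)
        if self.src.shape != self.dst.shape or self.src.shape[0] != self.descriptor_distance.size:
            raise ValueError("src, dst and descriptor_distance sizes disagree")
        if np.any(self.descriptor_distance < 0):
            raise ValueError("descriptor distances must be >= 0")
        if self.src.shape[0]:
            uniq = np.unique(self.src, axis=0)
            if uniq.shape[0] != self.src.shape[0]:
                raise ValueError("a source point appears in more than one match")

    def __len__(self) -> int:
        return int(self.src.shape[0])


# ---------------------------------------------------------------------------
# keypoint detection

def _corner_strength(image: np.ndarray, sigma: float = 1.5) -> np.ndarray:
    """Harmonic-mean corner response det(H)/trace(H) of the structure tensor."""
    axx, axy, ayy = structure_tensor(image, sigma=sigma, order="xy")
    det = axx * ayy - axy * axy
    tr = axx + ayy
    with np.errstate(invalid="ignore", divide="ignore"):
        resp = np.where(tr > 1e-12, det / (tr + 1e-18), 0.0)
    return resp


def _anms(points: np.ndarray, strengths: np.ndarray, max_points: int,
          robustness: float = 0.9) -> np.ndarray:
    """Adaptive non-maximal suppression: keep the max_points with largest
    suppression radius (distance to the nearest sufficiently-stronger point)."""
    n = points.shape[0]
    if n <= max_points:
        return np.arange(n)
    order = np.argsort(-strengths)
    pts = points[order]
    s = strengths[order]
    radii = np.full(n, np.inf)
    for i in range(1, n):
        # previous points are sorted stronger-first; require s_j * robustness > s_i
        mask = s[:i] * robustness > s[i]
        if np.any(mask):
            d2 = np.sum((pts[:i][mask] - pts[i]) ** 2, axis=1)
            radii[i] = np.sqrt(d2.min())
    keep_sorted = np.argsort(-radii)[:max_points]
    return order[keep_sorted]


def detect_keypoints(
    raster: Raster,
    n_pyramid_levels: int = 4,
    max_points: int = 500,
    descriptor_size: int = 8,
) -> list[Keypoint]:
    """Detect multi-scale oriented keypoints with normalised patch descriptors.

    Corner-strength maxima are collected from a Gaussian pyramid, reduced by
    adaptive non-maximal suppression to at most ``max_points``, and each
    keypoint gets an orientation from the local smoothed gradient and an
    ``descriptor_size**2``-vector descriptor sampled (with 2 px spacing) from
    an extra-blurred copy of its detection level, normalised to zero mean and
    unit standard deviation.  Degenerate (flat) patches are discarded.
    """
    img = np.asarray(raster.values, dtype=np.float64)
    if min(img.shape) < 32:
        raise ValueError(f"image too small for keypoint detection: {img.shape}")
    max_levels = int(np.floor(np.log2(min(img.shape) / 16))) + 1
    if n_pyramid_levels > max_levels:
        raise ValueError(
            f"image {img.shape} supports at most {max_levels} pyramid level(s), "
            f"requested {n_pyramid_levels}"
        )
    # contrast-normalise so detection thresholds are intensity-scale free
    sd = img.std()
    if sd > 0:
        img = (img - img.mean()) / sd

    pyramid = [ndimage.gaussian_filter(img, 1.0)]
    for _ in range(1, n_pyramid_levels):
        prev = pyramid[-1]
        pyramid.append(ndimage.gaussian_filter(prev, 1.0)[::2, ::2])

    cand_pos = []       # level-0 coords
    cand_level = []
    cand_strength = []
    cand_level_pos = []
    for level, pimg in enumerate(pyramid):
        if min(pimg.shape) < 16:
            break
        resp = _corner_strength(pimg)
        thr = max(1e-8, 0.01 * resp.max()) if resp.max() > 0 else np.inf
        if not np.isfinite(thr):
            continue
        peaks = peak_local_max(resp, min_distance=2, threshold_abs=thr, exclude_border=8)
        for r, c in peaks:
            # subpixel quadratic refinement of the response peak
            dr = dc = 0.0
            den_r = resp[r - 1, c] - 2 * resp[r, c] + resp[r + 1, c]
            den_c = resp[r, c - 1] - 2 * resp[r, c] + resp[r, c + 1]
            if den_r < 0:
                dr = float(np.clip(0.5 * (resp[r - 1, c] - resp[r + 1, c]) / den_r, -0.5, 0.5))
            if den_c < 0:
                dc = float(np.clip(0.5 * (resp[r, c - 1] - resp[r, c + 1]) / den_c, -0.5, 0.5))
            rf, cf = r + dr, c + dc
            cand_pos.append((rf * 2.0 ** level, cf * 2.0 ** level))
            cand_level.append(level)
            cand_level_pos.append((rf, cf))
            cand_strength.append(float(resp[r, c]))
    if not cand_pos:
        return []

    pos = np.asarray(cand_pos, dtype=float)
    strength = np.asarray(cand_strength, dtype=float)
    # cap the ANMS candidate pool to keep the O(n^2) suppression cheap
    if pos.shape[0] > 4 * max_points:
        top = np.argsort(-strength)[: 4 * max_points]
        pos, strength = pos[top], strength[top]
        cand_level = [cand_level[i] for i in top]
        cand_level_pos = [cand_level_pos[i] for i in top]
    keep = _anms(pos, strength, max_points)

    # orientation + descriptor per retained keypoint
    half = descriptor_size / 2.0 - 0.5
    spacing = 2.0
    offs = (np.arange(descriptor_size) - half) * spacing
    grid_dr, grid_dc = np.meshgrid(offs, offs, indexing="ij")
    keypoints: list[Keypoint] = []
    ori_maps = {}
    desc_maps = {}
    for idx in keep:
        level = cand_level[idx]
        pimg = pyramid[level]
        if level not in ori_maps:
            blur = ndimage.gaussian_filter(pimg, 2.0)
            gr = ndimage.sobel(blur, axis=0)
            gc = ndimage.sobel(blur, axis=1)
            ori_maps[level] = (gr, gc)
            desc_maps[level] = ndimage.gaussian_filter(pimg, 2.0)
        gr, gc = ori_maps[level]
        r, c = cand_level_pos[idx]
        ri, ci = int(round(r)), int(round(c))
        theta = float(np.arctan2(gr[ri, ci], gc[ri, ci])) % (2 * np.pi)
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        # rotate the sampling grid into the keypoint frame
        rr = r + grid_dr * cos_t + grid_dc * sin_t
        cc = c - grid_dr * sin_t + grid_dc * cos_t
        patch = ndimage.map_coordinates(
            desc_maps[level], np.stack([rr.ravel(), cc.ravel()]), order=1, mode="nearest"
        )
        psd = patch.std()
        if psd < 1e-10:
            continue  # flagged degenerate; discarded
        desc = (patch - patch.mean()) / psd
        keypoints.append(
            Keypoint(
                position=(float(pos[idx, 0]), float(pos[idx, 1])),
                scale_level=int(level),
                orientation_rad=theta,
                descriptor=desc,
                strength=float(strength[idx]),
            )
        )
    return keypoints


# ---------------------------------------------------------------------------
# matching

def match_keypoints(
    moving_kps: Sequence[Keypoint],
    fixed_kps: Sequence[Keypoint],
    ratio_threshold: float = 0.8,
    moving_pixel_size_um: float = 1.0,
    fixed_pixel_size_um: float = 1.0,
) -> MatchSet:
    """Nearest-neighbour descriptor matching with Lowe ratio test and
    symmetric cross-check.  An empty :class:`MatchSet` is a valid result."""
    if not moving_kps or not fixed_kps:
        raise ValueError("both keypoint lists must be non-empty")
    dm = np.stack([k.descriptor for k in moving_kps])
    df = np.stack([k.descriptor for k in fixed_kps])
    # Euclidean distances between descriptors
    d2 = (
        np.sum(dm * dm, axis=1)[:, None]
        + np.sum(df * df, axis=1)[None, :]
        - 2.0 * dm @ df.T
    )
    np.maximum(d2, 0, out=d2)
    dist = np.sqrt(d2)

    nn_f = np.argmin(dist, axis=1)
    nn_m = np.argmin(dist, axis=0)
    src, dst, dd = [], [], []
    for i, j in enumerate(nn_f):
        if nn_m[j] != i:  # cross-check
            continue
        row = dist[i]
        d1 = row[j]
        if row.size >= 2:
            d2nd = np.partition(row, 1)[1]
            # Lowe ratio: ambiguous when the runner-up is nearly as close
            if d2nd > 0 and d1 / d2nd >= ratio_threshold:
                continue
            if d2nd == 0 and d1 == 0 and row.size > 1 and np.sum(row == 0) > 1:
                continue  # duplicate descriptors: no unique correspondence
        src.append(moving_kps[i].position)
        dst.append(fixed_kps[j].position)
        dd.append(float(d1))
    if not src:
        return MatchSet(
            np.empty((0, 2)), np.empty((0, 2)), np.empty(0),
            moving_pixel_size_um, fixed_pixel_size_um,
        )
    return MatchSet(
        np.asarray(src), np.asarray(dst), np.asarray(dd),
        moving_pixel_size_um, fixed_pixel_size_um,
    )


def _estimate_similarity(src_xy: np.ndarray, dst_xy: np.ndarray) -> SimilarityTransform | None:
    """Least-squares global similarity (skimage convention, (x, y) points)."""
    if hasattr(SimilarityTransform, "from_estimate"):
        t = SimilarityTransform.from_estimate(src_xy, dst_xy)
        return t if t else None
    t = SimilarityTransform()
    return t if t.estimate(src_xy, dst_xy) else None


# ---------------------------------------------------------------------------
# moving least squares, similarity class

def _mls_similarity_map(
    query: np.ndarray, p: np.ndarray, q: np.ndarray, alpha: float
) -> np.ndarray:
    """Evaluate the similarity-class MLS deformation at query points.

    For each query v a similarity S_v = argmin sum_i w_i |S p_i - q_i|^2 with
    w_i = 1 / |p_i - v|^(2 alpha) is solved in closed form; query points that
    coincide with a control point map exactly onto its target.
    """
    v = np.atleast_2d(np.asarray(query, dtype=float))
    out = np.empty_like(v)
    eps = 1e-12
    # chunk over queries to bound memory at n_query * n_control
    chunk = max(1, int(2_000_000 // max(1, p.shape[0])))
    for start in range(0, v.shape[0], chunk):
        vv = v[start : start + chunk]                       # (M, 2)
        diff = p[None, :, :] - vv[:, None, :]               # (M, N, 2)
        d2 = np.sum(diff * diff, axis=2)                    # (M, N)
        exact = d2 < eps
        w = 1.0 / np.maximum(d2, eps) ** alpha              # (M, N)
        wsum = w.sum(axis=1, keepdims=True)
        p_star = (w[:, :, None] * p[None, :, :]).sum(axis=1) / wsum   # (M, 2)
        q_star = (w[:, :, None] * q[None, :, :]).sum(axis=1) / wsum
        ph = p[None, :, :] - p_star[:, None, :]             # (M, N, 2)
        qh = q[None, :, :] - q_star[:, None, :]
        mu = (w * np.sum(ph * ph, axis=2)).sum(axis=1)      # (M,)
        a = (w * np.sum(ph * qh, axis=2)).sum(axis=1) / np.maximum(mu, eps)
        b = (w * (ph[:, :, 0] * qh[:, :, 1] - ph[:, :, 1] * qh[:, :, 0])).sum(
            axis=1
        ) / np.maximum(mu, eps)
        rel = vv - p_star                                   # (M, 2)
        res = np.empty_like(vv)
        res[:, 0] = a * rel[:, 0] - b * rel[:, 1] + q_star[:, 0]
        res[:, 1] = b * rel[:, 0] + a * rel[:, 1] + q_star[:, 1]
        hit = exact.any(axis=1)
        if np.any(hit):
            idx = np.argmax(exact, axis=1)
            res[hit] = q[idx[hit]]
        out[start : start + chunk] = res
    return out


@dataclass
class MLSTransform:
    """Similarity-class moving-least-squares warp moving -> fixed.

    Built from control-point correspondences after robust outlier
    rejection; evaluates a locally weighted similarity at every query
    point (weight exponent ``alpha``), so each control source point maps
    exactly onto its target.
    """

    control_points: MatchSet
    alpha: float = 1.0
    mls_class: str = "similarity"

    def __post_init__(self) -> None:
        if len(self.control_points) < 2:
            raise DegenerateGeometryError(
                f"similarity-class MLS needs >= 2 control points, got {len(self.control_points)}"
            )
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    def map_points(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) (row, col) moving-image pixel coords into the fixed frame."""
        return _mls_similarity_map(
            points, self.control_points.src, self.control_points.dst, self.alpha
        )

    def inverse(self) -> "MLSTransform":
        """The MLS warp built on swapped control points (exact at controls,
        an excellent inverse for near-similarity deformations)."""
        swapped = MatchSet(
            self.control_points.dst.copy(),
            self.control_points.src.copy(),
            self.control_points.descriptor_distance.copy(),
            self.control_points.fixed_pixel_size_um,
            self.control_points.moving_pixel_size_um,
        )
        return MLSTransform(swapped, self.alpha, self.mls_class)


def fit_mls_similarity(
    match_set: MatchSet,
    alpha: float = 1.0,
    outlier_reject_px: float = 3.0,
    rng_seed: int = 0,
    min_inliers: int = 2,
) -> MLSTransform:
    """Reject outlier matches under a robust global similarity, then build
    the similarity-class MLS transform on the surviving control points.

    Outlier rejection: RANSAC with 2-point minimal samples; matches whose
    residual under the consensus similarity exceeds ``outlier_reject_px``
    (fixed-image pixels) are dropped.
    """
    n = len(match_set)
    if n < 2:
        raise DegenerateGeometryError(f"need >= 2 match pairs, got {n}")
    src = match_set.src[:, ::-1]  # skimage transforms use (x, y)
    dst = match_set.dst[:, ::-1]

    best_inliers = None
    rng = np.random.default_rng(rng_seed)
    n_iter = min(500, max(50, n * 4))
    for _ in range(n_iter):
        pick = rng.choice(n, size=2, replace=False)
        if np.allclose(src[pick[0]], src[pick[1]]):
            continue
        t = _estimate_similarity(src[pick], dst[pick])
        if t is None:
            continue
        resid = np.linalg.norm(t(src) - dst, axis=1)
        inliers = resid <= outlier_reject_px
        if best_inliers is None or inliers.sum() > best_inliers.sum():
            best_inliers = inliers
    if best_inliers is None or best_inliers.sum() < max(2, min_inliers):
        raise DegenerateGeometryError(
            f"no consensus similarity among matches (largest inlier set "
            f"{0 if best_inliers is None else int(best_inliers.sum())} < {max(2, min_inliers)})"
        )

    # refit on the consensus set, then apply the residual cut once more
    t = _estimate_similarity(src[best_inliers], dst[best_inliers])
    if t is None:
        raise DegenerateGeometryError("degenerate consensus set")
    resid = np.linalg.norm(t(src) - dst, axis=1)
    keep = resid <= outlier_reject_px
    if keep.sum() < 2:
        raise DegenerateGeometryError(
            f"fewer than 2 matches survive outlier rejection at {outlier_reject_px} px"
        )
    kept = MatchSet(
        match_set.src[keep],
        match_set.dst[keep],
        match_set.descriptor_distance[keep],
        match_set.moving_pixel_size_um,
        match_set.fixed_pixel_size_um,
    )
    return MLSTransform(kept, alpha=alpha)


# ---------------------------------------------------------------------------
# warping

def warp_raster(
    moving: Raster,
    transform: MLSTransform,
    fixed_grid_shape: tuple[int, int],
    fixed_pixel_size_um: float,
    keep_moving_resolution: bool = True,
    grid_step: int = 8,
) -> Raster:
    """Resample the moving raster onto the fixed image's physical extent.

    With ``keep_moving_resolution`` the output grid covers the fixed
    extent at the moving image's pixel pitch (the registered IF image keeps
    its sub-micron resolution); otherwise at the fixed pitch.  Sampling is
    inverse-mapped bilinear; samples outside the source are 0.  The inverse
    MLS displacement is evaluated on a coarse lattice (``grid_step`` output
    pixels) and interpolated — MLS fields are smooth, so the approximation
    error is far below a pixel.
    """
    out_pitch = moving.pixel_size_um if keep_moving_resolution else fixed_pixel_size_um
    ext_h = fixed_grid_shape[0] * fixed_pixel_size_um
    ext_w = fixed_grid_shape[1] * fixed_pixel_size_um
    out_h = int(round(ext_h / out_pitch))
    out_w = int(round(ext_w / out_pitch))

    inv = transform.inverse()
    gr = np.arange(0, out_h + grid_step, grid_step, dtype=float)
    gc = np.arange(0, out_w + grid_step, grid_step, dtype=float)
    gr = gr[gr <= out_h - 1 + grid_step]
    gc = gc[gc <= out_w - 1 + grid_step]
    mesh_r, mesh_c = np.meshgrid(gr, gc, indexing="ij")
    # output px -> fixed px -> (inverse MLS) -> moving px
    fixed_coords = np.stack(
        [mesh_r.ravel() * out_pitch / fixed_pixel_size_um,
         mesh_c.ravel() * out_pitch / fixed_pixel_size_um], axis=1
    )
    src_coords = inv.map_points(fixed_coords).reshape(mesh_r.shape + (2,))

    # bilinear upsample the displacement lattice to the full output grid
    rows = np.arange(out_h, dtype=float)
    cols = np.arange(out_w, dtype=float)
    ri = np.interp(rows, gr, np.arange(gr.size, dtype=float))
    ci = np.interp(cols, gc, np.arange(gc.size, dtype=float))
    rr, cc = np.meshgrid(ri, ci, indexing="ij")
    map_r = ndimage.map_coordinates(src_coords[..., 0], [rr, cc], order=1, mode="nearest")
    map_c = ndimage.map_coordinates(src_coords[..., 1], [rr, cc], order=1, mode="nearest")

    vals = ndimage.map_coordinates(
        np.asarray(moving.values, dtype=np.float64),
        [map_r, map_c],
        order=1,
        mode="constant",
        cval=0.0,
    )
    return Raster(vals, out_pitch, name=moving.name)


# ---------------------------------------------------------------------------
# end-to-end registration

@dataclass
class RegistrationResult:
    transform: MLSTransform             # IF px -> IMC px
    if_registered: Raster
    n_control_points: int
    median_residual_um: float


def register_modalities(
    if_nuclear: Raster,
    imc_dna: Raster,
    params: RegistrationParams | None = None,
) -> RegistrationResult:
    """Register the IF DAPI raster onto the IMC DNA-intercalator raster.

    Keypoints are detected on the IF image downsampled to the IMC pitch so
    descriptor patches see comparable physical footprints; control points
    are rescaled back to IF pixel coordinates before the MLS warp, and the
    warped IF output keeps the IF pixel size.
    """
    params = params or RegistrationParams()
    factor = imc_dna.pixel_size_um / if_nuclear.pixel_size_um
    ds_shape = (
        max(1, int(round(if_nuclear.shape[0] / factor))),
        max(1, int(round(if_nuclear.shape[1] / factor))),
    )
    if_ds = resize(
        np.asarray(if_nuclear.values, dtype=np.float64),
        ds_shape,
        order=1,
        anti_aliasing=factor > 1.001,
        preserve_range=True,
    )
    # clamp pyramid depth to what both images support
    min_side = min(*ds_shape, *imc_dna.shape)
    feasible = max(1, int(np.floor(np.log2(min_side / 16))) + 1)
    levels = min(params.n_pyramid_levels, feasible)
    kps_mov = detect_keypoints(
        Raster(if_ds, imc_dna.pixel_size_um, if_nuclear.name),
        n_pyramid_levels=levels,
        max_points=params.max_points,
        descriptor_size=params.descriptor_size,
    )
    kps_fix = detect_keypoints(
        imc_dna,
        n_pyramid_levels=levels,
        max_points=params.max_points,
        descriptor_size=params.descriptor_size,
    )
    if not kps_mov or not kps_fix:
        raise DegenerateGeometryError("keypoint detection produced no candidates")
    matches = match_keypoints(
        kps_mov, kps_fix, params.ratio_threshold,
        moving_pixel_size_um=imc_dna.pixel_size_um,
        fixed_pixel_size_um=imc_dna.pixel_size_um,
    )
    if len(matches) < 2:
        raise DegenerateGeometryError(
            f"only {len(matches)} descriptor matches; images may not overlap"
        )
    coarse = fit_mls_similarity(
        matches, alpha=params.mls_alpha, outlier_reject_px=params.outlier_reject_px,
        min_inliers=max(4, len(matches) // 5),
    )
    cp = coarse.control_points

    # guided re-matching: project every moving keypoint through the coarse
    # global similarity and pair it with the nearest fixed keypoint; this
    # recruits many well-distributed control points, averaging out the
    # per-keypoint localisation noise.
    guided = _guided_matches(kps_mov, kps_fix, cp, radius_px=1.5)
    if guided is not None and len(guided) >= len(cp):
        refit = fit_mls_similarity(
            guided, alpha=params.mls_alpha, outlier_reject_px=params.outlier_reject_px
        )
        cp = refit.control_points
    resid_px = np.linalg.norm(
        _global_similarity_residuals(cp.src, cp.dst), axis=1
    )
    median_residual_um = float(np.median(resid_px) * imc_dna.pixel_size_um)

    # rescale moving-side control points from IMC-pitch coords to IF px;
    # resize() is corner-aligned, so downsampled index i samples the source
    # at (i + 0.5) * factor - 0.5
    src_if = (cp.src + 0.5) * factor - 0.5
    final_cp = MatchSet(
        src_if, cp.dst, cp.descriptor_distance,
        moving_pixel_size_um=if_nuclear.pixel_size_um,
        fixed_pixel_size_um=imc_dna.pixel_size_um,
    )
    transform = MLSTransform(final_cp, alpha=params.mls_alpha)
    if_registered = warp_raster(
        if_nuclear, transform, imc_dna.shape, imc_dna.pixel_size_um,
        keep_moving_resolution=True,
    )
    return RegistrationResult(
        transform=transform,
        if_registered=if_registered,
        n_control_points=len(final_cp),
        median_residual_um=median_residual_um,
    )


def _guided_matches(
    kps_mov: Sequence[Keypoint],
    kps_fix: Sequence[Keypoint],
    control: MatchSet,
    radius_px: float,
) -> MatchSet | None:
    """Re-match keypoints by proximity under the global similarity implied by
    an initial control set (mutual nearest neighbours within radius_px)."""
    t = _estimate_similarity(control.src[:, ::-1], control.dst[:, ::-1])
    if t is None:
        return None
    mov = np.asarray([k.position for k in kps_mov], dtype=float)
    fix = np.asarray([k.position for k in kps_fix], dtype=float)
    proj = t(mov[:, ::-1])[:, ::-1]
    from scipy.spatial import cKDTree

    tree = cKDTree(fix)
    dist, idx = tree.query(proj, distance_upper_bound=radius_px)
    ok = np.isfinite(dist)
    if ok.sum() < 2:
        return None
    # enforce uniqueness on the fixed side: keep the closest claimant
    best: dict[int, int] = {}
    for i in np.flatnonzero(ok):
        j = int(idx[i])
        if j not in best or dist[i] < dist[best[j]]:
            best[j] = int(i)
    mov_idx = sorted(best.values())
    fix_idx = [int(idx[i]) for i in mov_idx]
    return MatchSet(
        mov[mov_idx], fix[fix_idx], np.zeros(len(mov_idx)),
        control.moving_pixel_size_um, control.fixed_pixel_size_um,
    )


def _global_similarity_residuals(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    t = _estimate_similarity(src[:, ::-1], dst[:, ::-1])
    if t is None:
        raise DegenerateGeometryError("degenerate control-point geometry")
    return t(src[:, ::-1]) - dst[:, ::-1]
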