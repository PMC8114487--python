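# Methods

## The problem and the pipeline

Imaging mass cytometry (IMC) images ~40 metal-conjugated antibody stains
at a fixed 1 µm/px pitch. At that resolution, nuclei in densely packed
regions (epithelial monolayers, immune infiltrates) blur into contiguous
masses, and segmentation pipelines built on IMC alone either merge
neighbouring cells into one event or cut single cells into fragments.
The dual-modality pipeline implemented here adds a sub-micron
fluorescence image of a DNA stain (DAPI) of the *same* section, acquired
before ablation, and uses it for the nucleus-detection stage only:

1. **Registration** — the fluorescence nuclear image is registered onto
   the IMC DNA-intercalator channel (Ir193) with multi-scale
   oriented-patch keypoints, descriptor matching, robust global
   similarity consensus, and a similarity-class moving-least-squares
   (MLS) warp. The warped image keeps the fluorescence pixel pitch.
2. **Pixel classification** — a random-forest pixel classifier per
   modality: 3 classes on fluorescence (nuclei / nucleus edges /
   background) using a fixed list of derivative and grayscale-morphology
   features of the raw DAPI signal; 5 classes on IMC (non-epithelial
   membranes, non-epithelial nuclei, epithelial cytoplasm/membrane,
   epithelial nuclei, background) using a standard 2-D filter family at
   σ 0.3–1.6 px on percentile-scaled channels.
3. **Segmentation** — nuclei are detected on the high-resolution nuclear
   probability map (smooth → threshold → fill holes → seeded-watershed
   declumping → minimum-area filter), downscaled to the IMC grid by
   per-pixel area majority, then expanded to whole cells by a seeded
   watershed ascending the IMC membrane probability, capped at a maximum
   expansion radius. The IMC-only reference pipeline runs the identical
   machinery with nuclei detected directly on the reduced IMC nuclear
   class at 1 µm.
4. **Scoring** — predicted nuclei/cells are compared with annotated
   nuclei via best-IOU recall curves (thresholds 0.5–1.0, step 0.05),
   the split-event fraction (≥ 2 predictions each covering ≥ 20 % of one
   annotation), an edge-intersection score, and fragmentation per
   externally supplied cell group.
5. **Quantification** — per-cell means of the *unscaled* channel values,
   centroids, areas, neighbour counts within 10 µm, line profiles, and a
   log1p-transformed clustering export restricted to panel-flagged
   channels.

## Spatial conventions

Pixel coordinates are 0-based `(row, col)`; pixel centres sit at integer
coordinates and `position_um = index × pixel_size_um`, so pixel *i*
spans `[i·p − p/2, i·p + p/2)`. Every resampling operation in the
package (label downscaling, ground-truth downscaling, warping) uses this
one convention; mixing centre- and corner-aligned conventions introduces
a systematic sub-pixel shift between the downscaled nuclei and the
IMC-native membrane topography that is large enough (0.375 µm at the
4:1 pitch ratio) to bias boundary placement measurably.

## Registration details

* Keypoints: Harris-type corner strength (det/trace of the structure
  tensor) per level of a Gaussian pyramid (σ 1 blur, ×2 decimation),
  sub-pixel quadratic peak refinement, adaptive non-maximal suppression
  to ≤ 500 points, orientation from the σ 2-blurred gradient, and an
  8×8 patch descriptor sampled with 2 px spacing from an extra-blurred
  copy of the detection level, normalised to zero mean / unit variance.
* Matching: nearest-neighbour descriptor distance with a Lowe ratio test
  (0.8) and symmetric cross-check.
* Robust consensus: RANSAC over 2-point similarity hypotheses with a
  3 px residual gate, followed by **guided re-matching** — every
  keypoint is re-paired with its nearest counterpart (≤ 1.5 px) under
  the consensus similarity. This recruits an order of magnitude more,
  well-distributed control points and averages out per-keypoint
  localisation noise; without it the centroid-displacement error roughly
  doubles.
* The scale gap between modalities is bridged by detecting on the
  fluorescence image downsampled to the IMC pitch; control points are
  mapped back to fluorescence pixels with the corner-aligned
  `(i + ½)·f − ½` convention of the resizing routine.
* The similarity-class MLS warp (weights `1/|p_i − v|^{2α}`, α = 1)
  interpolates the control points exactly. The inverse warp is the MLS
  built on swapped control points. For image resampling the inverse
  displacement is evaluated on an 8-px lattice and bilinearly
  interpolated — MLS fields are smooth, and the approximation error is
  far below 0.1 px.

Measured on 20 scenes with random misalignments (scale 0.95–1.05,
rotation ≤ 5°, translation ≤ 20 µm), the recovered warp keeps ≥ 95 % of
true nucleus centroids within 1 IMC pixel (mean displacement ≈ 0.3 µm).

## Segmentation parameters

| parameter | default | rationale |
|---|---|---|
| `nucleus_prob_threshold` | 0.35 | with a 3-class posterior the nucleus-edge class absorbs mass near the true boundary, so 0.5 systematically erodes nuclei; 0.35 approximates arg-max membership |
| `min_nucleus_area_um2` | 2 µm² | removes speckle (2 px at IMC pitch) without deleting rim-eroded small nuclei |
| `smoothing_sigma_um` | 0.5 µm | probability smoothing in physical units so both resolutions are treated identically |
| `declump` | `intensity-valley` | seeds are regional-maximum *plateaus* of the (smoothed) probability — one seed per plateau — greedily thinned so survivors are ≥ `maxima_suppression_um` apart; `shape` (smoothed distance transform) is available but under-fragments noisy 1 µm masks |
| `maxima_suppression_um` | 2.5 µm | about half the expected nucleus diameter (CellProfiler's maxima-suppression-distance semantics) |
| `max_expansion_um` | 5 µm | cytoplasm reach of colonic epithelial/immune cells |

Two implementation points matter for correctness: each connected mask
component always keeps at least one watershed seed (suppression may
declump, never delete objects), and a flat probability plateau counts as
a single seed rather than a field of tied peaks.

Label downscaling takes, per target pixel, the label (background
included) with the largest covered source area; exact ties go to the
lowest label id; non-integer pitch ratios use area-weighted coverage.

## Scoring details

Recall uses all annotated nuclei as the denominator: an annotation with
no overlapping prediction is a false negative at every threshold. The
split fraction follows the 20 % area rule per interaction.

The edge-intersection score needed a concrete formula. The default,
`gt_interior`, counts predicted-cell boundary pixels that fall strictly
inside an annotated nucleus (a pixel whose full 8-neighbourhood carries
the same annotation label), normalised by total annotated area: a
boundary that *grazes* an annotation's rim is not a cut; one that
crosses its interior is. Two alternatives are selectable:
`gt_area` (boundary pixels anywhere inside an annotation / annotated
area) and `boundary_length` (the same numerator / total boundary
pixels). `gt_area` is kept for reference but is degenerate on
contiguous epithelium: measured on synthetic scenes, a *perfect*
segmentation scores ≈ 0.074 while a merge-heavy segmentation scores
≈ 0.054 — i.e. the variant rewards missing boundaries, inverting the
intended "lower is better" semantics. Boundary pixels use the
4-neighbourhood (two-sided, so an internal cut is two pixels wide).

Ground-truth annotations are produced from the high-resolution truth as
a *binary mask* downscale: an IMC pixel is annotated only when more than
half its area is covered by nuclei (plurality label among the covering
nuclei). This keeps sub-micron inter-nucleus gaps open at the coarse
pitch, as a conservative annotator would draw them. Objects clipped by
the annotation window are kept only when at least half their area lies
inside.

## The synthetic scene generator

Scenes emulate colon-like tissue imaged by both modalities, with exact
ground truth:

* **Geometry** — elliptical nuclei (radius 2.6 ± 0.4 µm before packing)
  placed by profile: `sparse` (uniform), `crowded` (70 % of nuclei in
  bounded clumps of ~12 grown by local attachment — crypt cross-sections
  — with neighbours one diameter + a 0.4–2.2 µm cytoplasmic sliver
  apart), `epithelial-ribbon` (a tightly packed band along a sine
  curve). Radii shrink to half the nearest-neighbour distance minus a
  1 µm gap (floor 1.2–1.5 µm), so nuclei pack without interpenetrating,
  as in tissue. The default crowded condition is 300 nuclei at minimum
  centre spacing 2 µm in a 250×250 µm field.
* **Fluorescence channel** — per-cell lognormal staining gain
  (sd 0.25), a 0.2 µm PSF (0.75 NA dry objective), a smooth ±10 %
  multiplicative illumination field, additive Gaussian read noise
  (sd 0.03 of the nuclear peak), at 0.25 µm/px.
* **IMC channels** — 1 µm/px; the DNA channel is the nuclear intensity
  modulated by chromatin-scale lognormal texture (sd 1.5 at ~1.2 µm
  correlation length) with Poisson counts (≈ 6 expected counts at unit
  signal — realistic ion statistics); membrane channels are ridges on
  cell-territory boundaries plus a 0.4-relative bleed over the whole
  cell body (membranes wrap cells in 3-D, so a thick section projects
  membrane signal over the nucleus), with region-dependent gain between
  the epithelial band and the rest.
* **Misalignment** — the fluorescence frame relates to the IMC (world)
  frame by an exact similarity (scale, rotation, translation) stored in
  the scene; ground-truth labels exist in both frames.
* **Scribbles** — training annotations are sampled from the true class
  regions (1-px nucleus rims for the fluorescence edge class), standing
  in for expert scribbles.

What the generator does **not** model: real marker co-expression
biology, ablation artefacts (streaks, spillover between mass channels),
autofluorescence, tissue deformation between imaging rounds beyond a
global similarity, and out-of-focus light. Passing benchmarks on these
scenes therefore demonstrates that the pipeline machinery behaves as
designed under controlled resolution/noise contrasts — not that any
particular biological accuracy is achieved on real tissue.

## Benchmark design and measured behaviour

The headline benchmark (`matisse.benchmark.pipeline_comparison`)
generates crowded scenes, trains both classifiers on 500 scribbles per
class from each scene, runs both segmentation pipelines with identical
parameters, and scores both against the full-field annotation. At the
default conditions the dual-modality pipeline finds more cells, reaches
markedly higher recall at IOU 0.6, and produces fewer split events and
a lower edge-intersection score than the IMC-only pipeline — the same
direction on all four metrics as the original tissue study, at desk
scale. Problem sizes (20 scenes of 250×250 µm, 300 nuclei) were chosen
so the whole benchmark suite completes in a few minutes on one CPU.

## Known limitations

* The MLS warp is similarity-class only; tissue deformation beyond a
  near-similarity is not recovered.
* The IMC filter-bank preset approximates the interactive tool's
  feature family; exact per-pixel equivalence with the original runs is
  not claimed, only the same class contract and I/O.
* Ground-truth-free operation is untested: every quality number in this
  package is measured against generated truth.
* The guided re-matching step assumes the global misalignment really is
  close to a similarity; grossly non-rigid inputs would need the
  RANSAC gate loosened and more local control points.
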