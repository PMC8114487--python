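# matisse

Dual-modality single-cell segmentation for imaging mass cytometry (IMC).

IMC images ~40 metal-conjugated antibody stains on one tissue section,
but at a fixed 1 µm/px pitch — too coarse to separate nuclei in densely
packed regions such as epithelial monolayers, so IMC-only segmentation
merges neighbouring cells and fragments others. This package implements
a pipeline that registers a sub-micron fluorescence image of the DNA
stain (DAPI) of the *same* section onto the IMC DNA-intercalator
channel, detects nuclei at high resolution, downscales them to the IMC
grid, and expands them to whole cells on the IMC membrane probability.
It is aimed at labs analysing multiplex IMC of epithelial tissues who
can add one round of ordinary fluorescence microscopy before ablation.

The package contains, as tested library modules with a thin CLI:

* `registration` — multi-scale oriented-patch keypoints, ratio-test
  matching, RANSAC similarity consensus, and a similarity-class
  moving-least-squares warp `f(v) = S_v·(v − p*) + q*` with per-query
  weights `w_i = 1/|p_i − v|^{2α}`, keeping the fluorescence resolution;
* `pixel_classification` — the two filter-bank feature sets
  (fluorescence: fixed derivative + grayscale-morphology features of the
  raw DAPI signal; IMC: a standard 2-D filter family at σ 0.3–1.6 px)
  and a random-forest pixel classifier producing per-class probability
  maps (3 classes for fluorescence, 5 for IMC);
* `segmentation` — primary/secondary objects: seeded-watershed nucleus
  detection and declumping, area-majority label downscaling, and
  membrane-guided cell expansion; both the dual-modality (`matisse`) and
  the `imc-only` pipeline share one parameter surface;
* `scoring` — best-IOU recall curves (recall = TP/(TP+FN) at IOU
  thresholds 0.5–1.0, step 0.05), split-event fraction (≥ 2 predictions
  each covering ≥ 20 % of one annotated nucleus), edge-intersection
  score, and fragmentation per cell group;
* `quantification` — per-cell means from unscaled channels, neighbour
  counts within 10 µm, line profiles, log1p clustering export;
* `synthetic` — a dual-resolution scene generator with exact ground
  truth (crowded elliptical nuclei, membrane ridges, known similarity
  misalignment, camera vs ion-count noise), used as the test substrate;
* `benchmark` — reproducible scene batches comparing the two pipelines.

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.

## Worked example

```python
from matisse import SceneSpec, generate_scene, make_ground_truth_annotations
from matisse.benchmark import scene_probability_maps_trained
from matisse.segmentation import run_matisse, run_imc_only
from matisse.scoring import score_prediction

scene = generate_scene(SceneSpec(seed=0))        # 250x250 um, 300 crowded nuclei
pm_if, pm_imc = scene_probability_maps_trained(scene, seed=0)

res_m = run_matisse(pm_if["nuclei"], pm_imc)     # high-res nuclei -> IMC cells
res_i = run_imc_only(pm_imc)                     # 1 um nuclei -> IMC cells

gt = make_ground_truth_annotations(scene, (0, 0, 250, 250))
for name, res in [("matisse", res_m), ("imc-only", res_i)]:
    rep = score_prediction(res.nuclei, gt, res.cells)
    print(f"{name:9s} cells={res.cells.n_objects:4d} "
          f"recall@0.6={rep.recall_by_threshold[0.6]:.3f} "
          f"split={rep.split_fraction:.3f} edge={rep.edge_intersection_score:.4f}")
```

Output:

```
matisse   cells= 297 recall@0.6=0.857 split=0.023 edge=0.0084
imc-only  cells= 265 recall@0.6=0.597 split=0.027 edge=0.0049
```

The dual-modality pipeline recovers nearly all 300 generated nuclei and
matches annotations far more precisely (recall at IOU 0.6), because the
0.25 µm nuclear probability map separates nuclei that blur together at
1 µm. Single scenes are noisy in the two rarer-event metrics; averaged
over a 20-scene batch (`matisse.benchmark.pipeline_comparison`), the
dual-modality pipeline is better on all four: more cells, higher
recall, fewer split events, and a lower edge-intersection score.

The same steps are available as CLI verbs operating on TIFF/CSV files:

```bash
matisse simulate --out scene/ --seed 3 --config run.yaml
matisse register --if-image scene/if_dapi.tiff \
    --imc-dna-channel scene/imc/DNA-Ir193.tiff --out-transform t.csv
matisse train / classify / segment --mode matisse|imc-only / score / quantify
```

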