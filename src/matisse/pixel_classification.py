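"""Filter-bank pixel features and a supervised probability-map classifier.

Two configurations mirror the two imaging modalities:

* **imc** — a standard 2-D filter family (Gaussian, Laplacian of Gaussian,
  gradient magnitude, structure-tensor eigenvalues, Hessian eigenvalues,
  difference of Gaussians) evaluated per training channel at sigmas
  spanning 0.3–1.6 px, after deterministic percentile scaling of the raw
  counts to 16-bit range.  Five classes: non-epithelial membranes,
  non-epithelial nuclei, epithelial cytoplasm/membrane, epithelial
  nuclei, background.
* **if** — a fixed list of derivative features and grayscale-morphology
  filters of the raw DAPI signal (plus the raw image itself), each
  subsequently smoothed with a single Gaussian (sigma 1.0 px) on the
  classifier side.  Three classes: nuclei, edges of nuclei, background.

The classifier is a random-forest ensemble fitted on the sparsely
annotated (scribbled) pixels only; per-pixel class posteriors come from
the averaged tree votes.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
from scipy import ndimage
from skimage.feature import structure_tensor, structure_tensor_eigenvalues
from skimage.morphology import dilation, disk, erosion, opening, white_tophat
from sklearn.ensemble import RandomForestClassifier

from .model import ChannelStack, ProbabilityMap, Raster, SparseAnnotation

__all__ = [
    "IMC_CLASSES",
    "IF_CLASSES",
    "FeatureConfig",
    "PixelClassifier",
    "compute_features",
    "train_classifier",
    "predict_probability_map",
    "imc_class_reduce",
    "scale_to_16bit",
]

IMC_CLASSES = [
    "non_epithelial_membrane",
    "non_epithelial_nuclei",
    "epithelial_cytoplasm_membrane",
    "epithelial_nuclei",
    "background",
]
IF_CLASSES = ["nuclei", "nucleus_edges", "background"]

# published IF feature lists: filter -> sigmas (px)
_IF_FEATURES_DEFAULT = [
    ("laplacian", [0.7, 1.0, 1.6, 2.0, 3.0]),
    ("hessian_smallest", [3.0, 5.0]),
    ("hessian_largest", [1.0, 2.0]),
    ("structure_largest", [1.0, 2.0]),
    ("gaussian", [0.7, 1.6, 2.0, 3.5]),
]
# morphology filter -> disk radii (px)
_IF_MORPHOLOGY_DEFAULT = [
    ("opening", [1, 2, 3, 5]),
    ("internal_gradient", [1, 3, 5]),
    ("white_top_hat", [8, 10, 15, 20]),
    ("edges", [1, 2]),
]

# offset (additive-constant) invariance per filter, used by property tests
OFFSET_INVARIANT_FILTERS = {
    "laplacian": True,
    "hessian_smallest": True,
    "hessian_largest": True,
    "structure_largest": True,
    "structure_smallest": True,
    "gaussian": False,
    "gradient_magnitude": True,
    "log": True,
    "dog": True,
    "opening": False,
    "internal_gradient": True,
    "white_top_hat": True,
    "edges": True,
    "raw": False,
}


@dataclass
class FeatureConfig:
    mode: str = "imc"  # "imc" or "if"
    imc_sigmas: list[float] = field(default_factory=lambda: [0.3, 0.7, 1.0, 1.6])
    if_features: list[tuple[str, list[float]]] = field(
        default_factory=lambda: [(f, list(s)) for f, s in _IF_FEATURES_DEFAULT]
    )
    if_morphology: list[tuple[str, list[float]]] = field(
        default_factory=lambda: [(f, list(s)) for f, s in _IF_MORPHOLOGY_DEFAULT]
    )
    include_raw: bool = True
    post_feature_smoothing_sigma: float = 1.0  # IF mode only
    imc_scale_percentiles: tuple[float, float] = (0.1, 99.9)

    def __post_init__(self) -> None:
        if self.mode not in ("imc", "if"):
            raise ValueError(f"unknown feature mode {self.mode!r}")
        for s in self.imc_sigmas:
            if s <= 0:
                raise ValueError(f"sigma must be positive, got {s}")
        for fam in (self.if_features, self.if_morphology):
            for name, sigmas in fam:
                for s in sigmas:
                    if s <= 0:
                        raise ValueError(f"{name}: sigma/radius must be positive, got {s}")


def _hessian_eigs(img: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    hrr = ndimage.gaussian_filter(img, sigma, order=(2, 0))
    hcc = ndimage.gaussian_filter(img, sigma, order=(0, 2))
    hrc = ndimage.gaussian_filter(img, sigma, order=(1, 1))
    mean = 0.5 * (hrr + hcc)
    root = np.sqrt(np.maximum(0.25 * (hrr - hcc) ** 2 + hrc**2, 0))
    return mean + root, mean - root  # (largest, smallest) by signed value


def _structure_eigs(img: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    A = structure_tensor(img, sigma=sigma, order="rc")
    big, small = structure_tensor_eigenvalues(A)
    return big, small


_DERIVATIVE_FILTERS = {
    "laplacian", "log", "gradient_magnitude", "hessian_largest",
    "hessian_smallest", "structure_largest", "structure_smallest", "dog",
}


def _apply_filter(img: np.ndarray, name: str, sigma: float) -> np.ndarray:
    if name in _DERIVATIVE_FILTERS:
        # derivative kernels are DC-blind in exact math; removing the mean
        # cancels the truncated-kernel DC leak so offset invariance is exact
        img = img - img.mean()
    if name == "gaussian":
        return ndimage.gaussian_filter(img, sigma)
    if name in ("laplacian", "log"):
        return ndimage.gaussian_laplace(img, sigma)
    if name == "gradient_magnitude":
        return ndimage.gaussian_gradient_magnitude(img, sigma)
    if name == "hessian_largest":
        return _hessian_eigs(img, sigma)[0]
    if name == "hessian_smallest":
        return _hessian_eigs(img, sigma)[1]
    if name == "structure_largest":
        return _structure_eigs(img, sigma)[0]
    if name == "structure_smallest":
        return _structure_eigs(img, sigma)[1]
    if name == "dog":
        return ndimage.gaussian_filter(img, sigma) - ndimage.gaussian_filter(img, 0.66 * sigma)
    # grayscale morphology on a disk structuring element
    selem = disk(int(round(sigma)))
    if name == "opening":
        return opening(img, selem)
    if name == "internal_gradient":
        return img - erosion(img, selem)
    if name == "white_top_hat":
        return white_tophat(img, selem)
    if name == "edges":
        return dilation(img, selem) - erosion(img, selem)
    raise ValueError(f"unknown filter {name!r}")


_IMC_FILTER_FAMILY = [
    "gaussian",
    "log",
    "gradient_magnitude",
    "structure_largest",
    "structure_smallest",
    "hessian_largest",
    "hessian_smallest",
    "dog",
]


def scale_to_16bit(values: np.ndarray, percentiles: tuple[float, float] = (0.1, 99.9)) -> np.ndarray:
    """Deterministic percentile min-max scaling of raw counts to [0, 65535]."""
    lo, hi = np.percentile(values, percentiles)
    if hi <= lo:
        return np.zeros_like(values, dtype=np.float64)
    return np.clip((values.astype(np.float64) - lo) / (hi - lo), 0, 1) * 65535.0


def compute_features(
    image_or_stack: Raster | ChannelStack, feature_config: FeatureConfig
) -> ChannelStack:
    """Compute the configured filter bank as a named :class:`ChannelStack`.

    Channel naming is deterministic: ``<source>:<filter>:<sigma-or-radius>``
    (``<source>:raw`` for the passthrough channel in IF mode).
    """
    cfg = feature_config
    out_ch: list[Raster] = []
    out_names: list[str] = []
    if cfg.mode == "imc":
        if not isinstance(image_or_stack, ChannelStack):
            raise TypeError("imc feature mode expects a ChannelStack of training channels")
        stack = image_or_stack
        for raster, cname in zip(stack.channels, stack.channel_names):
            img = scale_to_16bit(
                np.asarray(raster.values, dtype=np.float64), cfg.imc_scale_percentiles
            )
            for filt in _IMC_FILTER_FAMILY:
                for sigma in cfg.imc_sigmas:
                    plane = _apply_filter(img, filt, sigma)
                    out_ch.append(Raster(plane, raster.pixel_size_um))
                    out_names.append(f"{cname}:{filt}:{sigma:g}")
    else:
        if not isinstance(image_or_stack, Raster):
            raise TypeError("if feature mode expects a single nuclear Raster")
        raster = image_or_stack
        src = raster.name or "dapi"
        img = np.asarray(raster.values, dtype=np.float64)  # raw intensities, no rescaling
        if cfg.include_raw:
            out_ch.append(Raster(img.copy(), raster.pixel_size_um))
            out_names.append(f"{src}:raw")
        for filt, sigmas in cfg.if_features:
            for sigma in sigmas:
                out_ch.append(Raster(_apply_filter(img, filt, sigma), raster.pixel_size_um))
                out_names.append(f"{src}:{filt}:{sigma:g}")
        for filt, radii in cfg.if_morphology:
            for r in radii:
                out_ch.append(Raster(_apply_filter(img, filt, r), raster.pixel_size_um))
                out_names.append(f"{src}:{filt}:{r:g}")
        if cfg.post_feature_smoothing_sigma > 0:
            s = cfg.post_feature_smoothing_sigma
            out_ch = [
                Raster(ndimage.gaussian_filter(r.values, s), r.pixel_size_um) for r in out_ch
            ]
    for r, n in zip(out_ch, out_names):
        r.name = n
    return ChannelStack(out_ch, out_names)


@dataclass
class PixelClassifier:
    model: RandomForestClassifier
    feature_config: FeatureConfig
    feature_names: list[str]
    class_names: list[str]
    training_summary: dict

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @staticmethod
    def load(path: str | Path) -> "PixelClassifier":
        obj = pickle.loads(Path(path).read_bytes())
        if not isinstance(obj, PixelClassifier):
            raise TypeError(f"{path} does not contain a PixelClassifier")
        return obj


def train_classifier(
    features: ChannelStack,
    sparse_annotation: SparseAnnotation,
    n_trees: int = 100,
    seed: int = 0,
    feature_config: FeatureConfig | None = None,
) -> PixelClassifier:
    """Fit the ensemble on the annotated (scribbled) pixels only.

    Every class must have at least one annotated pixel; the fit is fixed by
    ``seed``.  The training summary records per-class pixel counts and the
    out-of-bag accuracy estimate.
    """
    scrib = sparse_annotation.scribbles
    if scrib.shape != features.shape:
        raise ValueError(
            f"annotation shape {scrib.shape} does not match feature shape {features.shape}"
        )
    counts = sparse_annotation.pixels_per_class()
    empty = [name for name, n in counts.items() if n == 0]
    if empty:
        raise ValueError(f"no annotated pixels for class(es): {empty}")

    X_all = features.as_array()  # (C, H, W)
    mask = scrib > 0
    X = X_all[:, mask].T
    y = scrib[mask]
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=int(seed),
        oob_score=True,
        n_jobs=1,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    oob = float(getattr(model, "oob_score_", float("nan")))
    return PixelClassifier(
        model=model,
        feature_config=feature_config or FeatureConfig(mode="if"),
        feature_names=list(features.channel_names),
        class_names=list(sparse_annotation.class_names),
        training_summary={"n_pixels": counts, "oob_accuracy": oob},
    )


def predict_probability_map(
    classifier: PixelClassifier, features: ChannelStack
) -> ProbabilityMap:
    """Per-pixel class posteriors (averaged tree votes) as a ProbabilityMap."""
    if list(features.channel_names) != list(classifier.feature_names):
        raise ValueError(
            "feature stack does not match the classifier's training features;\n"
            f"expected: {classifier.feature_names}\nreceived: {list(features.channel_names)}"
        )
    X = features.as_array()
    C, H, W = X.shape
    flat = X.reshape(C, H * W).T
    # chunk rows to bound the predict_proba working set
    probs = np.empty((H * W, len(classifier.class_names)), dtype=np.float64)
    step = 1_000_000
    for start in range(0, flat.shape[0], step):
        probs[start : start + step] = classifier.model.predict_proba(flat[start : start + step])
    probs /= probs.sum(axis=1, keepdims=True)
    rasters = [
        Raster(probs[:, k].reshape(H, W), features.pixel_size_um, name=name)
        for k, name in enumerate(classifier.class_names)
    ]
    return ProbabilityMap(rasters, list(classifier.class_names))


def imc_class_reduce(prob_map_5class: ProbabilityMap) -> dict[str, Raster]:
    """Collapse the 5 IMC classes to nuclear / membrane / background.

    nuclear = non-epithelial nuclei + epithelial nuclei; membrane =
    non-epithelial membranes + epithelial cytoplasm/membrane; background
    passes through.  Probability mass is preserved.
    """
    if list(prob_map_5class.class_names) != IMC_CLASSES:
        raise ValueError(
            f"expected the 5 IMC classes {IMC_CLASSES}, got {list(prob_map_5class.class_names)}"
        )
    px = prob_map_5class.pixel_size_um
    arr = prob_map_5class.as_array()
    nuclear = arr[1] + arr[3]
    membrane = arr[0] + arr[2]
    background = arr[4]
    return {
        "nuclear": Raster(nuclear, px, name="nuclear"),
        "membrane": Raster(membrane, px, name="membrane"),
        "background": Raster(background, px, name="background"),
    }
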