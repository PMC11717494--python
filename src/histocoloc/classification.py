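"""Nine-class cell classification from image patches.

Each detected cell is classified from a 51 x 51 pixel patch (at the
0.44 μm/pixel working resolution) centred on its detected position and
resized to 224 x 224 pixels.  The classifier emits a probability for each
of the eight cell types plus "unknown"; the cell takes the argmax label
unless the winning probability is strictly below the 50% confidence
threshold, in which case it is reassigned to "unknown".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import resize

from .detection import DetectedCellSet
from .vocab import LABELS, UNKNOWN, UNKNOWN_THRESHOLD, WORKING_RESOLUTION_UM_PER_PX, prob_columns


@dataclass(frozen=True)
class ClassifierSpec:
    patch_edge: int = 51
    resize_edge: int = 224
    working_resolution: float = WORKING_RESOLUTION_UM_PER_PX
    unknown_threshold: float = UNKNOWN_THRESHOLD
    vocabulary: tuple[str, ...] = LABELS

    def __post_init__(self) -> None:
        if len(self.vocabulary) != 9:
            raise ValueError("vocabulary must have 9 labels (8 types + unknown)")
        if not 0.0 < self.unknown_threshold < 1.0:
            raise ValueError("unknown_threshold must be in (0, 1)")


# ---------------------------------------------------------------------------
# patch extraction
# ---------------------------------------------------------------------------


def extract_patch(
    image: np.ndarray, cell_point_px: tuple[float, float], spec: ClassifierSpec | None = None
) -> np.ndarray:
    """Cut the patch_edge^2 patch centred on a detected cell and resize it.

    ``cell_point_px`` is (x, y) in pixels; it must lie inside the image.
    Off-image patch regions are mirror-padded before the bilinear resize
    to ``resize_edge``.  Returns a float array in [0, 1], H x W (x 3).
    """
    spec = spec or ClassifierSpec()
    img = np.asarray(image, dtype=float)
    if img.max() > 1.0:
        img = img / 255.0
    h, w = img.shape[:2]
    x, y = cell_point_px
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError(f"cell point ({x}, {y}) outside {h}x{w} image")
    half = spec.patch_edge // 2
    cx, cy = int(round(x)), int(round(y))
    pad_spec = ((half, half), (half, half)) + (((0, 0),) if img.ndim == 3 else ())
    padded = np.pad(img, pad_spec, mode="reflect")
    patch = padded[cy : cy + spec.patch_edge, cx : cx + spec.patch_edge]
    out_shape = (spec.resize_edge, spec.resize_edge) + patch.shape[2:]
    return resize(patch, out_shape, order=1, preserve_range=True, anti_aliasing=False)


# ---------------------------------------------------------------------------
# the unknown rule
# ---------------------------------------------------------------------------


def apply_unknown_rule(probs: np.ndarray, spec: ClassifierSpec | None = None) -> str:
    """Label for a 9-class probability vector.

    Returns the argmax label (ties broken by vocabulary order) unless the
    maximum probability is strictly below the confidence threshold, in
    which case the cell is reassigned to "unknown".
    """
    spec = spec or ClassifierSpec()
    p = np.asarray(probs, dtype=float)
    if p.shape != (9,):
        raise ValueError("expected a 9-class probability vector")
    if (p < 0).any() or (p > 1).any() or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("probabilities must be in [0, 1] and sum to 1 (tol 1e-6)")
    k = int(np.argmax(p))  # argmax takes the first maximum: vocabulary order
    if p[k] < spec.unknown_threshold:
        return UNKNOWN
    return spec.vocabulary[k]


# ---------------------------------------------------------------------------
# toy classifier
# ---------------------------------------------------------------------------


class _FeatureGrid:
    """Precomputed pixel grids for rotation-invariant nucleus features."""

    def __init__(self, edge: int):
        self.edge = edge
        yy, xx = np.mgrid[0:edge, 0:edge].astype(float)
        c = (edge - 1) / 2.0
        self.xx, self.yy = xx, yy
        self.rr = np.sqrt((xx - c) ** 2 + (yy - c) ** 2)
        # Gaussian focus on the central nucleus (~45/224 of the patch edge)
        self.gw = np.exp(-self.rr**2 / (2 * (0.2 * edge) ** 2))
        ring_frac = [(0, 12), (12, 24), (24, 36), (36, 50), (50, 70), (70, 95), (95, 130)]
        self.ring_masks = [
            (self.rr >= a * edge / 224) & (self.rr < b * edge / 224) for a, b in ring_frac
        ]
        self.centre = self.rr < 70 * edge / 224


_GRIDS: dict[int, _FeatureGrid] = {}


def _patch_features(patch224: np.ndarray) -> np.ndarray:
    """Rotation-invariant features of one resized patch.

    Darkness-weighted mass, second-moment scale and elongation, mean
    chromatin colour, peak darkness and texture of the central nucleus,
    plus a 7-ring radial darkness profile (16 values).  Invariance to
    nucleus orientation is what lets a small model separate the spindle
    types that a raw-pixel representation confuses.
    """
    p = np.asarray(patch224, dtype=float)
    if p.ndim == 2:
        p = np.repeat(p[:, :, None], 3, axis=2)
    g = _GRIDS.setdefault(p.shape[0], _FeatureGrid(p.shape[0]))
    d = 1.0 - p.mean(axis=2)
    wd = g.gw * np.clip(d - 0.12, 0.0, None)
    m = wd.sum()
    f = [m / 1000.0]
    if m > 1e-6:
        mx, my = (wd * g.xx).sum() / m, (wd * g.yy).sum() / m
        cxx = (wd * (g.xx - mx) ** 2).sum() / m
        cyy = (wd * (g.yy - my) ** 2).sum() / m
        cxy = (wd * (g.xx - mx) * (g.yy - my)).sum() / m
        tr, det = cxx + cyy, cxx * cyy - cxy * cxy
        disc = max(tr * tr / 4 - det, 0.0) ** 0.5
        l1, l2 = tr / 2 + disc, max(tr / 2 - disc, 1e-9)
        f += [np.sqrt(l1) / 10, np.sqrt(l2) / 10, np.sqrt(l2 / l1)]
        f += [(wd * p[:, :, ch]).sum() / m for ch in range(3)]
        f += [float(np.percentile(d[g.centre], 97)), float(d[g.centre].std())]
    else:
        f += [0.0, 0.0, 1.0, p[:, :, 0].mean(), p[:, :, 1].mean(), p[:, :, 2].mean(), 0.0, 0.0]
    f += [float(d[msk].mean()) for msk in g.ring_masks]
    return np.asarray(f)


@dataclass
class ToyCellClassifier:
    """Gradient-boosted classifier over rotation-invariant patch features.

    Honours the resized-patch -> 9-class-probabilities contract; classes
    never seen at training time get probability 0.
    """

    spec: ClassifierSpec
    model: object  # sklearn classifier with predict_proba
    classes_: tuple[str, ...]  # training classes, subset of the vocabulary

    def predict_proba(self, patches224: "np.ndarray | list[np.ndarray]") -> np.ndarray:
        """(n, 9) probability matrix in vocabulary order, rows summing to 1."""
        feats = np.stack([_patch_features(p) for p in patches224])
        raw = self.model.predict_proba(feats)
        out = np.zeros((len(feats), 9))
        for j, cls in enumerate(self.classes_):
            out[:, self.spec.vocabulary.index(cls)] = raw[:, j]
        # guard against numerical drift; training classes always sum to 1
        out /= out.sum(axis=1, keepdims=True)
        return out


def train_toy_classifier(
    annotations: list[tuple[np.ndarray, tuple[float, float], str]],
    spec: ClassifierSpec | None = None,
    seed: int = 0,
) -> ToyCellClassifier:
    """Fit the stand-in classifier from (image, point_px, type) annotations.

    Requires at least 20 annotations spanning at least 2 classes.
    Deterministic given ``seed``.
    """
    from sklearn.ensemble import HistGradientBoostingClassifier

    spec = spec or ClassifierSpec()
    if len(annotations) < 20:
        raise ValueError("need >= 20 annotations")
    labels = [a[2] for a in annotations]
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes in the annotations")
    for cls in classes:
        if cls not in spec.vocabulary:
            raise ValueError(f"annotation type {cls!r} not in vocabulary")

    X = np.stack(
        [_patch_features(extract_patch(img, pt, spec)) for img, pt, _ in annotations]
    )
    model = HistGradientBoostingClassifier(random_state=seed)
    model.fit(X, labels)
    return ToyCellClassifier(spec=spec, model=model, classes_=tuple(model.classes_))


# ---------------------------------------------------------------------------
# classification of detected cells
# ---------------------------------------------------------------------------


def classify_cells(
    image: np.ndarray,
    points: DetectedCellSet,
    model: ToyCellClassifier,
    spec: ClassifierSpec | None = None,
) -> pd.DataFrame:
    """Classify every detected cell in an image.

    Returns the classified cell table: one row per detected point with
    x_um, y_um, cell_type (after the unknown rule) and the nine
    probability columns.  An empty point set gives an empty table.
    """
    spec = spec or (model.spec if model is not None else ClassifierSpec())
    cols = ["x_um", "y_um", "cell_type"] + prob_columns()
    if len(points) == 0:
        return pd.DataFrame(columns=cols)
    patches = [extract_patch(image, tuple(pt), spec) for pt in points.coords_px]
    probs = model.predict_proba(patches)
    labels = [apply_unknown_rule(p, spec) for p in probs]
    um = points.coords_um
    out = pd.DataFrame({"x_um": um[:, 0], "y_um": um[:, 1], "cell_type": labels})
    for j, col in enumerate(prob_columns()):
        out[col] = probs[:, j]
    return out
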