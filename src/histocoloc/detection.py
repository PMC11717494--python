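"""Nucleus detection: tiled probability-map assembly and peak extraction.

A detector model receives a 31 x 31 pixel image patch at the 0.44 μm/pixel
working resolution and emits an 11 x 11 tile of nucleus-presence
probabilities for the patch centre.  Sliding the model over the image and
averaging overlapping tiles yields a full-frame probability map; peaks of
that map, merged by proximity, are the detected cell positions.

The peak extractor thresholds the map, takes 8-connected local maxima as
candidates, links candidates closer than ``min_separation`` into connected
components, and emits one intensity-weighted centroid per component
(repeating the merge until all centroids respect the separation).  This is
a deterministic, checkable reading of collapsing cliques of clustered
high-intensity pixels into single cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .vocab import WORKING_RESOLUTION_UM_PER_PX


@dataclass(frozen=True)
class DetectorPatchSpec:
    input_edge: int = 31
    output_edge: int = 11
    working_resolution: float = WORKING_RESOLUTION_UM_PER_PX
    # Output tiles tile the frame exactly at stride = output_edge (11); the
    # default of 4 overlaps tiles so averaging sharpens peak localisation.
    stride: int = 4

    def __post_init__(self) -> None:
        if self.output_edge > self.input_edge:
            raise ValueError("output_edge must be <= input_edge")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.working_resolution <= 0:
            raise ValueError("working_resolution must be > 0")


@dataclass(frozen=True)
class PeakParams:
    prob_threshold: float = 0.5
    min_separation: int = 6  # px, ~2.6 μm at 0.44 μm/px

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob_threshold <= 1.0:
            raise ValueError("prob_threshold must be in [0, 1]")
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1")


@dataclass
class DetectedCellSet:
    """Detected cell centres, (n, 2) float array of (x, y) pixel coords."""

    coords_px: np.ndarray
    resolution: float = WORKING_RESOLUTION_UM_PER_PX

    def __post_init__(self) -> None:
        self.coords_px = np.asarray(self.coords_px, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.coords_px)

    @property
    def coords_um(self) -> np.ndarray:
        return self.coords_px * self.resolution


# ---------------------------------------------------------------------------
# probability-map assembly
# ---------------------------------------------------------------------------


def assemble_probability_map(
    tile_outputs: list[tuple[tuple[int, int], np.ndarray]],
    image_shape: tuple[int, int],
    spec: DetectorPatchSpec | None = None,
) -> np.ndarray:
    """Arrange detector output tiles into a full-frame probability map.

    ``tile_outputs`` holds ``((row, col), tile)`` pairs where (row, col) is
    the tile's top-left pixel in the image frame.  Overlapping
    contributions are averaged; pixels covered by no tile are 0.
    """
    spec = spec or DetectorPatchSpec()
    h, w = image_shape
    acc = np.zeros((h, w), dtype=float)
    cnt = np.zeros((h, w), dtype=float)
    for (r, c), tile in tile_outputs:
        tile = np.asarray(tile, dtype=float)
        th, tw = tile.shape
        if r < 0 or c < 0 or r + th > h or c + tw > w:
            raise ValueError(f"tile at ({r}, {c}) extends outside the {h}x{w} frame")
        if tile.min() < 0.0 or tile.max() > 1.0:
            raise ValueError("tile values must lie in [0, 1]")
        acc[r : r + th, c : c + tw] += tile
        cnt[r : r + th, c : c + tw] += 1.0
    covered = cnt > 0
    out = np.zeros((h, w), dtype=float)
    out[covered] = acc[covered] / cnt[covered]
    return out


# ---------------------------------------------------------------------------
# peak extraction
# ---------------------------------------------------------------------------


def _merge_candidates(xy: np.ndarray, weights: np.ndarray, min_sep: float) -> np.ndarray:
    """Link points closer than min_sep into components; one weighted
    centroid each; repeat until all centroids are >= min_sep apart."""
    pts, wts = xy, weights
    for _ in range(100):
        if len(pts) <= 1:
            return pts
        tree = cKDTree(pts)
        pairs = tree.query_pairs(min_sep - 1e-9, output_type="ndarray")
        if len(pairs) == 0:
            return pts
        parent = np.arange(len(pts))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b in pairs:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
        roots = np.array([find(i) for i in range(len(pts))])
        uniq, inv = np.unique(roots, return_inverse=True)
        new_pts = np.zeros((len(uniq), 2))
        new_wts = np.zeros(len(uniq))
        np.add.at(new_wts, inv, wts)
        np.add.at(new_pts, (inv, 0), wts * pts[:, 0])
        np.add.at(new_pts, (inv, 1), wts * pts[:, 1])
        new_pts /= new_wts[:, None]
        pts, wts = new_pts, new_wts
    return pts


def detect_peaks(prob_map: np.ndarray, params: PeakParams | None = None) -> DetectedCellSet:
    """Extract detected cell points from a nucleus probability map.

    Candidates are supra-threshold 8-connected local maxima (plateaus
    admit all their pixels; the subsequent proximity merge collapses
    them).  Candidates within ``min_separation`` of each other are merged
    into intensity-weighted centroids, transitively, until the returned
    points are pairwise at least ``min_separation`` apart.
    """
    params = params or PeakParams()
    m = np.asarray(prob_map, dtype=float)
    if m.size == 0:
        return DetectedCellSet(np.empty((0, 2)))
    local_max = m == ndimage.maximum_filter(m, size=3, mode="nearest")
    cand = local_max & (m > params.prob_threshold)
    rr, cc = np.nonzero(cand)
    if len(rr) == 0:
        return DetectedCellSet(np.empty((0, 2)))
    xy = np.stack([cc.astype(float), rr.astype(float)], axis=1)  # (x, y)
    merged = _merge_candidates(xy, m[rr, cc], float(params.min_separation))
    return DetectedCellSet(merged)


# ---------------------------------------------------------------------------
# trainable toy detector
# ---------------------------------------------------------------------------


def _to_gray(image: np.ndarray) -> np.ndarray:
    """Darkness map in [0, 1]: 1 at black nuclei, 0 at white background."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.max() > 1.0:
        img = img / 255.0
    return 1.0 - img


def _target_map(shape: tuple[int, int], truth_px: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Per-pixel nucleus-presence target: max of Gaussian bumps at truth
    points (amplitude 1, sd ``sigma`` pixels)."""
    h, w = shape
    out = np.zeros((h, w))
    r = int(np.ceil(3.5 * sigma))
    for x, y in np.asarray(truth_px, dtype=float):
        cx, cy = x, y
        x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
        y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        bump = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2)))
        out[y0:y1, x0:x1] = np.maximum(out[y0:y1, x0:x1], bump)
    return out


@dataclass
class ToyDetector:
    """Small MLP patch-to-tile detector honouring the 31->11 contract.

    A one-hidden-layer perceptron regresses the central 11 x 11 window of
    a Gaussian-bump nucleus-presence target map from the flattened patch
    darkness, followed by an output gain calibrated on the training peaks
    and clipping to [0, 1].
    """

    spec: DetectorPatchSpec
    model: object  # sklearn regressor with .predict
    gain: float = 1.0

    def predict_tiles(self, patches: np.ndarray) -> np.ndarray:
        """Map (n, input_edge, input_edge) darkness patches to (n,
        output_edge, output_edge) probability tiles in [0, 1]."""
        e = self.spec.output_edge
        pred = self.model.predict(np.asarray(patches).reshape(len(patches), -1)) * self.gain
        return np.clip(pred, 0.0, 1.0).reshape(-1, e, e)

    def predict_tile(self, patch: np.ndarray) -> np.ndarray:
        return self.predict_tiles(np.asarray(patch)[None])[0]


def _extract_patches(gray: np.ndarray, centres_rc: np.ndarray, edge: int) -> np.ndarray:
    half = edge // 2
    padded = np.pad(gray, half, mode="reflect")
    out = np.empty((len(centres_rc), edge, edge))
    for i, (r, c) in enumerate(centres_rc):
        out[i] = padded[r : r + edge, c : c + edge]
    return out


def train_toy_detector(
    images: list[np.ndarray],
    truth_points_px: list[np.ndarray],
    spec: DetectorPatchSpec | None = None,
    seed: int = 0,
    samples_per_image: int = 400,
    hidden: int = 128,
    max_iter: int = 250,
    target_sigma: float = 2.0,
) -> ToyDetector:
    """Fit the stand-in detector on rendered images with known nucleus centres.

    Training pairs are (31 x 31 darkness patch, central 11 x 11 window of
    the Gaussian-bump target map), sampled at nucleus centres, at jittered
    copies of the centres (±4 px, so near-misses are localised), and at
    random positions.  The output gain is calibrated so the median
    training peak sits at 0.95.  Deterministic given ``seed``.
    """
    from sklearn.neural_network import MLPRegressor

    spec = spec or DetectorPatchSpec()
    n_truth = sum(len(t) for t in truth_points_px)
    if len(images) == 0 or n_truth == 0:
        raise ValueError("need at least one image with at least one truth point")
    if n_truth < 10:
        raise ValueError("need >= 10 truth points to train")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))

    feats, targs, n_pos = [], [], []
    half_out = spec.output_edge // 2
    for img, truth in zip(images, truth_points_px):
        gray = _to_gray(img)
        tmap = _target_map(gray.shape, truth, sigma=target_sigma)
        h, w = gray.shape
        truth = np.asarray(truth, dtype=float).reshape(-1, 2)
        pos_rc = np.stack(
            [np.clip(np.round(truth[:, 1]), 0, h - 1), np.clip(np.round(truth[:, 0]), 0, w - 1)],
            axis=1,
        ).astype(int)
        jit_rc = np.clip(
            pos_rc + rng.integers(-4, 5, size=pos_rc.shape), 0, [h - 1, w - 1]
        )
        n_rand = max(samples_per_image, len(pos_rc))
        rand_rc = np.stack(
            [rng.integers(0, h, size=n_rand), rng.integers(0, w, size=n_rand)], axis=1
        )
        centres = np.concatenate([pos_rc, jit_rc, rand_rc])
        feats.append(_extract_patches(gray, centres, spec.input_edge))
        tpad = np.pad(tmap, half_out, mode="constant")
        tiles = np.empty((len(centres), spec.output_edge, spec.output_edge))
        for i, (r, c) in enumerate(centres):
            tiles[i] = tpad[r : r + spec.output_edge, c : c + spec.output_edge]
        targs.append(tiles)
        n_pos.append(len(pos_rc))

    X = np.concatenate(feats).reshape(-1, spec.input_edge**2)
    Y = np.concatenate(targs).reshape(len(X), -1)
    model = MLPRegressor(hidden_layer_sizes=(hidden,), random_state=seed, max_iter=max_iter)
    model.fit(X, Y)

    det = ToyDetector(spec=spec, model=model, gain=1.0)
    # Calibrate output gain so the median predicted peak at a true nucleus
    # centre sits at ~0.95 (regression shrinkage pulls raw peaks below 1).
    pos_mask = np.zeros(len(X), dtype=bool)
    off = 0
    for f, npos in zip(feats, n_pos):
        pos_mask[off : off + npos] = True
        off += len(f)
    centre_idx = half_out * spec.output_edge + half_out
    raw_peaks = model.predict(X[pos_mask])[:, centre_idx]
    med = float(np.median(raw_peaks))
    if med > 1e-6:
        det.gain = min(0.95 / med, 3.0)
    return det


# ---------------------------------------------------------------------------
# sliding-window application
# ---------------------------------------------------------------------------


def run_detector(
    image: np.ndarray,
    model: ToyDetector,
    spec: DetectorPatchSpec | None = None,
    params: PeakParams | None = None,
) -> DetectedCellSet:
    """Detect cells in an image: sliding-window model application, tile
    assembly, peak extraction.

    The image is mirror-padded so that output tiles cover every pixel;
    the image must be at least ``input_edge`` on each side.
    """
    spec = spec or (model.spec if model is not None else DetectorPatchSpec())
    params = params or PeakParams()
    gray = _to_gray(image)
    h, w = gray.shape
    if h < spec.input_edge or w < spec.input_edge:
        raise ValueError(f"image {h}x{w} smaller than detector input {spec.input_edge}")

    half_in = spec.input_edge // 2
    half_out = spec.output_edge // 2
    pad = half_in
    padded = np.pad(gray, pad, mode="reflect")

    # output tile origins (in the unpadded frame), covering [0, h) x [0, w)
    def origins(extent: int) -> np.ndarray:
        last = extent - spec.output_edge
        o = np.arange(0, last + 1, spec.stride)
        if o[-1] != last:
            o = np.append(o, last)
        return o

    rows, cols = origins(h), origins(w)
    patches = []
    tile_origins = []
    for r in rows:
        for c in cols:
            # patch centred on the output tile centre
            pr = r + half_out - half_in + pad
            pc = c + half_out - half_in + pad
            patches.append(padded[pr : pr + spec.input_edge, pc : pc + spec.input_edge])
            tile_origins.append((int(r), int(c)))
    tiles = model.predict_tiles(np.asarray(patches))
    pmap = assemble_probability_map(
        list(zip(tile_origins, tiles)), (h, w), spec
    )
    det = detect_peaks(pmap, params)
    det.resolution = spec.working_resolution
    return det


# ---------------------------------------------------------------------------
# evaluation helper
# ---------------------------------------------------------------------------


def match_detections(
    detected_px: np.ndarray, truth_px: np.ndarray, tol_px: float = 3.0
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detections to truth points.

    Pairs are matched closest-first within ``tol_px``.  Returns
    (true_positives, false_positives, false_negatives).
    """
    det = np.asarray(detected_px, dtype=float).reshape(-1, 2)
    tru = np.asarray(truth_px, dtype=float).reshape(-1, 2)
    if len(det) == 0 or len(tru) == 0:
        return 0, len(det), len(tru)
    d = np.sqrt(((det[:, None, :] - tru[None, :, :]) ** 2).sum(-1))
    pairs = [(d[i, j], i, j) for i in range(len(det)) for j in range(len(tru)) if d[i, j] <= tol_px]
    pairs.sort()
    used_d, used_t = set(), set()
    tp = 0
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        tp += 1
    return tp, len(det) - tp, len(tru) - tp


def detection_f1(detected_px: np.ndarray, truth_px: np.ndarray, tol_px: float = 3.0) -> float:
    tp, fp, fn = match_detections(detected_px, truth_px, tol_px)
    if tp == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)
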