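"""Cross-modality concordance of H&E cell labels against mIF marker tables.

The validation path mirrors how a multiplexed-immunofluorescence section
is used to check an H&E classifier: mIF cells are typed by threshold
gating of their marker intensities (epithelial <- pan-cytokeratin,
lymphocyte <- any of CD3e/CD4/CD8/CD20, macrophage <- CD68, endothelial <-
CD31); the two point sets are aligned by an automated registration
(coarse grid search over flip/rotation/scale on rasterised point-density
images, then trimmed iterative-closest-point refinement); the common
frame is divided into square windows (default 1,887 μm, with a manual
exclusion mask for artefact windows) and per-type counts per window are
compared with Spearman correlation and a linear fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats
from scipy.spatial import cKDTree

from .transforms import PlanarTransform, compose_flip_then, similarity_from_matches

logger = logging.getLogger(__name__)

#: Priority order used when a cell satisfies several gate signatures.
GATE_PRIORITY: tuple[str, ...] = ("epithelial", "endothelial", "macrophage", "lymphocyte")


@dataclass(frozen=True)
class GatingPanel:
    """Marker signatures and thresholds for typing mIF cells.

    A cell receives a type when any of that type's signature markers
    exceeds its threshold; conflicts are resolved by
    :data:`GATE_PRIORITY`.  The default panel follows the standard
    colorectal validation markers.
    """

    signatures: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "epithelial": ("pan_cytokeratin",),
            "lymphocyte": ("CD3e", "CD4", "CD8", "CD20"),
            "macrophage": ("CD68",),
            "endothelial": ("CD31",),
        }
    )
    thresholds: dict[str, float] = field(default_factory=dict)
    default_threshold: float = 1.0

    def __post_init__(self) -> None:
        for t, markers in self.signatures.items():
            if len(markers) == 0:
                raise ValueError(f"type {t!r} has an empty marker signature")
        if self.default_threshold <= 0 or any(v <= 0 for v in self.thresholds.values()):
            raise ValueError("thresholds must be > 0")

    def threshold(self, marker: str) -> float:
        return self.thresholds.get(marker, self.default_threshold)


@dataclass(frozen=True)
class WindowSpec:
    window_edge_um: float = 1887.0
    excluded: frozenset[tuple[int, int]] = frozenset()

    def __post_init__(self) -> None:
        if self.window_edge_um <= 0:
            raise ValueError("window_edge_um must be > 0")


@dataclass
class RegistrationResult:
    transform: PlanarTransform
    residual_rms_um: float
    residual_median_um: float
    n_matched: int
    coarse_score: float


@dataclass
class ConcordanceResult:
    """Per-type windowed count concordance between two modalities."""

    paired_counts: pd.DataFrame  # window_ix, window_iy, cell_type, count_a, count_b
    stats: pd.DataFrame  # cell_type, rho, p, slope, slope_ci_low, slope_ci_high, n_windows


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------


def gate_cells(marker_table: pd.DataFrame, panel: GatingPanel | None = None) -> pd.DataFrame:
    """Type mIF cells by threshold gating of their marker intensities.

    Returns a copy of the table with a ``gated_type`` column; cells
    matching no signature get the empty string.  Cells matching several
    signatures take the highest-priority type (conflict count logged).
    """
    panel = panel or GatingPanel()
    all_markers = {m for sig in panel.signatures.values() for m in sig}
    missing = all_markers - set(marker_table.columns)
    if missing:
        raise ValueError(f"marker columns missing from table: {sorted(missing)}")

    positive = {}
    for t, markers in panel.signatures.items():
        pos = np.zeros(len(marker_table), dtype=bool)
        for m in markers:
            pos |= marker_table[m].to_numpy(dtype=float) > panel.threshold(m)
        positive[t] = pos

    order = [t for t in GATE_PRIORITY if t in panel.signatures] + [
        t for t in panel.signatures if t not in GATE_PRIORITY
    ]
    gated = np.full(len(marker_table), "", dtype=object)
    assigned = np.zeros(len(marker_table), dtype=bool)
    n_conflicts = 0
    for t in order:
        hit = positive[t]
        n_conflicts += int((hit & assigned).sum())
        take = hit & ~assigned
        gated[take] = t
        assigned |= hit
    if n_conflicts:
        logger.info("gating: %d cells matched multiple signatures (priority applied)",
                    n_conflicts)
    out = marker_table.copy()
    out["gated_type"] = gated
    return out


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------


def _rasterise(points: np.ndarray, origin: np.ndarray, shape: tuple[int, int],
               bin_um: float, smooth_bins: float) -> np.ndarray:
    ij = np.floor((points - origin) / bin_um).astype(int)
    ok = (ij[:, 0] >= 0) & (ij[:, 0] < shape[1]) & (ij[:, 1] >= 0) & (ij[:, 1] < shape[0])
    img = np.zeros(shape)
    np.add.at(img, (ij[ok, 1], ij[ok, 0]), 1.0)
    img = ndimage.gaussian_filter(img, smooth_bins)
    img -= img.mean()
    return img


def _coarse_search(
    pts_a: np.ndarray,
    pts_b: np.ndarray,
    rotations: np.ndarray,
    scales: np.ndarray,
    bin_um: float,
    smooth_bins: float,
) -> tuple[PlanarTransform, float]:
    """Grid search over flip x rotation x scale; the translation for each
    candidate comes from the peak of the density-image cross-correlation."""
    mins_b = pts_b.min(axis=0) - 2 * bin_um
    maxs_b = pts_b.max(axis=0) + 2 * bin_um
    shape_b = (
        int(np.ceil((maxs_b[1] - mins_b[1]) / bin_um)),
        int(np.ceil((maxs_b[0] - mins_b[0]) / bin_um)),
    )
    img_b = _rasterise(pts_b, mins_b, shape_b, bin_um, smooth_bins)

    best: tuple[float, PlanarTransform] | None = None
    for flip in (False, True):
        for rot in rotations:
            for sc in scales:
                cand = PlanarTransform(flip, float(rot), float(sc), (0.0, 0.0))
                moved = cand.apply(pts_a)
                mins_a = moved.min(axis=0) - 2 * bin_um
                shape_a = (
                    int(np.ceil((moved[:, 1].max() - mins_a[1]) / bin_um)) + 4,
                    int(np.ceil((moved[:, 0].max() - mins_a[0]) / bin_um)) + 4,
                )
                img_a = _rasterise(moved, mins_a, shape_a, bin_um, smooth_bins)
                corr = signal.fftconvolve(img_b, img_a[::-1, ::-1], mode="full")
                k = np.unravel_index(np.argmax(corr), corr.shape)
                score = float(corr[k])
                # peak at (r, c) means img_a origin sits at b-origin offset
                dr = k[0] - (img_a.shape[0] - 1)
                dc = k[1] - (img_a.shape[1] - 1)
                t = (
                    mins_b[0] + dc * bin_um - mins_a[0],
                    mins_b[1] + dr * bin_um - mins_a[1],
                )
                full = PlanarTransform(flip, float(rot), float(sc), t)
                if best is None or score > best[0]:
                    best = (score, full)
    assert best is not None
    return best[1], best[0]


def _icp_refine(
    pts_a: np.ndarray,
    pts_b: np.ndarray,
    init: PlanarTransform,
    n_iter: int = 30,
    trim: float = 0.8,
) -> tuple[PlanarTransform, np.ndarray]:
    """Trimmed iterative closest point with a similarity model.

    Keeps the best ``trim`` fraction of nearest-neighbour matches each
    iteration (robustness to outliers and dropout).  The flip is frozen
    at the initial estimate.  Returns the refined transform and the final
    trimmed residuals.
    """
    flip = init.flip
    flipped_a = PlanarTransform(flip=flip).apply(pts_a)
    sim = PlanarTransform(False, init.rotation_deg, init.scale, init.translation)
    tree_b = cKDTree(pts_b)
    res = np.array([np.inf])
    for _ in range(n_iter):
        moved = sim.apply(flipped_a)
        dist, idx = tree_b.query(moved)
        keep = np.argsort(dist)[: max(int(trim * len(dist)), 3)]
        new_sim = similarity_from_matches(flipped_a[keep], pts_b[idx[keep]])
        if (
            abs(new_sim.rotation_deg - sim.rotation_deg) < 1e-9
            and np.allclose(new_sim.translation, sim.translation, atol=1e-9)
            and abs(new_sim.scale - sim.scale) < 1e-12
        ):
            sim = new_sim
            res = dist[keep]
            break
        sim = new_sim
        res = dist[keep]
    return compose_flip_then(sim, flip), res


def estimate_registration(
    points_a: np.ndarray,
    points_b: np.ndarray,
    rotation_range_deg: float = 20.0,
    rotation_step_deg: float = 2.0,
    scales: tuple[float, ...] = (1.0,),
    bin_um: float = 10.0,
    smooth_bins: float = 1.5,
) -> RegistrationResult:
    """Estimate the flip + similarity transform mapping point set A onto B.

    Two stages: a coarse grid search over {flip} x rotation x scale scored
    by cross-correlation of smoothed point-density rasters (which also
    yields the translation), then trimmed ICP refinement of rotation,
    scale and translation at full coordinate precision.
    """
    pts_a = np.asarray(points_a, dtype=float).reshape(-1, 2)
    pts_b = np.asarray(points_b, dtype=float).reshape(-1, 2)
    if len(pts_a) < 20 or len(pts_b) < 20:
        raise ValueError("registration needs >= 20 points in each set")
    for pts, name in ((pts_a, "A"), (pts_b, "B")):
        if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-6) < 2:
            raise ValueError(f"point set {name} is degenerate (collinear)")

    rotations = np.arange(-rotation_range_deg, rotation_range_deg + 1e-9, rotation_step_deg)
    coarse, score = _coarse_search(pts_a, pts_b, rotations, np.asarray(scales), bin_um, smooth_bins)
    refined, residuals = _icp_refine(pts_a, pts_b, coarse)
    return RegistrationResult(
        transform=refined,
        residual_rms_um=float(np.sqrt((residuals**2).mean())),
        residual_median_um=float(np.median(residuals)),
        n_matched=int(len(residuals)),
        coarse_score=score,
    )


# ---------------------------------------------------------------------------
# windowed counts
# ---------------------------------------------------------------------------


def window_counts(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    spec: WindowSpec | None = None,
    type_col_a: str = "cell_type",
    type_col_b: str = "gated_type",
    types: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-window per-type paired counts of two tables in a common frame.

    Windows are half-open squares of ``window_edge_um``, indexed from the
    minimum corner over both tables (a cell exactly on a boundary belongs
    to the higher-index window).  Excluded windows are dropped from both
    modalities.  Returns a long DataFrame: window_ix, window_iy,
    cell_type, count_a, count_b, covering every window in the joint
    bounding grid minus exclusions.
    """
    spec = spec or WindowSpec()
    if types is None:
        types = tuple(
            sorted(set(table_a[type_col_a].unique()) | set(table_b[type_col_b].unique()) - {""})
        )
        types = tuple(t for t in types if t)

    both = np.concatenate(
        [table_a[["x_um", "y_um"]].to_numpy(float), table_b[["x_um", "y_um"]].to_numpy(float)]
    )
    if len(both) == 0:
        return pd.DataFrame(
            columns=["window_ix", "window_iy", "cell_type", "count_a", "count_b"]
        )
    origin = both.min(axis=0)
    idx_max = np.floor((both.max(axis=0) - origin) / spec.window_edge_um).astype(int)
    nx, ny = idx_max[0] + 1, idx_max[1] + 1

    def counts(tab: pd.DataFrame, type_col: str) -> dict[str, np.ndarray]:
        out = {t: np.zeros((ny, nx), dtype=int) for t in types}
        if len(tab) == 0:
            return out
        ij = np.floor(
            (tab[["x_um", "y_um"]].to_numpy(float) - origin) / spec.window_edge_um
        ).astype(int)
        for t in types:
            sel = (tab[type_col] == t).to_numpy()
            np.add.at(out[t], (ij[sel, 1], ij[sel, 0]), 1)
        return out

    ca, cb = counts(table_a, type_col_a), counts(table_b, type_col_b)
    rows = []
    for iy in range(ny):
        for ix in range(nx):
            if (ix, iy) in spec.excluded:
                continue
            for t in types:
                rows.append(
                    {"window_ix": ix, "window_iy": iy, "cell_type": t,
                     "count_a": int(ca[t][iy, ix]), "count_b": int(cb[t][iy, ix])}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# concordance statistics
# ---------------------------------------------------------------------------


def concordance(paired_counts: pd.DataFrame) -> ConcordanceResult:
    """Spearman correlation and linear fit of paired per-window counts.

    One row of statistics per cell type: rank correlation (two-sided p)
    and the slope of the ordinary least-squares fit of modality-B counts
    on modality-A counts with its 95% CI.  Types with zero variance in
    either modality get rho = NaN (reported, not an error).
    """
    stats_rows = []
    for t, grp in paired_counts.groupby("cell_type"):
        a, b = grp.count_a.to_numpy(float), grp.count_b.to_numpy(float)
        if len(a) < 3:
            raise ValueError("concordance needs >= 3 windows")
        if a.std() == 0 or b.std() == 0:
            stats_rows.append(
                {"cell_type": t, "rho": np.nan, "p": np.nan, "slope": np.nan,
                 "slope_ci_low": np.nan, "slope_ci_high": np.nan, "n_windows": len(a)}
            )
            continue
        rho, p = stats.spearmanr(a, b)
        fit = stats.linregress(a, b)
        tcrit = stats.t.ppf(0.975, len(a) - 2)
        stats_rows.append(
            {
                "cell_type": t,
                "rho": float(rho),
                "p": float(p),
                "slope": float(fit.slope),
                "slope_ci_low": float(fit.slope - tcrit * fit.stderr),
                "slope_ci_high": float(fit.slope + tcrit * fit.stderr),
                "n_windows": len(a),
            }
        )
    return ConcordanceResult(paired_counts=paired_counts, stats=pd.DataFrame(stats_rows))
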