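"""Tumour-colocalisation metrics, patient aggregation and density maps.

A cell is *tumour-associated* if at least one cancer-epithelial cell lies
within the neighbourhood radius of its position (closed disc; default
44 μm, i.e. 100 px at the 0.44 μm/pixel working resolution).  Slide-level
counts of cancer cells and of tumour-associated lymphocytes, macrophages
and endothelial cells are aggregated into patient-level metrics by
averaging over the patient's slides; the endothelial/cancer ratio divides
the patient-level mean tumour-associated endothelial count by the
patient-level mean cancer count.

Density maps bin the slide into 88 x 88 μm regions (half-open bins) and
count cells of each type per bin; a ternary RGB rendering colours each
bin by the barycentric balance of three selected types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from .vocab import (
    CELL_TYPES,
    DEFAULT_RADIUS_UM,
    DENSITY_BIN_UM,
    SENSITIVITY_RADII_UM,
    TA_TYPES,
)


class UndefinedRatioError(ZeroDivisionError):
    """Raised when the endothelial/cancer ratio has a zero denominator."""


@dataclass(frozen=True)
class NeighbourhoodSpec:
    radius_um: float = DEFAULT_RADIUS_UM
    sensitivity_radii_um: tuple[float, ...] = SENSITIVITY_RADII_UM

    def __post_init__(self) -> None:
        if self.radius_um <= 0 or any(r <= 0 for r in self.sensitivity_radii_um):
            raise ValueError("radii must be > 0")


@dataclass(frozen=True)
class ColocalisationSummary:
    """Per-slide counts at a given neighbourhood radius."""

    slide_id: str
    radius_um: float
    cancer_count: int
    ta_lymphocyte_count: int
    ta_macrophage_count: int
    ta_endothelial_count: int
    total_counts: dict[str, int] = field(default_factory=dict)

    def ta_count(self, cell_type: str) -> int:
        return getattr(self, f"ta_{cell_type}_count")


@dataclass(frozen=True)
class PatientMetrics:
    """Patient-level means over slides plus the endothelial/cancer ratio."""

    patient_id: str
    n_slides: int
    mean_cancer_count: float
    mean_ta_lymphocyte_count: float
    mean_ta_macrophage_count: float
    mean_ta_endothelial_count: float
    endothelial_cancer_ratio: float


# ---------------------------------------------------------------------------
# colocalisation counts
# ---------------------------------------------------------------------------


def _validate_coords(df: pd.DataFrame) -> None:
    xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("non-finite coordinates in cell table")


def tumour_associated_counts(
    table: pd.DataFrame,
    spec: NeighbourhoodSpec | float | None = None,
    slide_id: str = "",
) -> ColocalisationSummary:
    """Count cancer cells and tumour-associated stromal cells on one slide.

    ``table`` is a classified cell table with columns x_um, y_um,
    cell_type.  For each of lymphocyte/macrophage/endothelial, a cell
    counts as tumour-associated if a cancer-epithelial cell lies within
    Euclidean distance <= radius.  "unknown" cells never enter any count;
    cancer cells are never counted among the stromal subgroups.
    """
    if isinstance(spec, (int, float)):
        spec = NeighbourhoodSpec(radius_um=float(spec))
    spec = spec or NeighbourhoodSpec()
    _validate_coords(table)

    cancer = table[table.cell_type == "cancer_epithelial"]
    cancer_xy = cancer[["x_um", "y_um"]].to_numpy(dtype=float)
    totals = table.cell_type.value_counts().to_dict()

    ta: dict[str, int] = {}
    if len(cancer_xy) == 0:
        ta = {t: 0 for t in TA_TYPES}
    else:
        tree = cKDTree(cancer_xy)
        for t in TA_TYPES:
            pts = table.loc[table.cell_type == t, ["x_um", "y_um"]].to_numpy(dtype=float)
            if len(pts) == 0:
                ta[t] = 0
                continue
            dist, _ = tree.query(pts, k=1)
            ta[t] = int((dist <= spec.radius_um).sum())

    return ColocalisationSummary(
        slide_id=slide_id,
        radius_um=spec.radius_um,
        cancer_count=int(len(cancer)),
        ta_lymphocyte_count=ta["lymphocyte"],
        ta_macrophage_count=ta["macrophage"],
        ta_endothelial_count=ta["endothelial"],
        total_counts={k: int(v) for k, v in totals.items()},
    )


def tumour_associated_counts_bruteforce(
    table: pd.DataFrame, radius_um: float = DEFAULT_RADIUS_UM, slide_id: str = ""
) -> ColocalisationSummary:
    """O(n^2) all-pairs oracle for :func:`tumour_associated_counts`."""
    _validate_coords(table)
    cancer_xy = table.loc[table.cell_type == "cancer_epithelial", ["x_um", "y_um"]].to_numpy(
        dtype=float
    )
    ta = {}
    for t in TA_TYPES:
        pts = table.loc[table.cell_type == t, ["x_um", "y_um"]].to_numpy(dtype=float)
        if len(pts) == 0 or len(cancer_xy) == 0:
            ta[t] = 0
            continue
        n = 0
        for p in pts:
            d2 = ((cancer_xy - p) ** 2).sum(axis=1)
            if (d2 <= radius_um**2).any():
                n += 1
        ta[t] = n
    return ColocalisationSummary(
        slide_id=slide_id,
        radius_um=radius_um,
        cancer_count=int(len(cancer_xy)),
        ta_lymphocyte_count=ta["lymphocyte"],
        ta_macrophage_count=ta["macrophage"],
        ta_endothelial_count=ta["endothelial"],
        total_counts=table.cell_type.value_counts().to_dict(),
    )


# ---------------------------------------------------------------------------
# patient aggregation
# ---------------------------------------------------------------------------


def endothelial_cancer_ratio(summaries: list[ColocalisationSummary]) -> float:
    """Patient-level endothelial/cancer ratio: mean tumour-associated
    endothelial count over slides divided by mean cancer count.

    Raises :class:`UndefinedRatioError` when the mean cancer count is 0.
    """
    if not summaries:
        raise ValueError("need at least one slide summary")
    mean_endo = float(np.mean([s.ta_endothelial_count for s in summaries]))
    mean_cancer = float(np.mean([s.cancer_count for s in summaries]))
    if mean_cancer == 0:
        raise UndefinedRatioError(
            "endothelial/cancer ratio undefined: patient-level mean cancer count is 0"
        )
    return mean_endo / mean_cancer


def aggregate_patient(
    summaries_by_patient: dict[str, list[ColocalisationSummary]],
) -> list[PatientMetrics]:
    """Aggregate slide summaries to patient-level metrics (arithmetic means)."""
    out = []
    for pid in sorted(summaries_by_patient):
        ss = summaries_by_patient[pid]
        if not ss:
            raise ValueError(f"patient {pid!r} has no slides")
        out.append(
            PatientMetrics(
                patient_id=pid,
                n_slides=len(ss),
                mean_cancer_count=float(np.mean([s.cancer_count for s in ss])),
                mean_ta_lymphocyte_count=float(np.mean([s.ta_lymphocyte_count for s in ss])),
                mean_ta_macrophage_count=float(np.mean([s.ta_macrophage_count for s in ss])),
                mean_ta_endothelial_count=float(np.mean([s.ta_endothelial_count for s in ss])),
                endothelial_cancer_ratio=endothelial_cancer_ratio(ss),
            )
        )
    return out


def patient_metrics_frame(metrics: list[PatientMetrics]) -> pd.DataFrame:
    return pd.DataFrame([m.__dict__ for m in metrics])


# ---------------------------------------------------------------------------
# radius sensitivity
# ---------------------------------------------------------------------------


def radius_sensitivity(
    tables: dict[str, pd.DataFrame],
    radii_um: tuple[float, ...] = (22.0, DEFAULT_RADIUS_UM, 88.0),
    reference_um: float = DEFAULT_RADIUS_UM,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recompute tumour-associated counts at several radii and correlate.

    Returns ``(counts, rho)``: per-slide per-radius counts, and the
    Spearman rank correlation of each alternative radius's per-slide
    counts against the reference radius, per cell type.
    """
    radii = tuple(float(r) for r in radii_um)
    if len(radii) < 2:
        raise ValueError("need at least two radii")
    if any(r <= 0 for r in radii):
        raise ValueError("radii must be > 0")
    if reference_um not in radii:
        raise ValueError("reference radius must be among the radii")

    rows = []
    for sid in sorted(tables):
        for r in radii:
            s = tumour_associated_counts(tables[sid], r, slide_id=sid)
            rows.append(
                {
                    "slide_id": sid,
                    "radius_um": r,
                    "cancer_count": s.cancer_count,
                    **{f"ta_{t}_count": s.ta_count(t) for t in TA_TYPES},
                }
            )
    counts = pd.DataFrame(rows)

    rho_rows = []
    ref = counts[counts.radius_um == reference_um].set_index("slide_id")
    for r in radii:
        if r == reference_um:
            continue
        alt = counts[counts.radius_um == r].set_index("slide_id")
        for t in TA_TYPES:
            a = ref.loc[sorted(tables), f"ta_{t}_count"]
            b = alt.loc[sorted(tables), f"ta_{t}_count"]
            rho, p = spearmanr(a, b)
            rho_rows.append(
                {"radius_um": r, "reference_um": reference_um, "cell_type": t,
                 "rho": float(rho), "p": float(p)}
            )
    return counts, pd.DataFrame(rho_rows)


# ---------------------------------------------------------------------------
# density maps
# ---------------------------------------------------------------------------


@dataclass
class DensityMap:
    """Per-bin per-type counts on a square grid.

    ``counts`` maps cell type -> (ny, nx) integer array; bin (i, j) covers
    the half-open square [j*b, (j+1)*b) x [i*b, (i+1)*b) in μm, origin at
    (0, 0), x = column, y = row.
    """

    counts: dict[str, np.ndarray]
    bin_edge_um: float
    shape: tuple[int, int]

    def total(self, cell_type: str) -> int:
        return int(self.counts[cell_type].sum()) if cell_type in self.counts else 0


def compute_density_map(
    table: pd.DataFrame,
    bin_edge_um: float = DENSITY_BIN_UM,
    extent_um: tuple[float, float] | None = None,
) -> DensityMap:
    """Bin a classified cell table into an 88 μm (by default) grid.

    ``extent_um`` (width, height) fixes the grid size; by default it is
    taken from the table's coordinate maxima.  Bins are half-open, so a
    cell at exactly a bin boundary belongs to the higher-index bin.
    """
    if bin_edge_um <= 0:
        raise ValueError("bin_edge_um must be > 0")
    _validate_coords(table) if len(table) else None
    if extent_um is None:
        if len(table) == 0:
            extent_um = (bin_edge_um, bin_edge_um)
        else:
            extent_um = (float(table.x_um.max()), float(table.y_um.max()))
    nx = max(1, int(np.floor(extent_um[0] / bin_edge_um)) + 1)
    ny = max(1, int(np.floor(extent_um[1] / bin_edge_um)) + 1)

    counts: dict[str, np.ndarray] = {}
    for t, grp in table.groupby("cell_type"):
        ix = np.floor(grp.x_um.to_numpy() / bin_edge_um).astype(int)
        iy = np.floor(grp.y_um.to_numpy() / bin_edge_um).astype(int)
        if (ix < 0).any() or (iy < 0).any() or (ix >= nx).any() or (iy >= ny).any():
            raise ValueError("cell outside the density-map extent")
        arr = np.zeros((ny, nx), dtype=int)
        np.add.at(arr, (iy, ix), 1)
        counts[str(t)] = arr
    return DensityMap(counts=counts, bin_edge_um=float(bin_edge_um), shape=(ny, nx))


#: Channel primaries for ternary rendering: first type -> red, second ->
#: green, third -> blue (pure colour at a simplex vertex).
_PRIMARIES = np.eye(3)


def render_density_map(dmap: DensityMap, triple: tuple[str, str, str]) -> np.ndarray:
    """Ternary RGB rendering of three cell types' per-bin balance.

    Each bin's colour is the barycentric mix of red/green/blue weighted by
    the three types' count shares; bins with none of the three types are
    white.  Returns a uint8 (ny, nx, 3) image.
    """
    if len(set(triple)) != 3:
        raise ValueError("triple must contain three distinct types")
    ny, nx = dmap.shape
    stack = np.stack(
        [dmap.counts.get(t, np.zeros((ny, nx), dtype=int)).astype(float) for t in triple]
    )
    total = stack.sum(axis=0)
    img = np.ones((ny, nx, 3))
    nz = total > 0
    for k in range(3):
        share = np.zeros((ny, nx))
        share[nz] = stack[k][nz] / total[nz]
        for ch in range(3):
            img[..., ch] = np.where(nz, img[..., ch] - share * (1 - _PRIMARIES[k, ch]), img[..., ch])
    return np.clip(img * 255, 0, 255).astype(np.uint8)
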