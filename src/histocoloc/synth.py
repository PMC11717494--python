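"""Synthetic colorectal-tissue generators with known ground truth.

Four generators cover the inputs the analysis pipeline consumes:

* :func:`simulate_slide` — a point pattern of the eight cell types, with
  cancer cells arranged in nest-like clusters and a tunable degree of
  stromal/immune infiltration into those nests.
* :func:`render_slide` — an H&E-like raster of the point pattern, one
  nucleus per cell, with type-distinct morphology (size, elongation,
  chromatin colour, texture) so a small classifier can separate them.
* :func:`simulate_cohort_survival` — exponential proportional-hazards
  progression times with a planted log hazard ratio between "high" and
  "low" metric groups, plus independent censoring.
* :func:`simulate_paired_mif` — a multiplex-immunofluorescence marker
  table for the same section, related to the H&E frame by an unknown
  flip + similarity transform, with positional noise, marker noise and
  detection dropout.

Every generator is a pure function of its parameters and seed.  A single
cohort seed can be expanded into per-component substreams with
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transforms import PlanarTransform
from .vocab import CELL_TYPES, WORKING_RESOLUTION_UM_PER_PX

STROMAL_TYPES: tuple[str, ...] = (
    "normal_epithelial",
    "fibroblast",
    "lymphocyte",
    "neutrophil",
    "macrophage",
    "endothelial",
    "myocyte",
)


# ---------------------------------------------------------------------------
# parameters and containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueSimParams:
    """Parameters of a simulated slide.

    ``infiltration`` interpolates between stromal cells repelled from the
    cancer nests (0.0) and fully intermixed with them (1.0).  Endothelial
    cells are laid along short vessel segments when ``vessel_count`` > 0,
    so endothelial-cancer proximity is governed by vessel placement.
    """

    n_cancer: int = 300
    n_per_stromal_type: dict[str, int] = field(
        default_factory=lambda: {
            "normal_epithelial": 60,
            "fibroblast": 150,
            "lymphocyte": 150,
            "neutrophil": 40,
            "macrophage": 60,
            "endothelial": 60,
            "myocyte": 40,
        }
    )
    nest_count: int = 3
    nest_radius: float = 70.0  # μm
    infiltration: float = 0.5
    vessel_count: int = 4
    field_size: tuple[float, float] = (600.0, 600.0)  # μm (width, height)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cancer < 0 or self.nest_count < 0 or self.vessel_count < 0:
            raise ValueError("counts must be >= 0")
        for t, n in self.n_per_stromal_type.items():
            if t not in STROMAL_TYPES:
                raise ValueError(f"unknown stromal type {t!r}")
            if n < 0:
                raise ValueError("counts must be >= 0")
        if not (self.field_size[0] > 0 and self.field_size[1] > 0):
            raise ValueError("field_size must be positive")
        if not 0.0 <= self.infiltration <= 1.0:
            raise ValueError("infiltration must be in [0, 1]")
        if self.nest_radius <= 0:
            raise ValueError("nest_radius must be > 0")


@dataclass
class GroundTruthCellTable:
    """Per-slide ground-truth cell records: (cell_id, x_um, y_um, cell_type)."""

    df: pd.DataFrame
    field_size: tuple[float, float]
    seed: int

    def __post_init__(self) -> None:
        required = {"cell_id", "x_um", "y_um", "cell_type"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.df)

    def points(self, cell_type: str | None = None) -> np.ndarray:
        df = self.df if cell_type is None else self.df[self.df.cell_type == cell_type]
        return df[["x_um", "y_um"]].to_numpy(dtype=float)


@dataclass(frozen=True)
class SurvivalSimParams:
    """Exponential proportional-hazards simulation parameters."""

    true_log_hr: float = 0.0
    baseline_hazard: float = 0.05  # events per month
    censor_rate: float = 0.3  # expected censored fraction in the low group
    n_patients: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.n_patients < 2:
            raise ValueError("need n_patients >= 2")


@dataclass(frozen=True)
class PairedModalityParams:
    """Geometry + noise linking an H&E frame to its paired mIF frame."""

    flip: bool = True
    rotation_deg: float = 0.0
    scale: float = 1.0
    translation: tuple[float, float] = (0.0, 0.0)
    positional_noise_sd: float = 0.0  # μm
    marker_noise_sd: float = 0.15  # intensity units
    detection_dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if not 0.0 <= self.detection_dropout < 1.0:
            raise ValueError("detection_dropout must be in [0, 1)")

    @property
    def transform(self) -> PlanarTransform:
        return PlanarTransform(self.flip, self.rotation_deg, self.scale, self.translation)


# ---------------------------------------------------------------------------
# slide simulation
# ---------------------------------------------------------------------------


def _sample_in_field(rng, n, field):
    return rng.uniform((0.0, 0.0), field, size=(n, 2))


def _sample_nested(rng, n, centres, sigma, field):
    """Gaussian-around-nest-centre samples, truncated to the field by
    rejection (clipped as a last resort)."""
    if n == 0 or len(centres) == 0:
        return _sample_in_field(rng, n, field)
    idx = rng.integers(0, len(centres), size=n)
    pts = centres[idx] + rng.normal(0.0, sigma, size=(n, 2))
    for _ in range(50):
        bad = (pts[:, 0] < 0) | (pts[:, 0] > field[0]) | (pts[:, 1] < 0) | (pts[:, 1] > field[1])
        if not bad.any():
            break
        k = int(bad.sum())
        pts[bad] = centres[rng.integers(0, len(centres), size=k)] + rng.normal(
            0.0, sigma, size=(k, 2)
        )
    return np.clip(pts, 0.0, field)


def _sample_repelled(rng, n, centres, min_dist, field):
    """Uniform samples conditioned on being > min_dist from every nest centre.
    Falls back to the farthest candidates if the admissible region is tiny."""
    if n == 0:
        return np.empty((0, 2))
    if len(centres) == 0:
        return _sample_in_field(rng, n, field)
    kept: list[np.ndarray] = []
    best_pts, best_d = None, None
    for _ in range(60):
        cand = _sample_in_field(rng, max(4 * n, 64), field)
        d = np.sqrt(((cand[:, None, :] - centres[None, :, :]) ** 2).sum(-1)).min(axis=1)
        ok = cand[d > min_dist]
        kept.append(ok)
        if best_d is None or (d.max() > best_d):
            order = np.argsort(d)[::-1]
            best_pts, best_d = cand[order[:n]], d.max()
        if sum(len(k) for k in kept) >= n:
            break
    pool = np.concatenate(kept) if kept else np.empty((0, 2))
    if len(pool) >= n:
        return pool[:n]
    # degenerate geometry: admissible region nearly empty
    return np.concatenate([pool, best_pts[: n - len(pool)]])


def _sample_vessels(rng, n, vessel_count, field, jitter_sd=2.0, length_mean=120.0):
    """Endothelial positions along short random line segments (vessels)."""
    if n == 0:
        return np.empty((0, 2))
    starts = _sample_in_field(rng, vessel_count, field)
    angles = rng.uniform(0, 2 * np.pi, size=vessel_count)
    lengths = np.abs(rng.normal(length_mean, length_mean / 5, size=vessel_count))
    which = rng.integers(0, vessel_count, size=n)
    t = rng.uniform(0, 1, size=n)
    dx = np.cos(angles[which]) * lengths[which] * t
    dy = np.sin(angles[which]) * lengths[which] * t
    pts = starts[which] + np.stack([dx, dy], axis=1)
    pts += rng.normal(0.0, jitter_sd, size=pts.shape)
    return np.clip(pts, 0.0, field)


def simulate_slide(params: TissueSimParams) -> GroundTruthCellTable:
    """Simulate one slide's ground-truth cell point pattern.

    Cancer cells are placed in ``nest_count`` isotropic Gaussian clusters
    (sd = nest_radius / 2, truncated to the field).  Each stromal/immune
    cell is drawn from the uniform field distribution with probability
    ``infiltration`` and from a nest-repelled distribution otherwise.
    Endothelial cells are laid along vessel segments when vessels are
    requested.  Deterministic given ``params.seed``.
    """
    field = np.asarray(params.field_size, dtype=float)
    streams = np.random.SeedSequence(params.seed).spawn(3 + len(STROMAL_TYPES))
    rng_nest, rng_cancer, rng_vessel = (np.random.default_rng(s) for s in streams[:3])

    margin = min(params.nest_radius, float(field.min()) / 4)
    if params.nest_count > 0:
        centres = rng_nest.uniform(margin, field - margin, size=(params.nest_count, 2))
    else:
        centres = np.empty((0, 2))

    sigma = params.nest_radius / 2.0
    rows: list[pd.DataFrame] = []

    cancer = _sample_nested(rng_cancer, params.n_cancer, centres, sigma, field)
    rows.append(pd.DataFrame({"x_um": cancer[:, 0], "y_um": cancer[:, 1],
                              "cell_type": "cancer_epithelial"}))

    repel_dist = 1.6 * params.nest_radius
    for stype, stream in zip(STROMAL_TYPES, streams[3:]):
        rng = np.random.default_rng(stream)
        n = params.n_per_stromal_type.get(stype, 0)
        if stype == "endothelial" and params.vessel_count > 0:
            pts = _sample_vessels(rng_vessel, n, params.vessel_count, field)
        else:
            n_mixed = int(rng.binomial(n, params.infiltration))
            uni = _sample_in_field(rng, n_mixed, field)
            rep = _sample_repelled(rng, n - n_mixed, centres, repel_dist, field)
            pts = np.concatenate([uni, rep]) if n else np.empty((0, 2))
        rows.append(pd.DataFrame({"x_um": pts[:, 0], "y_um": pts[:, 1], "cell_type": stype}))

    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["x_um", "y_um", "cell_type"]
    )
    df.insert(0, "cell_id", np.arange(len(df)))
    df["cell_type"] = df["cell_type"].astype(str)
    return GroundTruthCellTable(df=df, field_size=tuple(field), seed=params.seed)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NucleusStyle:
    """Per-type nucleus morphology: semi-axes in μm, RGB chromatin colour in
    [0,1], speckle texture amplitude, and number of sub-lobes.  Every
    nucleus additionally gets a small dark nucleolus at its centre
    (radius ``nucleolus_um``), as real nuclei do."""

    a_um: float
    b_um: float
    color: tuple[float, float, float]
    speckle: float = 0.05
    lobes: int = 1
    nucleolus_um: float = 1.1


#: Default morphology table.  Chosen for visual separability (size,
#: elongation, darkness, hue), not for stain realism.
DEFAULT_STYLES: dict[str, NucleusStyle] = {
    "cancer_epithelial": NucleusStyle(4.2, 3.4, (0.36, 0.20, 0.52), 0.12),
    "normal_epithelial": NucleusStyle(3.0, 2.8, (0.50, 0.34, 0.62), 0.04),
    "fibroblast": NucleusStyle(4.2, 1.1, (0.58, 0.46, 0.70), 0.04),
    "lymphocyte": NucleusStyle(1.9, 1.8, (0.14, 0.10, 0.38), 0.03),
    "neutrophil": NucleusStyle(1.6, 1.5, (0.24, 0.14, 0.46), 0.10, lobes=3),
    "macrophage": NucleusStyle(4.4, 4.0, (0.66, 0.56, 0.74), 0.08),
    "endothelial": NucleusStyle(3.6, 0.8, (0.26, 0.40, 0.72), 0.04),
    "myocyte": NucleusStyle(5.8, 1.7, (0.70, 0.28, 0.40), 0.05),
}


@dataclass(frozen=True)
class RenderStyle:
    um_per_px: float = WORKING_RESOLUTION_UM_PER_PX
    background: tuple[float, float, float] = (0.93, 0.89, 0.94)
    background_noise_sd: float = 0.015
    styles: dict[str, NucleusStyle] = field(default_factory=lambda: dict(DEFAULT_STYLES))

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")


def _draw_ellipse(img, cx, cy, a_px, b_px, theta, color, speckle, rng):
    h, w = img.shape[:2]
    r = int(math.ceil(max(a_px, b_px))) + 1
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    u = (xx - cx) * math.cos(theta) + (yy - cy) * math.sin(theta)
    v = -(xx - cx) * math.sin(theta) + (yy - cy) * math.cos(theta)
    r2 = (u / a_px) ** 2 + (v / b_px) ** 2
    inside = r2 <= 1.0
    if not inside.any():
        return
    base = np.asarray(color)
    # slight radial brightening towards the rim + per-pixel speckle
    shade = 1.0 + 0.25 * r2[inside][:, None]
    tex = rng.normal(0.0, speckle, size=(int(inside.sum()), 1))
    pix = np.clip(base[None, :] * shade + tex, 0.0, 1.0)
    region = img[y0:y1, x0:x1]
    cur = region[inside]
    region[inside] = np.minimum(cur, pix)  # overlapping nuclei stay dark


def render_slide(
    table: GroundTruthCellTable,
    style: RenderStyle | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a slide's cells into an H&E-like RGB image.

    Returns ``(image, truth_px)`` where ``image`` is a uint8 H x W x 3
    raster at ``style.um_per_px`` resolution and ``truth_px`` is the
    (n, 2) array of rendered nucleus centres in float pixel coordinates,
    row i corresponding to row i of the table.  ``truth_px * um_per_px``
    recovers the table's μm coordinates exactly.
    """
    style = style or RenderStyle()
    if seed is None:
        seed = table.seed
    upp = style.um_per_px
    # +1 so cells at the far field boundary still land inside the raster
    w = int(math.ceil(table.field_size[0] / upp)) + 1
    h = int(math.ceil(table.field_size[1] / upp)) + 1
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))

    img = np.clip(
        np.asarray(style.background)[None, None, :]
        + rng.normal(0.0, style.background_noise_sd, size=(h, w, 3)),
        0.0,
        1.0,
    )

    truth = table.df[["x_um", "y_um"]].to_numpy(dtype=float) / upp
    types = table.df["cell_type"].to_numpy()
    for i in range(len(table.df)):
        st = style.styles.get(types[i])
        if st is None:
            raise ValueError(f"no rendering style for type {types[i]!r}")
        cx, cy = truth[i]
        theta = rng.uniform(0, np.pi)
        a_px, b_px = st.a_um / upp, st.b_um / upp
        if st.lobes <= 1:
            _draw_ellipse(img, cx, cy, a_px, b_px, theta, st.color, st.speckle, rng)
        else:
            for k in range(st.lobes):
                ang = theta + 2 * np.pi * k / st.lobes
                off = 1.2 * a_px
                _draw_ellipse(
                    img,
                    cx + off * math.cos(ang),
                    cy + off * math.sin(ang),
                    a_px,
                    b_px,
                    theta,
                    st.color,
                    st.speckle,
                    rng,
                )
        if st.nucleolus_um > 0:
            nuc_col = tuple(c * 0.45 for c in st.color)
            n_px = st.nucleolus_um / upp
            _draw_ellipse(img, cx, cy, n_px, n_px, 0.0, nuc_col, 0.02, rng)
    return (img * 255).astype(np.uint8), truth


# ---------------------------------------------------------------------------
# survival simulation
# ---------------------------------------------------------------------------


def simulate_cohort_survival(
    metric_group: "pd.Series | np.ndarray | list[str]",
    params: SurvivalSimParams,
) -> pd.DataFrame:
    """Draw progression-free survival records under exponential
    proportional hazards with a planted log hazard ratio for "high".

    ``metric_group`` holds per-patient labels "high"/"low" (length must
    equal ``params.n_patients``).  Censoring times are independent
    exponentials with rate ``baseline_hazard * censor_rate / (1 -
    censor_rate)``, giving an expected censored fraction of about
    ``censor_rate`` in the low group.

    Returns a DataFrame with columns patient_id, group, pfs_months, event.
    """
    groups = pd.Series(metric_group).astype(str).to_numpy()
    if len(groups) == 0:
        raise ValueError("metric_group is empty")
    if len(groups) != params.n_patients:
        raise ValueError("metric_group length must equal n_patients")
    bad = set(groups) - {"high", "low"}
    if bad:
        raise ValueError(f"labels must be 'high'/'low', got {sorted(bad)}")

    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 11]))
    hazard = params.baseline_hazard * np.exp(params.true_log_hr * (groups == "high"))
    t_event = rng.exponential(1.0 / hazard)
    if params.censor_rate > 0:
        c_rate = params.baseline_hazard * params.censor_rate / (1 - params.censor_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=len(groups))
    else:
        t_cens = np.full(len(groups), np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(len(groups))],
            "group": groups,
            "pfs_months": time,
            "event": event,
        }
    )


# ---------------------------------------------------------------------------
# paired mIF simulation
# ---------------------------------------------------------------------------

#: mIF markers carried in synthetic marker tables.
MIF_MARKERS: tuple[str, ...] = (
    "pan_cytokeratin",
    "CD3e",
    "CD4",
    "CD8",
    "CD20",
    "CD68",
    "CD31",
)

#: Ground-truth type -> markers expressed.  Lymphocytes get CD3e plus a
#: random T-cell subset marker, or CD20 alone for the B-cell fraction.
TYPE_MARKERS: dict[str, tuple[str, ...]] = {
    "cancer_epithelial": ("pan_cytokeratin",),
    "normal_epithelial": ("pan_cytokeratin",),
    "macrophage": ("CD68",),
    "endothelial": ("CD31",),
}

#: Types expressing none of the panel markers.
BACKGROUND_TYPES: frozenset[str] = frozenset({"fibroblast", "neutrophil", "myocyte"})

POSITIVE_LEVEL = 3.0
NEGATIVE_LEVEL = 0.2


def simulate_paired_mif(
    table: GroundTruthCellTable,
    params: PairedModalityParams,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the mIF marker table paired with an H&E ground-truth table.

    Coordinates are mapped through ``params.transform`` (flip then rotation,
    scale, translation) with Gaussian positional noise; each cell's
    signature markers get intensity ~``POSITIVE_LEVEL``, others
    ~``NEGATIVE_LEVEL``, both with ``marker_noise_sd`` noise (clipped at 0).
    Exactly ``round(detection_dropout * n)`` cells are omitted (seeded).

    Returns a DataFrame with cell_id, true_type, x_um, y_um and one column
    per marker in :data:`MIF_MARKERS`.
    """
    if seed is None:
        seed = table.seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))

    types = table.df["cell_type"].to_numpy()
    unmapped = set(types) - set(TYPE_MARKERS) - BACKGROUND_TYPES - {"lymphocyte"}
    if unmapped:
        raise ValueError(f"no marker signature for types: {sorted(unmapped)}")

    pts = params.transform.apply(table.points())
    if params.positional_noise_sd > 0 and len(pts):
        pts = pts + rng.normal(0.0, params.positional_noise_sd, size=pts.shape)

    n = len(table.df)
    intensity = np.full((n, len(MIF_MARKERS)), NEGATIVE_LEVEL)
    midx = {m: j for j, m in enumerate(MIF_MARKERS)}
    lymph_subsets = (("CD3e", "CD4"), ("CD3e", "CD8"), ("CD20",))
    for i, t in enumerate(types):
        if t == "lymphocyte":
            markers = lymph_subsets[rng.integers(0, len(lymph_subsets))]
        else:
            markers = TYPE_MARKERS.get(t, ())
        for m in markers:
            intensity[i, midx[m]] = POSITIVE_LEVEL
    if params.marker_noise_sd > 0 and n:
        intensity = np.clip(
            intensity + rng.normal(0.0, params.marker_noise_sd, size=intensity.shape), 0.0, None
        )

    out = pd.DataFrame(
        {
            "cell_id": table.df["cell_id"].to_numpy(),
            "true_type": types,
            "x_um": pts[:, 0] if n else np.array([]),
            "y_um": pts[:, 1] if n else np.array([]),
        }
    )
    for m in MIF_MARKERS:
        out[m] = intensity[:, midx[m]]

    n_drop = int(round(params.detection_dropout * n))
    if n_drop:
        drop = rng.choice(n, size=n_drop, replace=False)
        out = out.drop(index=drop).reset_index(drop=True)
    return out
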