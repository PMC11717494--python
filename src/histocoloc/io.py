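"""File readers/writers and configuration for the pipeline.

CSV is the canonical table format (fixed headers, UTF-8, "." decimal).
Rasters are written as TIFF with an X/Y-resolution tag (preferred) or PNG
with the resolution carried in config.  YAML configs are validated on
load.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .vocab import LABELS, normalise_type, prob_columns

logger = logging.getLogger(__name__)

#: Fixed float format for CSV output (byte-identical reruns).
FLOAT_FORMAT = "%.6f"


# ---------------------------------------------------------------------------
# cell tables
# ---------------------------------------------------------------------------


def read_cell_table(path: str | Path, require_probs: bool = False) -> pd.DataFrame:
    """Read and validate a classified cell table CSV.

    Requires columns x_um, y_um, cell_type (order free; probability
    columns optional unless ``require_probs``).  Cell-type strings are
    canonicalised; a malformed row or missing column raises ``ValueError``
    naming it.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("x_um", "y_um", "cell_type") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if require_probs:
        missing_p = [c for c in prob_columns() if c not in df.columns]
        if missing_p:
            raise ValueError(f"{path}: missing probability columns {missing_p}")
    for col in ("x_um", "y_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int((vals.isna()).idxmax())
            raise ValueError(f"{path}: non-numeric {col} at row {row}")
        df[col] = vals.astype(float)
    try:
        df["cell_type"] = df["cell_type"].map(normalise_type)
    except ValueError as exc:
        bad_rows = [i for i, v in df["cell_type"].items()
                    if not _is_known_type(v)]
        raise ValueError(f"{path}: invalid cell type at row(s) {bad_rows[:5]}: {exc}") from exc
    return df


def _is_known_type(v) -> bool:
    try:
        normalise_type(str(v))
        return True
    except ValueError:
        return False


def write_cell_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def write_image(image: np.ndarray, path: str | Path, um_per_px: float) -> None:
    """Write a raster; TIFF gets an X/Y resolution tag (pixels per cm)."""
    path = Path(path)
    if um_per_px <= 0:
        raise ValueError("um_per_px must be > 0")
    if path.suffix.lower() in (".tif", ".tiff"):
        px_per_cm = 1e4 / um_per_px
        tifffile.imwrite(
            path, image, resolution=(px_per_cm, px_per_cm), resolutionunit="CENTIMETER"
        )
    else:
        from PIL import Image

        Image.fromarray(image).save(path)


def read_image(path: str | Path, um_per_px: float | None = None) -> tuple[np.ndarray, float]:
    """Read a raster and its resolution.

    TIFFs carry the resolution tag; other formats need ``um_per_px``
    passed explicitly (e.g. from config).
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            img = page.asarray()
            tags = page.tags
            if um_per_px is None and "XResolution" in tags:
                num, den = tags["XResolution"].value
                unit = tags.get("ResolutionUnit")
                per_cm = num / den
                if unit is not None and getattr(unit.value, "name", str(unit.value)) in (
                    "INCH",
                    "2",
                ):
                    per_cm = per_cm / 2.54
                um_per_px = 1e4 / per_cm
        if um_per_px is None:
            raise ValueError(f"{path}: no resolution tag and none supplied")
        return img, float(um_per_px)
    from PIL import Image

    if um_per_px is None:
        raise ValueError(f"{path}: resolution must be supplied for non-TIFF images")
    return np.asarray(Image.open(path)), float(um_per_px)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs, loadable from YAML."""

    out_dir: str = "results"
    seed: int = 0
    working_resolution: float = 0.44  # μm/pixel
    radius_um: float = 44.0
    sensitivity_radii_um: tuple[float, ...] = (22.0, 88.0)
    density_bin_um: float = 88.0
    unknown_threshold: float = 0.5
    detector_stride: int = 4
    prob_threshold: float = 0.5
    min_separation_px: int = 6
    window_edge_um: float = 1887.0
    # cohort simulation
    n_patients: int = 5
    slides_per_patient: int = 1
    n_training_slides: int = 2
    field_um: float = 220.0
    n_cancer: int = 110
    n_per_stromal_type: dict[str, int] = field(
        default_factory=lambda: {
            "normal_epithelial": 22,
            "fibroblast": 55,
            "lymphocyte": 55,
            "neutrophil": 14,
            "macrophage": 22,
            "endothelial": 22,
            "myocyte": 14,
        }
    )
    nest_count: int = 2
    nest_radius_um: float = 45.0
    vessel_count: int = 2
    # survival simulation
    true_log_hr: float = 0.0
    baseline_hazard: float = 0.05
    censor_rate: float = 0.3
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.working_resolution <= 0:
            raise ValueError("working_resolution must be > 0")
        if self.radius_um <= 0 or self.density_bin_um <= 0 or self.window_edge_um <= 0:
            raise ValueError("radii/bin/window sizes must be > 0")
        if not 0 < self.unknown_threshold < 1:
            raise ValueError("unknown_threshold must be in (0, 1)")
        if self.n_patients < 2 or self.slides_per_patient < 1 or self.n_training_slides < 1:
            raise ValueError("cohort sizes too small")


_CONFIG_FIELDS = set(PipelineConfig.__dataclass_fields__)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "sensitivity_radii_um" in raw:
        raw["sensitivity_radii_um"] = tuple(raw["sensitivity_radii_um"])
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    d = asdict(config)
    d["sensitivity_radii_um"] = list(d["sensitivity_radii_um"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
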