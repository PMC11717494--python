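"""Cell-type vocabulary and pipeline-wide physical constants.

The analysis recognises eight cell types commonly found in colorectal
tissue, plus a ninth "unknown" label for detections the classifier
cannot confidently assign.  All spatial quantities are carried in
micrometres; rasters additionally carry a micrometre-per-pixel
resolution so pixel and physical frames can be converted exactly.
"""

from __future__ import annotations

# The eight biological cell types (fixed order: used for argmax tie-breaking
# and as the canonical column order of probability vectors).
CELL_TYPES: tuple[str, ...] = (
    "cancer_epithelial",
    "normal_epithelial",
    "fibroblast",
    "lymphocyte",
    "neutrophil",
    "macrophage",
    "endothelial",
    "myocyte",
)

UNKNOWN = "unknown"

#: Full 9-label classifier vocabulary (eight types + unknown).
LABELS: tuple[str, ...] = CELL_TYPES + (UNKNOWN,)

#: Working resolution of the cell detector and classifier, μm per pixel.
WORKING_RESOLUTION_UM_PER_PX = 0.44

#: Neighbourhood radius defining tumour-associated cells: 100 px at the
#: working resolution, i.e. 44 μm.
DEFAULT_RADIUS_PX = 100
DEFAULT_RADIUS_UM = DEFAULT_RADIUS_PX * WORKING_RESOLUTION_UM_PER_PX  # 44.0

#: Alternative radii used for the sensitivity analysis, μm.
SENSITIVITY_RADII_UM = (22.0, 88.0)

#: Edge of a density-map bin, μm.
DENSITY_BIN_UM = 88.0

#: Minimum winning probability for a confident class assignment; below
#: this the cell is reassigned to "unknown".
UNKNOWN_THRESHOLD = 0.5

#: Stromal/immune types quantified as tumour-associated subgroups.
TA_TYPES: tuple[str, ...] = ("lymphocyte", "macrophage", "endothelial")


def normalise_type(name: str) -> str:
    """Canonicalise a cell-type string (case, surrounding space, separators).

    Raises ``ValueError`` if the result is not in the 9-label vocabulary.
    """
    canon = name.strip().lower().replace(" ", "_").replace("-", "_")
    if canon not in LABELS:
        raise ValueError(f"unknown cell type {name!r} (canonical {canon!r})")
    return canon


def prob_columns() -> list[str]:
    """Names of the nine per-class probability columns in cell tables."""
    return [f"p_{lab}" for lab in LABELS]
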