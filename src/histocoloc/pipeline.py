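"""End-to-end pipeline: simulate -> detect -> classify -> metrics -> survival.

Each stage reads the previous stage's artefacts from the output directory,
writes its own versioned outputs, and records them (with SHA-256 hashes,
parameters and seeds) in a JSON manifest.  All randomness flows from the
config seed through per-stage substreams; a rerun with an unchanged config
is byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .classification import ClassifierSpec, classify_cells, train_toy_classifier
from .detection import DetectedCellSet, DetectorPatchSpec, PeakParams, run_detector, train_toy_detector
from .spatial import (
    NeighbourhoodSpec,
    aggregate_patient,
    patient_metrics_frame,
    tumour_associated_counts,
)
from .survival import associate, dichotomise, km_curves
from .synth import (
    GroundTruthCellTable,
    RenderStyle,
    SurvivalSimParams,
    TissueSimParams,
    render_slide,
    simulate_cohort_survival,
    simulate_slide,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "detect", "classify", "metrics", "survival")

#: Upstream artefacts each stage depends on.
_DEPS = {
    "simulate": (),
    "detect": ("simulate",),
    "classify": ("detect",),
    "metrics": ("classify",),
    "survival": ("metrics",),
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _slide_params(cfg: hio.PipelineConfig, seed: int, infiltration: float) -> TissueSimParams:
    return TissueSimParams(
        n_cancer=cfg.n_cancer,
        n_per_stromal_type=dict(cfg.n_per_stromal_type),
        nest_count=cfg.nest_count,
        nest_radius=cfg.nest_radius_um,
        infiltration=infiltration,
        vessel_count=cfg.vessel_count,
        field_size=(cfg.field_um, cfg.field_um),
        seed=seed,
    )


def run_pipeline(
    config: hio.PipelineConfig, stages: tuple[str, ...] = STAGES
) -> dict:
    """Run the requested pipeline stages; returns the artefact manifest.

    Stage dependencies must be satisfied either within this call or by
    artefacts already present in ``config.out_dir`` from an earlier run;
    otherwise a ``ValueError`` names the stage to run first.
    """
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest: dict = {"config": hio.asdict(config), "stages": {}}

    done: set[str] = set()

    def artefact_exists(stage: str) -> bool:
        probe = {
            "simulate": out / "slides" / "slide_000.csv",
            "detect": out / "detected" / "slide_000.csv",
            "classify": out / "classified" / "slide_000.csv",
            "metrics": out / "patient_metrics.csv",
            "survival": out / "survival_results.csv",
        }[stage]
        return probe.exists()

    for stage in STAGES:
        if stage not in stages:
            continue
        for dep in _DEPS[stage]:
            if dep not in done and dep not in stages and not artefact_exists(dep):
                raise ValueError(f"stage {stage!r} needs {dep!r}: run that stage first")
        logger.info("running stage %s", stage)
        outputs = _RUNNERS[stage](config, out)
        manifest["stages"][stage] = {
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(outputs)},
            "seed": config.seed,
        }
        done.add(stage)

    hio.write_json(manifest, manifest_path)
    return manifest


# ---------------------------------------------------------------------------
# stage runners (each returns the list of files it wrote)
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: hio.PipelineConfig, out: Path) -> list[Path]:
    """Training slides + analysis cohort: ground-truth tables and rendered
    images.  Infiltration varies across patients so the spatial metric has
    cohort-level spread."""
    style = RenderStyle(um_per_px=cfg.working_resolution)
    written = []
    (out / "slides").mkdir(exist_ok=True)
    (out / "training").mkdir(exist_ok=True)

    ss = np.random.SeedSequence([cfg.seed, 101])
    train_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(cfg.n_training_slides)]
    for i, seed in enumerate(train_seeds):
        params = _slide_params(cfg, seed, infiltration=0.5)
        table = simulate_slide(params)
        img, _ = render_slide(table, style)
        tpath = out / "training" / f"train_{i:03d}.csv"
        ipath = out / "training" / f"train_{i:03d}.tiff"
        hio.write_cell_table(table.df, tpath)
        hio.write_image(img, ipath, cfg.working_resolution)
        written += [tpath, ipath]

    ss2 = np.random.SeedSequence([cfg.seed, 102])
    n_slides = cfg.n_patients * cfg.slides_per_patient
    slide_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss2.spawn(n_slides)]
    mapping = []
    k = 0
    for p in range(cfg.n_patients):
        infiltration = p / max(cfg.n_patients - 1, 1)  # cohort-wide gradient
        for _ in range(cfg.slides_per_patient):
            params = _slide_params(cfg, slide_seeds[k], infiltration)
            table = simulate_slide(params)
            img, _ = render_slide(table, style)
            tpath = out / "slides" / f"slide_{k:03d}.csv"
            ipath = out / "slides" / f"slide_{k:03d}.tiff"
            hio.write_cell_table(table.df, tpath)
            hio.write_image(img, ipath, cfg.working_resolution)
            written += [tpath, ipath]
            mapping.append(
                {"slide_id": f"slide_{k:03d}", "patient_id": f"P{p:03d}",
                 "infiltration": infiltration}
            )
            k += 1
    mpath = out / "slide_patient_map.csv"
    pd.DataFrame(mapping).to_csv(mpath, index=False, float_format=hio.FLOAT_FORMAT)
    written.append(mpath)
    return written


def _load_training(cfg: hio.PipelineConfig, out: Path):
    images, tables = [], []
    for i in range(cfg.n_training_slides):
        img, _ = hio.read_image(out / "training" / f"train_{i:03d}.tiff")
        tab = hio.read_cell_table(out / "training" / f"train_{i:03d}.csv")
        images.append(img)
        tables.append(tab)
    return images, tables


def _stage_detect(cfg: hio.PipelineConfig, out: Path) -> list[Path]:
    spec = DetectorPatchSpec(stride=cfg.detector_stride, working_resolution=cfg.working_resolution)
    images, tables = _load_training(cfg, out)
    truths = [t[["x_um", "y_um"]].to_numpy() / cfg.working_resolution for t in tables]
    detector = train_toy_detector(images, truths, spec=spec, seed=cfg.seed)
    params = PeakParams(cfg.prob_threshold, cfg.min_separation_px)

    written = []
    (out / "detected").mkdir(exist_ok=True)
    for ipath in sorted((out / "slides").glob("slide_*.tiff")):
        img, upp = hio.read_image(ipath)
        det = run_detector(img, detector, spec=spec, params=params)
        df = pd.DataFrame(
            {
                "x_px": det.coords_px[:, 0],
                "y_px": det.coords_px[:, 1],
                "x_um": det.coords_um[:, 0],
                "y_um": det.coords_um[:, 1],
            }
        )
        dpath = out / "detected" / (ipath.stem + ".csv")
        df.to_csv(dpath, index=False, float_format=hio.FLOAT_FORMAT)
        written.append(dpath)
    return written


def _stage_classify(cfg: hio.PipelineConfig, out: Path) -> list[Path]:
    spec = ClassifierSpec(
        working_resolution=cfg.working_resolution, unknown_threshold=cfg.unknown_threshold
    )
    images, tables = _load_training(cfg, out)
    annotations = []
    for img, tab in zip(images, tables):
        for _, row in tab.iterrows():
            pt = (row.x_um / cfg.working_resolution, row.y_um / cfg.working_resolution)
            annotations.append((img, pt, row.cell_type))
    clf = train_toy_classifier(annotations, spec=spec, seed=cfg.seed)

    written = []
    (out / "classified").mkdir(exist_ok=True)
    for dpath in sorted((out / "detected").glob("slide_*.csv")):
        img, upp = hio.read_image(out / "slides" / (dpath.stem + ".tiff"))
        det_df = pd.read_csv(dpath)
        det = DetectedCellSet(det_df[["x_px", "y_px"]].to_numpy(), resolution=cfg.working_resolution)
        table = classify_cells(img, det, clf, spec)
        cpath = out / "classified" / dpath.name
        hio.write_cell_table(table, cpath)
        written.append(cpath)
    return written


def _stage_metrics(cfg: hio.PipelineConfig, out: Path) -> list[Path]:
    nspec = NeighbourhoodSpec(cfg.radius_um, tuple(cfg.sensitivity_radii_um))
    mapping = pd.read_csv(out / "slide_patient_map.csv").set_index("slide_id")
    summaries: dict[str, list] = {}
    rows = []
    for cpath in sorted((out / "classified").glob("slide_*.csv")):
        table = hio.read_cell_table(cpath, require_probs=True)
        s = tumour_associated_counts(table, nspec, slide_id=cpath.stem)
        pid = mapping.loc[cpath.stem, "patient_id"]
        summaries.setdefault(pid, []).append(s)
        rows.append(
            {"slide_id": s.slide_id, "patient_id": pid, "radius_um": s.radius_um,
             "cancer_count": s.cancer_count,
             "ta_lymphocyte_count": s.ta_lymphocyte_count,
             "ta_macrophage_count": s.ta_macrophage_count,
             "ta_endothelial_count": s.ta_endothelial_count}
        )
    spath = out / "slide_summaries.csv"
    pd.DataFrame(rows).to_csv(spath, index=False, float_format=hio.FLOAT_FORMAT)
    metrics = aggregate_patient(summaries)
    ppath = out / "patient_metrics.csv"
    patient_metrics_frame(metrics).to_csv(ppath, index=False, float_format=hio.FLOAT_FORMAT)
    return [spath, ppath]


def _stage_survival(cfg: hio.PipelineConfig, out: Path) -> list[Path]:
    """Stratify on the tumour-associated lymphocyte metric and test the
    association on survival simulated with the configured planted log-HR."""
    metrics = pd.read_csv(out / "patient_metrics.csv")
    values = metrics.set_index("patient_id")["mean_ta_lymphocyte_count"]
    cohort = dichotomise(values)
    sparams = SurvivalSimParams(
        true_log_hr=cfg.true_log_hr,
        baseline_hazard=cfg.baseline_hazard,
        censor_rate=cfg.censor_rate,
        n_patients=len(values),
        seed=cfg.seed,
    )
    records = simulate_cohort_survival(cohort.labels.to_numpy(), sparams)
    records["patient_id"] = values.index.to_numpy()

    res = associate(records, cohort, covariates=cfg.covariates or None)
    rpath = out / "survival_results.csv"
    table = res.hazard_table.copy()
    table.insert(0, "metric", cohort.metric_name)
    table["logrank_stat"] = res.logrank_stat
    table["logrank_p"] = res.logrank_p
    table["cutpoint"] = cohort.cutpoint
    table.to_csv(rpath, index=False, float_format=hio.FLOAT_FORMAT)

    written = [rpath]
    curves = km_curves(records, cohort, at_risk_times=np.arange(0.0, 61.0, 12.0))
    for g, tab in curves.items():
        kpath = out / f"km_{g}.csv"
        tab.to_csv(kpath, index=False, float_format=hio.FLOAT_FORMAT)
        written.append(kpath)
    spath = out / "survival_records.csv"
    records.to_csv(spath, index=False, float_format=hio.FLOAT_FORMAT)
    written.append(spath)
    return written


_RUNNERS = {
    "simulate": _stage_simulate,
    "detect": _stage_detect,
    "classify": _stage_classify,
    "metrics": _stage_metrics,
    "survival": _stage_survival,
}
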