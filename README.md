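# histocoloc

Tumour-microenvironment (TME) colocalisation analysis for H&E cell maps.

Colorectal cancers with similar molecular subtype can progress very
differently, and part of that variability is carried by the spatial
organisation of the tumour microenvironment: how densely lymphocytes,
macrophages and endothelial cells infiltrate the tumour nests.
`histocoloc` implements the full computational-pathology chain needed to
quantify that organisation from a stained section and relate it to
outcome, for researchers who want a tested, seedable, desk-scale pipeline:

1. **Synthetic tissue** (`histocoloc.synth`) — point patterns of eight
   colorectal cell types with clustered cancer nests, tunable stromal
   infiltration and vessel structures; H&E-like renderings with
   type-distinct nuclear morphology; proportional-hazards survival times
   with a planted log hazard ratio; paired multiplex-immunofluorescence
   (mIF) marker tables related to the H&E frame by an unknown
   flip + similarity transform. Every generator is a pure function of
   (parameters, seed), so each downstream stage is testable against known
   ground truth.
2. **Nucleus detection** (`histocoloc.detection`) — a trainable detector
   maps each 31 × 31 px image patch (0.44 μm/px) to an 11 × 11 tile of
   nucleus probabilities; tiles are assembled into a full-frame
   probability map (overlaps averaged) and peaks are extracted by
   thresholding, local-maximum detection and transitive proximity merging
   into intensity-weighted centroids.
3. **Cell classification** (`histocoloc.classification`) — a 51 × 51 px
   patch centred on each detected cell is resized to 224 × 224 and scored
   against nine classes (eight cell types + *unknown*); a cell keeps its
   argmax label only when the winning probability is ≥ 50%, otherwise it
   is reassigned to *unknown*.
4. **Spatial metrics** (`histocoloc.spatial`) — a cell is
   *tumour-associated* when a cancer-epithelial cell lies within a 44 μm
   radius (100 px) of it. Per-slide counts are averaged to patient level;
   the endothelial/cancer ratio is the patient-level mean tumour-associated
   endothelial count divided by the patient-level mean cancer count.
   Density maps bin the slide at 88 μm and render the ternary balance of
   any three cell types; a sensitivity analysis recomputes all counts at
   22 and 88 μm.
5. **Outcome analysis** (`histocoloc.survival`) — median dichotomisation
   into high/low groups, a directly implemented two-sided log-rank test
   and Kaplan–Meier estimator (both oracle-tested by hand), and a
   multivariate Cox proportional-hazards fit (lifelines, Efron ties) with
   per-term hazard ratios, 95% CIs and p values, plus subgroup analyses.
6. **Cross-modality concordance** (`histocoloc.concordance`) — mIF cells
   are typed by threshold gating (epithelial ← pan-cytokeratin;
   lymphocyte ← any of CD3e/CD4/CD8/CD20; macrophage ← CD68; endothelial
   ← CD31), the two point sets are registered (coarse flip/rotation/scale
   grid search on density rasters, then trimmed ICP), and per-type counts
   in square windows are compared with Spearman correlation and a linear
   fit.

## The statistics at the core

For cell *i* of type *t* at position **x**ᵢ and the set *C* of
cancer-epithelial cells, the tumour-associated indicator is

    TA(i) = 1[ min_{c ∈ C} ‖x_i − x_c‖ ≤ r ],   r = 44 μm,

slide counts are `N_t = Σ_i TA(i)`, patient metrics are means over the
patient's slides, and the endothelial/cancer ratio is
`mean_slides(N_endo) / mean_slides(|C|)`. High/low groups on a metric *m*
are compared with the log-rank statistic
`(Σ_k (O_k − E_k))² / Σ_k V_k` (hypergeometric expectation per event
time) and the adjusted model `h(t | z) = h₀(t) · exp(βᵀ z)`.

## Worked example

```python
import numpy as np
from histocoloc.synth import TissueSimParams, simulate_slide
from histocoloc.spatial import tumour_associated_counts

params = TissueSimParams(
    n_cancer=300, nest_count=3, nest_radius=70.0,
    infiltration=0.8, field_size=(600.0, 600.0), seed=7,
)
table = simulate_slide(params)
summary = tumour_associated_counts(table.df, 44.0, slide_id="demo")
print(f"cancer cells:        {summary.cancer_count}")
print(f"TA lymphocytes:      {summary.ta_lymphocyte_count} / "
      f"{summary.total_counts['lymphocyte']}")
print(f"TA endothelial:      {summary.ta_endothelial_count}")
print(f"endo/cancer ratio:   "
      f"{summary.ta_endothelial_count / summary.cancer_count:.4f}")
```

prints

```
cancer cells:        300
TA lymphocytes:      43 / 150
TA endothelial:      17
endo/cancer ratio:   0.0567
```

i.e. on this slide 43 of the 150 lymphocytes sit within 44 μm of a
cancer cell (the three nests cover a minority of the 600 × 600 μm field,
so even well-mixed stroma is mostly outside the neighbourhoods), 17 of
the 60 vessel-borne endothelial cells are tumour-associated, and the
slide-level endothelial/cancer ratio is 0.057. Lowering `infiltration`
towards 0 pushes the lymphocyte count towards zero while the
vessel-driven endothelial count barely moves.

The composed pipeline (simulate → detect → classify → metrics →
survival) runs from one config:

```
histocoloc run --config config.yaml --seed 11 --out results/
```

and writes per-stage CSVs plus a manifest with parameters, seeds and
output hashes; a rerun with the same config is byte-identical.

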