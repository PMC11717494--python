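# Methods

This note documents the models, parameter choices and numerical
conventions behind `histocoloc`, and what the synthetic-data tests do and
do not establish about behaviour on real tissue.

## Synthetic tissue model

A slide is a marked point pattern on a rectangular field (default
600 × 600 μm; smaller fields are used throughout the test suite to keep
runtimes short). Cancer-epithelial cells are drawn from a mixture of
isotropic Gaussian clusters ("nests": default 3 clusters, sd =
nest_radius / 2 with nest_radius 70 μm, truncated to the field by
resampling). Each stromal/immune cell is drawn, independently, from the
uniform field distribution with probability `infiltration` and from a
nest-repelled distribution (uniform conditioned on being > 1.6 ×
nest_radius from every nest centre, by rejection) otherwise. This single
mixture weight reproduces the two qualitative regimes of interest —
stroma segregated from tumour versus stroma intermixed with tumour —
with a monotone, testable link between the parameter and the
tumour-associated counts. Endothelial cells are laid along short random
line segments ("vessels", length ~N(120, 24) μm, jitter sd 2 μm) so that
endothelial–cancer proximity is governed by vessel placement rather than
by `infiltration`; with `vessel_count = 0` they fall back to the generic
stromal mechanism.

Default per-slide counts (300 cancer cells plus ~560 stromal cells on
600 × 600 μm, i.e. ≈ 2,400 cells/mm²) sit in the range typical of
colorectal sections; the test fixtures scale the same mix down to
250 × 250 μm fields (~345 cells) so a slide renders in ~0.1 s.

### Rendering

Nuclei are rendered one ellipse per cell at 0.44 μm/pixel onto a pale
background with Gaussian noise (sd 0.015). Types are separated by
semi-axes, elongation, chromatin colour, speckle amplitude and lobe count
(neutrophils get three small lobes); overlapping nuclei combine by
channel-wise minimum so dense nests stay dark. Every nucleus carries a
small dark nucleolus (radius 1.1 μm) at its centre: real nuclei have
nucleoli, and the consistent central anchor is what makes the centre of
strongly elongated nuclei (fibroblast, myocyte, endothelial)
well-defined at the 3-pixel matching tolerance used for detector
evaluation. The styles aim at *separability*, not stain realism: colour
distributions, texture statistics and out-of-focus artefacts of real
H&E are not modelled, so the reported detector/classifier scores
characterise the pipeline's mechanics, not expected performance on
scanned slides.

### Survival and paired-mIF generators

Progression times are exponential with hazard
`h = h₀ · exp(β · 1[high])` (h₀ = 0.05 events/month by default);
censoring times are independent exponentials with rate
`h₀ · c / (1 − c)`, giving an expected censored fraction ≈ c in the low
group (default c = 0.3). A constant baseline is sufficient for
proportional-hazards recovery testing and keeps every quantity in closed
form.

The paired mIF table transforms coordinates by a flip-first planar
similarity `y = s·R(θ)·F·x + t` plus Gaussian positional noise. Marker
intensities are ~3.0 for a cell's signature markers and ~0.2 otherwise
(threshold 1.0), with Gaussian noise clipped at zero; lymphocytes are
randomly assigned a T-helper (CD3e+CD4), cytotoxic-T (CD3e+CD8) or
B-cell (CD20) signature so the OR-gate over the four lymphocyte markers
is exercised. Detection dropout removes exactly `round(d·n)` cells
(seeded subsampling), which makes thinning counts exactly reproducible.
Fibroblasts, neutrophils and myocytes express none of the panel markers,
mirroring a panel that does not target them.

All generators draw from `numpy.random.SeedSequence` substreams of a
single seed, so components are reproducible in isolation and jointly.

## Detection

The detector contract is patch-in/tile-out: 31 × 31 px at 0.44 μm/px in,
11 × 11 probability tile out. The trainable stand-in is a one-hidden-
layer MLP regressor (128 units, seeded) from flattened patch darkness to
the central 11 × 11 window of a target map made of Gaussian bumps
(amplitude 1, sd 2 px) at the true nucleus centres. Training samples are
taken at every nucleus centre, at ±4 px jitters of those centres, and at
400 random positions per image; after fitting, a scalar output gain is
calibrated so the median predicted peak at a training nucleus centre is
0.95 (regression shrinkage otherwise leaves peaks below the 0.5
threshold), and outputs are clipped to [0, 1]. Any model honouring the
patch contract can be substituted.

Sliding-window application mirror-pads the image so output tiles cover
every pixel, and averages overlapping tiles. The default stride is 4 px:
with non-overlapping tiles (stride 11) the assembled map has block
artefacts whose maxima snap to the tile grid and peak localisation
degrades markedly, while stride-4 overlap-averaging smooths the map at
acceptable cost (~0.5 s for a 570 px square field). The stride is a
config parameter.

Peak extraction: threshold (default 0.5) → 8-connected local maxima
(plateaus admit all their pixels) → link candidates closer than
`min_separation` (default 6 px ≈ 2.6 μm) → one intensity-weighted
centroid per connected component, repeated until all centroids are
pairwise ≥ `min_separation` apart. Connected components are a
conservative superset of cliques; the procedure is deterministic and is
verified against an exhaustive brute-force oracle on small maps. The
threshold and separation defaults are plausible nucleus-scale choices
and are exposed in config.

Detector evaluation uses greedy closest-first one-to-one matching at
3 px tolerance; under-detection concentrates where nuclei overlap inside
dense nests, where two merged nuclei genuinely render as one blob.

## Classification

Patches are 51 × 51 px centred on the detected position (mirror-padded
at image borders), bilinearly resized to 224 × 224. The stand-in
classifier computes 16 rotation-invariant features per patch — darkness
mass, second-moment scale and elongation, mean chromatin colour, peak
darkness, texture sd, and a 7-ring radial darkness profile, all under a
Gaussian focus window centred on the cell — and fits a seeded
gradient-boosted tree ensemble. Rotation invariance is the operative
choice: raw downsampled pixels confuse the spindle-shaped types at
random orientations (held-out recall ~0.55–0.75), while the invariant
features separate all eight types (recall ≥ 0.85). Classes absent from
training receive probability zero; the emitted 9-vector always sums
to 1.

The unknown rule follows the strict reading of "below 50%": a cell keeps
the argmax label when the winning probability is ≥ 0.5 and is reassigned
to *unknown* only strictly below. Argmax ties break by fixed vocabulary
order.

## Spatial metrics

"Within the neighbourhood" is a closed disc (distance ≤ r); the default
radius is 44 μm = 100 px at 0.44 μm/px, with 22 and 88 μm for the
sensitivity analysis. Neighbourhood queries use a KD-tree and are tested
for exact agreement with an O(n²) all-pairs oracle. Unknown cells enter
no metric; cancer cells are never counted in the stromal subgroups. The
intra-tumour endothelial count is the tumour-associated endothelial
count under the same 44 μm rule — no additional tumour-region mask is
applied. Patient metrics are arithmetic means over the patient's slides,
and the endothelial/cancer ratio is mean-then-divide (patient-level
numerator over patient-level denominator), not a mean of per-slide
ratios; a zero patient-level cancer count raises an explicit
undefined-ratio error rather than returning 0 or infinity.

Coordinates are 0-based with x = column, y = row, origin top-left.
Density-map bins and concordance windows are half-open
(`floor(coord / edge)`), so a cell exactly on a boundary belongs to the
higher-index bin. Ternary rendering colours each bin by the barycentric
mix of the three selected types' count shares (red/green/blue
primaries); bins empty of all three types are white.

## Outcome analysis

High/low stratification defaults to the cohort median with ties at the
cutpoint assigned low; the cutpoint is always reported so alternative
rules stay auditable. The two-group log-rank statistic and the
Kaplan–Meier product-limit estimator are implemented directly (they are
part of the reported analysis surface) and verified against hand-derived
toys and against lifelines on random data. The adjusted proportional-
hazards fit delegates to lifelines' `CoxPHFitter` with its Efron tie
correction; ties are therefore handled identically across runs. Patients
with missing covariates are dropped listwise and the count logged.
Non-convergence raises an explicit error; strata with fewer than two
patients or no events are skipped with a warning in subgroup analyses.

## Registration and concordance

The published registration pipeline behind the original validation is
not available as a specification, so the estimator here is a transparent
two-stage procedure defined by its recovery tests: (1) a coarse grid
search over {flip} × rotation (±20° in 2° steps) × scale, scoring each
candidate by FFT cross-correlation of mean-centred, Gaussian-smoothed
point-density rasters (10 μm bins, smoothing 1.5 bins), which also
yields the translation at the correlation peak; (2) trimmed ICP — keep
the best 80% of nearest-neighbour matches, refit a similarity transform
(Umeyama), iterate to convergence — which refines rotation, scale and
translation at full coordinate precision while the flip stays frozen.
The 80% trim absorbs the tested 10% outlier fraction plus dropout. On
synthetic sections (~1,600 cells, 5 μm positional noise, 10% dropout,
10% outliers) the planted flip + 7° + (50, −30) μm transform is
recovered within ~0.1° and ~1 μm.

Gating is threshold-based (per-marker thresholds, default 1.0);
lymphocyte gating is an OR over CD3e/CD4/CD8/CD20. A cell satisfying
several signatures takes the highest-priority type
(epithelial > endothelial > macrophage > lymphocyte) and the conflict
count is logged — a deterministic analogue of manual gating. The window
edge defaults to 1,887 μm, the physical window size of the original
validation design; the stated pixel count at the stated mIF resolution
is inconsistent with that physical size, and the physical units are
taken as authoritative because they are modality-independent. Synthetic
tests use smaller windows (250 μm) scaled to the synthetic fields.
Spearman correlations with two-sided p and an OLS slope with 95% CI are
reported per type; zero-variance counts yield NaN rho (reported, not an
error).

## Pipeline and reproducibility

The composed pipeline (simulate → detect → classify → metrics →
survival) writes per-stage CSVs and a manifest with parameters, seeds
and SHA-256 hashes of every output. CSV floats are written at fixed
6-decimal precision, so identical configs rerun byte-identically. The
bundled smoke configuration uses 2 training slides and 5 patients on
220 μm fields, completing in well under a minute; the acceptance script
uses 20 training slides for detection and 200 replicates at n = 1,000
for hazard-ratio recovery.

## Known limitations

- The rendering model is a separability device; no claim is made about
  detector/classifier performance on real H&E (stain variation, blur,
  tissue folds, touching nuclei are unmodelled).
- The survival generator is exponential with a single binary effect;
  recovery tests therefore check estimator correctness, not robustness
  to non-proportional hazards.
- The registration estimator assumes a global similarity transform plus
  a flip; it does not model local tissue deformation.
- Gating thresholds are synthetic-scale defaults; real mIF panels need
  per-marker calibration.
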