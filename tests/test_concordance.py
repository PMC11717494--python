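"""Cross-modality concordance: gating, registration, windows, correlation."""

import numpy as np
import pandas as pd
import pytest

from histocoloc.concordance import (
    GatingPanel,
    WindowSpec,
    concordance,
    estimate_registration,
    gate_cells,
    window_counts,
)
from histocoloc.synth import (
    PairedModalityParams,
    TissueSimParams,
    simulate_paired_mif,
    simulate_slide,
)
from histocoloc.transforms import PlanarTransform

from .conftest import make_slide_params

#: H&E type -> expected gate label for mIF comparison.
TYPE_TO_GATE = {
    "cancer_epithelial": "epithelial",
    "normal_epithelial": "epithelial",
    "lymphocyte": "lymphocyte",
    "macrophage": "macrophage",
    "endothelial": "endothelial",
    "fibroblast": "",
    "neutrophil": "",
    "myocyte": "",
}


def big_slide(seed=3, field=1500.0):
    return simulate_slide(
        TissueSimParams(
            field_size=(field, field),
            n_cancer=600,
            n_per_stromal_type={
                "normal_epithelial": 100,
                "fibroblast": 250,
                "lymphocyte": 300,
                "neutrophil": 60,
                "macrophage": 120,
                "endothelial": 120,
                "myocyte": 60,
            },
            nest_count=5,
            nest_radius=100.0,
            infiltration=0.5,
            vessel_count=8,
            seed=seed,
        )
    )


class TestGating:
    def test_all_zero_intensities_untype_everything(self):
        t = pd.DataFrame(
            {m: [0.0, 0.0] for m in ("pan_cytokeratin", "CD3e", "CD4", "CD8", "CD20",
                                      "CD68", "CD31")}
        )
        g = gate_cells(t)
        assert (g.gated_type == "").all()

    def test_zero_noise_simulation_fully_recovered(self):
        table = simulate_slide(make_slide_params(20))
        mif = simulate_paired_mif(table, PairedModalityParams(flip=False, marker_noise_sd=0.0))
        g = gate_cells(mif)
        assert (g.true_type.map(TYPE_TO_GATE) == g.gated_type).all()

    def test_cd31_only_cell_is_endothelial(self):
        row = {m: 0.1 for m in ("pan_cytokeratin", "CD3e", "CD4", "CD8", "CD20", "CD68")}
        row["CD31"] = 2.5
        g = gate_cells(pd.DataFrame([row]))
        assert g.gated_type.iloc[0] == "endothelial"

    def test_lymphocyte_gate_is_or_over_four_markers(self):
        base = {m: 0.1 for m in ("pan_cytokeratin", "CD3e", "CD4", "CD8", "CD20",
                                  "CD68", "CD31")}
        for marker in ("CD3e", "CD4", "CD8", "CD20"):
            row = dict(base)
            row[marker] = 2.0
            assert gate_cells(pd.DataFrame([row])).gated_type.iloc[0] == "lymphocyte"

    def test_conflict_resolved_by_priority(self):
        row = {m: 0.1 for m in ("CD3e", "CD4", "CD8", "CD20", "CD68")}
        row["pan_cytokeratin"] = 3.0
        row["CD31"] = 3.0
        g = gate_cells(pd.DataFrame([row]))
        assert g.gated_type.iloc[0] == "epithelial"

    def test_missing_marker_column_rejected(self):
        t = pd.DataFrame({"CD68": [1.0]})
        with pytest.raises(ValueError, match="missing"):
            gate_cells(t)

    def test_empty_signature_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GatingPanel(signatures={"epithelial": ()})


class TestRegistration:
    def test_identity_on_identical_point_sets(self):
        pts = big_slide().points()
        r = estimate_registration(pts, pts)
        assert not r.transform.flip
        assert abs(r.transform.rotation_deg) <= 0.5
        assert np.linalg.norm(r.transform.translation) <= 1.0

    def test_planted_transform_recovered_under_noise_and_outliers(self, rng):
        table = big_slide()
        params = PairedModalityParams(
            flip=True, rotation_deg=7.0, translation=(50.0, -30.0),
            positional_noise_sd=5.0, detection_dropout=0.10,
        )
        mif = simulate_paired_mif(table, params)
        pts_b = mif[["x_um", "y_um"]].to_numpy()
        outliers = rng.uniform(pts_b.min(0), pts_b.max(0), size=(len(pts_b) // 10, 2))
        pts_b = np.concatenate([pts_b, outliers])
        r = estimate_registration(table.points(), pts_b)
        assert r.transform.flip
        assert abs(r.transform.rotation_deg - 7.0) <= 1.0
        assert np.linalg.norm(np.subtract(r.transform.translation, (50.0, -30.0))) <= 5.0

    def test_reestimation_after_alignment_is_identity(self):
        table = big_slide(seed=4)
        mif = simulate_paired_mif(
            table, PairedModalityParams(flip=True, rotation_deg=-5.0,
                                        translation=(20.0, 35.0), positional_noise_sd=2.0)
        )
        pts_a, pts_b = table.points(), mif[["x_um", "y_um"]].to_numpy()
        r1 = estimate_registration(pts_a, pts_b)
        moved = r1.transform.apply(pts_a)
        r2 = estimate_registration(moved, pts_b)
        assert not r2.transform.flip
        assert abs(r2.transform.rotation_deg) <= 0.5
        assert np.linalg.norm(r2.transform.translation) <= 2.0

    def test_too_few_points_rejected(self):
        pts = np.random.default_rng(0).uniform(0, 100, (10, 2))
        with pytest.raises(ValueError, match=">= 20"):
            estimate_registration(pts, pts)

    def test_collinear_points_rejected(self):
        pts = np.stack([np.arange(30.0), np.arange(30.0) * 2.0], axis=1)
        with pytest.raises(ValueError, match="degenerate"):
            estimate_registration(pts, pts)


class TestWindowCounts:
    def test_empty_tables_give_empty_frame(self):
        empty = pd.DataFrame(columns=["x_um", "y_um", "cell_type"])
        out = window_counts(empty, empty.rename(columns={"cell_type": "gated_type"}))
        assert len(out) == 0

    def test_conservation_minus_exclusions(self):
        rng = np.random.default_rng(1)
        a = pd.DataFrame(
            {"x_um": rng.uniform(0, 400, 300), "y_um": rng.uniform(0, 400, 300),
             "cell_type": "lymphocyte"}
        )
        b = pd.DataFrame(
            {"x_um": rng.uniform(0, 400, 200), "y_um": rng.uniform(0, 400, 200),
             "gated_type": "lymphocyte"}
        )
        spec = WindowSpec(window_edge_um=100.0)
        full = window_counts(a, b, spec)
        assert full.count_a.sum() == 300
        assert full.count_b.sum() == 200
        excl = WindowSpec(window_edge_um=100.0, excluded=frozenset({(0, 0), (1, 2)}))
        part = window_counts(a, b, excl)
        assert part.count_a.sum() <= full.count_a.sum()
        assert part.count_b.sum() <= full.count_b.sum()
        dropped = full.merge(
            pd.DataFrame([{"window_ix": 0, "window_iy": 0}, {"window_ix": 1, "window_iy": 2}])
        )
        assert part.count_a.sum() == full.count_a.sum() - dropped.count_a.sum()

    def test_boundary_cell_goes_to_higher_window(self):
        a = pd.DataFrame(
            {"x_um": [0.0, 100.0], "y_um": [0.0, 0.0], "cell_type": "lymphocyte"}
        )
        b = pd.DataFrame(columns=["x_um", "y_um", "gated_type"])
        out = window_counts(a, b, WindowSpec(window_edge_um=100.0))
        at = out.set_index(["window_ix", "window_iy", "cell_type"]).count_a
        assert at[(0, 0, "lymphocyte")] == 1
        assert at[(1, 0, "lymphocyte")] == 1

    def test_exclusion_monotonicity(self):
        rng = np.random.default_rng(2)
        a = pd.DataFrame(
            {"x_um": rng.uniform(0, 300, 200), "y_um": rng.uniform(0, 300, 200),
             "cell_type": "epithelial"}
        )
        b = a.rename(columns={"cell_type": "gated_type"})
        masks = [frozenset(), frozenset({(0, 0)}), frozenset({(0, 0), (1, 1)})]
        totals = [
            window_counts(a, b, WindowSpec(100.0, m)).count_a.sum() for m in masks
        ]
        assert totals[0] >= totals[1] >= totals[2]


class TestConcordance:
    @staticmethod
    def paired(a, b, t="lymphocyte"):
        return pd.DataFrame(
            {"window_ix": range(len(a)), "window_iy": 0, "cell_type": t,
             "count_a": a, "count_b": b}
        )

    def test_identical_counts_rho_one(self):
        res = concordance(self.paired([1, 5, 9, 2], [1, 5, 9, 2]))
        assert res.stats.rho.iloc[0] == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        res = concordance(self.paired([1, 2, 3, 4], [9, 7, 5, 1]))
        assert res.stats.rho.iloc[0] == pytest.approx(-1.0)

    def test_matches_rank_then_correlate_oracle(self, rng):
        a = rng.integers(0, 300, 50).astype(float)
        b = a + rng.normal(0, 40, 50)
        res = concordance(self.paired(a, b))
        ra, rb = pd.Series(a).rank().to_numpy(), pd.Series(b).rank().to_numpy()
        expected = np.corrcoef(ra, rb)[0, 1]
        assert res.stats.rho.iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_reported_as_nan(self):
        res = concordance(self.paired([3, 3, 3, 3], [1, 2, 3, 4]))
        assert np.isnan(res.stats.rho.iloc[0])

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            concordance(self.paired([1, 2], [1, 2]))

    def test_end_to_end_abundant_types_concordant(self, rng):
        """With moderate noise (5 μm positional sd, 10% dropout, marker
        noise), windowed counts correlate at rho >= 0.9 for the abundant
        epithelial and lymphocyte populations and strictly less for the
        sparse endothelial population."""
        table = big_slide(seed=5, field=2000.0)
        mif = simulate_paired_mif(
            table,
            PairedModalityParams(flip=True, rotation_deg=4.0, translation=(30.0, -20.0),
                                 positional_noise_sd=5.0, marker_noise_sd=0.15,
                                 detection_dropout=0.10),
        )
        gated = gate_cells(mif)
        reg = estimate_registration(table.points(), gated[["x_um", "y_um"]].to_numpy())
        he = table.df.copy()
        he[["x_um", "y_um"]] = reg.transform.apply(table.points())
        he["cell_type"] = he.cell_type.map(TYPE_TO_GATE)
        paired = window_counts(
            he[he.cell_type != ""], gated[gated.gated_type != ""],
            WindowSpec(window_edge_um=250.0),
            types=("epithelial", "lymphocyte", "macrophage", "endothelial"),
        )
        res = concordance(paired).stats.set_index("cell_type")
        assert res.loc["epithelial", "rho"] >= 0.9
        assert res.loc["lymphocyte", "rho"] >= 0.9
        assert res.loc["endothelial", "rho"] < res.loc["epithelial", "rho"]
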