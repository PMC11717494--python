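"""Shared fixtures: synthetic slides and trained toy models.

Everything is generated programmatically at test time; expensive model
fits are session-scoped so the suite trains each model once.
"""

from __future__ import annotations

import numpy as np
import pytest

from histocoloc.classification import train_toy_classifier
from histocoloc.detection import DetectorPatchSpec, train_toy_detector
from histocoloc.synth import TissueSimParams, render_slide, simulate_slide

#: Stromal mix used by most test slides (cells per 250 x 250 μm field).
TEST_STROMAL_MIX = {
    "normal_epithelial": 25,
    "fibroblast": 60,
    "lymphocyte": 60,
    "neutrophil": 15,
    "macrophage": 25,
    "endothelial": 25,
    "myocyte": 15,
}


def make_slide_params(seed: int, field: float = 250.0, infiltration: float = 0.5,
                      **overrides) -> TissueSimParams:
    kwargs = dict(
        n_cancer=120,
        n_per_stromal_type=dict(TEST_STROMAL_MIX),
        nest_count=2,
        nest_radius=50.0,
        infiltration=infiltration,
        vessel_count=2,
        field_size=(field, field),
        seed=seed,
    )
    kwargs.update(overrides)
    return TissueSimParams(**kwargs)


def make_rendered_slide(seed: int, **overrides):
    """(image, truth_px, ground-truth table) for one synthetic slide."""
    table = simulate_slide(make_slide_params(seed, **overrides))
    img, truth = render_slide(table)
    return img, truth, table


@pytest.fixture(scope="session")
def rendered_slides():
    """Twelve rendered training slides keyed 0..11."""
    return {s: make_rendered_slide(s) for s in range(12)}


@pytest.fixture(scope="session")
def toy_detector(rendered_slides):
    imgs = [rendered_slides[s][0] for s in range(12)]
    truths = [rendered_slides[s][1] for s in range(12)]
    return train_toy_detector(imgs, truths, spec=DetectorPatchSpec(stride=4), seed=0)


@pytest.fixture(scope="session")
def toy_classifier(rendered_slides):
    annotations = []
    for s in range(6):
        img, truth, table = rendered_slides[s]
        for pt, ct in zip(truth, table.df.cell_type):
            annotations.append((img, tuple(pt), ct))
    return train_toy_classifier(annotations, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
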