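"""Shared fixtures: synthetic fields, annotation sets and derived tables.

Expensive renderings are session-scoped and reused across unit and
end-to-end tests; everything is seeded so the suite is deterministic.
"""

from __future__ import annotations

import copy

import numpy as np
import pytest

from phenogate.classify import train_linear, train_supervised
from phenogate.features import build_cell_table
from phenogate.segmentation import SegmentationParams, segment_field
from phenogate.synthdata import (
    FieldParams,
    label_records_with_truth,
    make_annotation_set,
    render_field,
)

BALANCED_MIXTURE = {
    "healthy": 0.25,
    "initial_apoptotic": 0.25,
    "late_apoptotic": 0.25,
    "necrotic": 0.25,
}


@pytest.fixture(scope="session")
def seg_params() -> SegmentationParams:
    return SegmentationParams()


@pytest.fixture(scope="session")
def mixed_well(seg_params):
    """One 500-cell well (4 fields x 125 cells, balanced phenotypes) run
    through segmentation + features, with ground-truth labels attached.

    Returns (records, regions_list, truth_labels).
    """
    rng = np.random.default_rng(42)
    records, regions_list = [], []
    for fi in range(4):
        img, truth = render_field(
            BALANCED_MIXTURE, 125, FieldParams(), rng, well="B02", field_index=fi
        )
        regions, backgrounds = segment_field(img, seg_params)
        recs = build_cell_table(regions, img, backgrounds)
        records.extend(label_records_with_truth(recs, regions, truth))
        regions_list.append(regions)
    labels = [r.class_label for r in records]
    return records, regions_list, labels


@pytest.fixture(scope="session")
def annotation_set():
    """60 labeled cells per class from inducer-like reference fields."""
    return make_annotation_set(n_per_class=60, seed=7)


@pytest.fixture(scope="session")
def linear_model(annotation_set):
    return train_linear(annotation_set, seed=0)


@pytest.fixture(scope="session")
def supervised_model(annotation_set):
    return train_supervised(annotation_set, seed=0)


@pytest.fixture(scope="session")
def frag_annotation_set():
    """Annotation set including fragmented dye-negative cells labeled as
    initial apoptotic."""
    return make_annotation_set(n_per_class=60, seed=21, include_fragmented=True)


@pytest.fixture(scope="session")
def fragmented_heldout(seg_params):
    """Held-out fragmented dye-negative cells (feature records only)."""
    from scipy import ndimage as ndi

    rng = np.random.default_rng(500)
    out = []
    for _ in range(2):
        img, truth = render_field(
            {"fragmented_dye_negative": 0.7, "healthy": 0.3},
            60,
            FieldParams(edge_margin_px=16),
            rng,
        )
        regions, backgrounds = segment_field(img, seg_params)
        recs = build_cell_table(regions, img, backgrounds)
        ids = [r.cell_id for r in recs]
        cents = ndi.center_of_mass(regions.nuclei > 0, regions.nuclei, ids)
        tpos = np.array([[t.row, t.col] for t in truth])
        for rec, cen in zip(recs, cents):
            d = np.hypot(tpos[:, 0] - cen[0], tpos[:, 1] - cen[1])
            j = int(np.argmin(d))
            if d[j] <= 10 and truth[j].cell_class == "fragmented_dye_negative":
                out.append(rec)
    return out


def strip_labels(records):
    """Deep-copied records with class labels removed."""
    out = [copy.deepcopy(r) for r in records]
    for r in out:
        r.class_label = None
    return out
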