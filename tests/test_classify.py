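"""Classification backends: gating tree, linear discriminant, supervised
trees, morphology flags."""

import copy
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenogate.classify import (
    CellClass,
    GatingExclusion,
    GatingThresholds,
    MIN_CELLS_PER_CLASS,
    TrainingError,
    flag_morphology_outliers,
    gate_cell,
    gate_cells,
    predict_supervised,
    train_linear,
    train_supervised,
)
from phenogate.features import CLASS_LABELS, CellRecord
from tests.conftest import strip_labels


def ratio_record(yopro: float, annexin: float, **extra) -> CellRecord:
    feats = {
        "nuclei_eroded_yopro_bg_ratio": yopro,
        "nuclei_yopro_bg_ratio": yopro,
        "cell_annexin_bg_ratio": annexin,
    }
    feats.update(extra)
    return CellRecord(cell_id=1, well="A01", field_index=0, features=feats)


def brute_force_gate(yopro, annexin, thr=2.0) -> str:
    """Independent enumeration of the four (Yo-Pro+/-, annexin+/-) combos."""
    table = {
        (True, True): "late_apoptotic",
        (True, False): "necrotic",
        (False, True): "initial_apoptotic",
        (False, False): "healthy",
    }
    return table[(yopro > thr, annexin > thr)]


class TestGateCell:
    @pytest.mark.parametrize(
        "yopro,annexin,expected",
        [
            (3.0, 3.0, CellClass.late_apoptotic),
            (2.5, 1.5, CellClass.necrotic),
            (1.5, 2.5, CellClass.initial_apoptotic),
            (1.0, 1.0, CellClass.healthy),
            (2.0, 3.0, CellClass.initial_apoptotic),  # exactly 2.0: negative branch
            (2.0, 2.0, CellClass.healthy),
            (3.0, 2.0, CellClass.necrotic),
        ],
    )
    def test_decision_tree(self, yopro, annexin, expected):
        assert gate_cell(ratio_record(yopro, annexin)) is expected

    def test_missing_ratio_raises_exclusion(self):
        rec = CellRecord(cell_id=1, well="A01", field_index=0,
                         features={"cell_annexin_bg_ratio": 1.0})
        with pytest.raises(GatingExclusion, match="Yo-Pro"):
            gate_cell(rec)

    def test_excluded_cells_carry_reason(self):
        good = ratio_record(1.0, 1.0)
        bad = CellRecord(cell_id=2, well="A01", field_index=0, features={})
        labeled, excluded = gate_cells([good, bad])
        assert len(labeled) == 1 and len(excluded) == 1
        assert "missing" in excluded[0][1]

    def test_eroded_region_falls_back_to_plain_nucleus(self):
        rec = CellRecord(cell_id=1, well="A01", field_index=0, features={
            "nuclei_eroded_yopro_bg_ratio": math.nan,
            "nuclei_yopro_bg_ratio": 3.0,
            "cell_annexin_bg_ratio": 1.0,
        })
        assert gate_cell(rec) is CellClass.necrotic

    @settings(derandomize=True, max_examples=200)
    @given(
        yopro=st.floats(0.5, 4.0, allow_nan=False),
        annexin=st.floats(0.5, 4.0, allow_nan=False),
    )
    def test_matches_brute_force_enumeration(self, yopro, annexin):
        assert gate_cell(ratio_record(yopro, annexin)).value == brute_force_gate(yopro, annexin)

    @settings(derandomize=True, max_examples=100)
    @given(
        yopro=st.floats(0.5, 4.0, allow_nan=False),
        annexin=st.floats(0.5, 4.0, allow_nan=False),
        thr_lo=st.floats(1.1, 3.0, allow_nan=False),
        bump=st.floats(0.0, 2.0, allow_nan=False),
    )
    def test_raising_yopro_threshold_monotone(self, yopro, annexin, thr_lo, bump):
        """Raising the Yo-Pro threshold never moves a cell into the positive branch."""
        lo = gate_cell(ratio_record(yopro, annexin), GatingThresholds(yopro_ratio_min=thr_lo))
        hi = gate_cell(ratio_record(yopro, annexin), GatingThresholds(yopro_ratio_min=thr_lo + bump))
        positive = {CellClass.late_apoptotic, CellClass.necrotic}
        if lo not in positive:
            assert hi not in positive

    def test_thresholds_must_exceed_one(self):
        with pytest.raises(ValueError):
            GatingThresholds(yopro_ratio_min=1.0)


def _separable_clusters(n_per_class=60, seed=0):
    """Four linearly separable synthetic clusters in the gating features."""
    rng = np.random.default_rng(seed)
    centers = {
        "healthy": (1.0, 1.0),
        "initial_apoptotic": (1.0, 3.5),
        "late_apoptotic": (3.5, 3.5),
        "necrotic": (3.5, 1.0),
    }
    records = []
    for label, (y0, a0) in centers.items():
        for i in range(n_per_class):
            records.append(ratio_record(
                y0 + rng.normal(0, 0.1), a0 + rng.normal(0, 0.1),
                nuclei_hoechst_mean=rng.normal(300, 10),
                nucleus_area_px=rng.normal(150, 5),
                nucleus_circularity=0.9,
                cell_circularity=0.9,
                nuclear_cytoplasm_area_ratio=0.5,
                nucleus_fragment_count=1.0,
            ))
            records[-1].class_label = label
            records[-1].cell_id = len(records)
    return records


class TestTrainLinear:
    def test_39_in_one_class_fails(self):
        records = _separable_clusters(40)
        drop = next(r for r in records if r.class_label == "healthy")
        records.remove(drop)
        with pytest.raises(TrainingError, match="40"):
            train_linear(records)

    def test_40_per_class_succeeds(self):
        model = train_linear(_separable_clusters(40))
        assert all(n >= MIN_CELLS_PER_CLASS for n in model.n_per_class.values())

    def test_separable_clusters_perfect_training_accuracy(self):
        model = train_linear(_separable_clusters(60))
        assert model.training_accuracy == 1.0

    def test_agreement_with_gating_on_heldout(self, annotation_set):
        # train on gate-produced labels, check held-out agreement with gating
        gated_train, _ = gate_cells(strip_labels(annotation_set[::2]))
        heldout, _ = gate_cells(strip_labels(annotation_set[1::2]))
        model = train_linear(gated_train)
        preds = model.predict(heldout)
        agreement = np.mean([p.value == r.class_label for p, r in zip(preds, heldout)])
        assert agreement >= 0.95

    def test_row_order_invariance(self):
        records = _separable_clusters(45, seed=3)
        m1 = train_linear(records)
        m2 = train_linear(list(reversed(records)))
        np.testing.assert_array_equal(m1.coef, m2.coef)

    def test_json_roundtrip(self, tmp_path):
        model = train_linear(_separable_clusters(40))
        path = tmp_path / "model.json"
        model.to_json(path)
        from phenogate.classify import LinearClassifierModel

        back = LinearClassifierModel.from_json(path)
        probe = _separable_clusters(2, seed=9)
        assert [p.value for p in back.predict(probe)] == [p.value for p in model.predict(probe)]


class TestTrainSupervised:
    def test_single_class_degenerate(self):
        records = [r for r in _separable_clusters(50) if r.class_label == "healthy"]
        with pytest.raises(TrainingError, match="2 classes"):
            train_supervised(records)

    def test_training_accuracy_at_least_linear(self, annotation_set, linear_model, supervised_model):
        assert supervised_model.training_accuracy >= linear_model.training_accuracy - 1e-12

    def test_permuted_rows_identical_predictions(self, annotation_set):
        rng = np.random.default_rng(0)
        shuffled = list(annotation_set)
        rng.shuffle(shuffled)
        m1 = train_supervised(annotation_set, seed=5)
        m2 = train_supervised(shuffled, seed=5)
        probe = annotation_set[:25]
        assert [p.value for p in m1.predict(probe)] == [p.value for p in m2.predict(probe)]

    def test_binary_serialization_roundtrip(self, supervised_model, annotation_set, tmp_path):
        from phenogate.classify import SupervisedModel

        path = tmp_path / "model.joblib"
        supervised_model.save(path)
        back = SupervisedModel.load(path)
        probe = annotation_set[:20]
        assert [p.value for p in back.predict(probe)] == [
            p.value for p in supervised_model.predict(probe)
        ]

    def test_predict_single_record(self, supervised_model, annotation_set):
        rec = annotation_set[0]
        assert predict_supervised(supervised_model, rec).value in CLASS_LABELS

    def test_fragmented_dye_negative_divergence(self, frag_annotation_set, fragmented_heldout):
        """Fragmented, dye-negative nuclei: gating says healthy, the
        annotation-trained supervised model says initial apoptotic."""
        model = train_supervised(frag_annotation_set, seed=0)
        gated, _ = gate_cells(strip_labels(fragmented_heldout))
        assert all(r.class_label == "healthy" for r in gated)
        preds = model.predict(fragmented_heldout)
        frac_early = np.mean([p is CellClass.initial_apoptotic for p in preds])
        assert frac_early >= 0.8


def _area_records(n, nucleus_area, cell_area, well="A01", label="healthy", seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        out.append(CellRecord(
            cell_id=i + 1, well=well, field_index=0,
            features={
                "nucleus_area_px": nucleus_area * rng.uniform(0.9, 1.1),
                "cell_area_px": cell_area * rng.uniform(0.9, 1.1),
            },
            class_label=label,
        ))
    return out


class TestMorphologyFlags:
    def test_reference_drawn_cells_rarely_flagged(self):
        ref = _area_records(200, 150, 600, seed=1)
        cells = _area_records(200, 150, 600, well="B01", seed=2)
        flags = flag_morphology_outliers(cells, ref)
        rate = np.mean(list(flags.senescent_like.values()))
        assert rate <= 0.05 + 0.05  # 95th-percentile construction + sampling error

    def test_doubled_areas_mostly_flagged(self):
        ref = _area_records(200, 150, 600, seed=3)
        cells = _area_records(100, 300, 1200, well="B02", seed=4)
        flags = flag_morphology_outliers(cells, ref)
        assert np.mean(list(flags.senescent_like.values())) > 0.8
        assert flags.enlarged_wells["B02"]

    def test_small_reference_skips_with_warning(self):
        flags = flag_morphology_outliers(_area_records(10, 150, 600), [])
        assert flags.skipped and "skipped" in flags.warning

    def test_only_healthy_cells_get_senescent_flag(self):
        ref = _area_records(100, 150, 600)
        cells = _area_records(10, 400, 1600, well="C01", label="necrotic", seed=5)
        flags = flag_morphology_outliers(cells, ref)
        assert flags.senescent_like == {}


class TestPartition:
    def test_every_cell_exactly_one_class(self, mixed_well):
        records, _, _ = mixed_well
        gated, excluded = gate_cells(strip_labels(records))
        assert len(gated) + len(excluded) == len(records)
        assert all(r.class_label in CLASS_LABELS for r in gated)
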