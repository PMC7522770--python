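"""Cell-death classification: gating decision tree, linear classifier,
supervised classifier, and post-classification morphology flags.

The four states follow the live-cell three-dye phenotyping convention:

* **healthy** — Yo-Pro-3 nuclear ratio < threshold, annexin V whole-cell
  ratio < threshold;
* **initial_apoptotic** — annexin V positive (phosphatidylserine exposed)
  while the membrane still excludes Yo-Pro-3;
* **late_apoptotic** — both dyes positive;
* **necrotic** — Yo-Pro-3 positive without annexin V.

Gating uses only the two background ratios (strict ``>`` comparison at a
2-fold default). The linear and supervised backends are trained on
annotated cells and may exploit morphology and texture as well — which is
what lets them separate phenotypes the dye ratios cannot (e.g. fragmented,
dye-negative nuclei).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import HistGradientBoostingClassifier

from .features import (
    CLASS_LABELS,
    LINEAR_FEATURES,
    SUPERVISED_FEATURES,
    CellRecord,
    records_to_matrix,
)


class CellClass(str, Enum):
    healthy = "healthy"
    initial_apoptotic = "initial_apoptotic"
    late_apoptotic = "late_apoptotic"
    necrotic = "necrotic"


assert tuple(c.value for c in CellClass) == CLASS_LABELS

#: Minimum annotated cells per class required to train the linear classifier.
MIN_CELLS_PER_CLASS = 40


class TrainingError(ValueError):
    pass


@dataclass
class GatingThresholds:
    """Fold-over-background cutoffs of the gating tree (strict >)."""

    yopro_ratio_min: float = 2.0
    annexin_ratio_min: float = 2.0
    #: region whose Yo-Pro ratio drives step 1: "nuclei_eroded" or "nuclei"
    yopro_region: str = "nuclei_eroded"

    def __post_init__(self):
        if self.yopro_ratio_min <= 1 or self.annexin_ratio_min <= 1:
            raise ValueError("gating thresholds must exceed 1")
        if self.yopro_region not in ("nuclei", "nuclei_eroded"):
            raise ValueError("yopro_region must be 'nuclei' or 'nuclei_eroded'")


class GatingExclusion(Exception):
    """A cell whose gating ratios are missing; carries the reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def _gating_ratios(record: CellRecord, thresholds: GatingThresholds) -> tuple[float, float]:
    yopro = record.get(f"{thresholds.yopro_region}_yopro_bg_ratio")
    if thresholds.yopro_region == "nuclei_eroded" and math.isnan(yopro):
        # degenerate erosion (tiny nucleus): fall back to the plain nucleus
        yopro = record.get("nuclei_yopro_bg_ratio")
    annexin = record.get("cell_annexin_bg_ratio")
    return yopro, annexin


def gate_cell(record: CellRecord, thresholds: GatingThresholds | None = None) -> CellClass:
    """Two-step decision tree on the dye background ratios.

    Step 1: nuclear Yo-Pro-3 ratio > ``yopro_ratio_min`` selects the
    late/necrotic branch, otherwise healthy/initial. Step 2 splits each
    branch on the whole-cell annexin V ratio: Yo-Pro+ cells become
    late_apoptotic (annexin+) or necrotic (annexin−); Yo-Pro− cells become
    initial_apoptotic (annexin+) or healthy (annexin−). Comparisons are
    strict, so a ratio exactly at threshold falls in the negative branch.

    Raises :class:`GatingExclusion` when a required ratio is missing; the
    caller logs the reason rather than dropping the cell silently.
    """
    thresholds = thresholds or GatingThresholds()
    yopro, annexin = _gating_ratios(record, thresholds)
    if math.isnan(yopro):
        raise GatingExclusion("missing nuclear Yo-Pro-3 background ratio")
    if math.isnan(annexin):
        raise GatingExclusion("missing whole-cell annexin V background ratio")
    if yopro > thresholds.yopro_ratio_min:
        return CellClass.late_apoptotic if annexin > thresholds.annexin_ratio_min else CellClass.necrotic
    return CellClass.initial_apoptotic if annexin > thresholds.annexin_ratio_min else CellClass.healthy


def gate_cells(
    records: Sequence[CellRecord], thresholds: GatingThresholds | None = None
) -> tuple[list[CellRecord], list[tuple[CellRecord, str]]]:
    """Gate a batch; returns (labeled records, excluded records with reasons)."""
    labeled, excluded = [], []
    for rec in records:
        try:
            rec.class_label = gate_cell(rec, thresholds).value
            labeled.append(rec)
        except GatingExclusion as exc:
            excluded.append((rec, exc.reason))
    return labeled, excluded


# ---------------------------------------------------------------------------
# Linear classifier
# ---------------------------------------------------------------------------

@dataclass
class LinearClassifierModel:
    """Multiclass linear discriminant over standardized features.

    Prediction is the argmax of the per-class linear scores; ties resolve
    to the class listed first in the canonical enumeration order.
    """

    feature_names: list[str]
    class_names: list[str]
    coef: np.ndarray  # (n_classes, n_features)
    intercept: np.ndarray  # (n_classes,)
    means: np.ndarray
    sds: np.ndarray
    n_per_class: dict[str, int] = dc_field(default_factory=dict)
    seed: int = 0
    training_accuracy: float = math.nan

    def decision_scores(self, records: Sequence[CellRecord]) -> np.ndarray:
        x = records_to_matrix(records, self.feature_names)
        x = np.nan_to_num(x, nan=0.0)
        z = (x - self.means) / self.sds
        return z @ self.coef.T + self.intercept

    def predict(self, records: Sequence[CellRecord]) -> list[CellClass]:
        scores = self.decision_scores(records)
        # reorder columns canonically; np.argmax takes the first maximum,
        # realizing the ties-to-first-enumerated-class rule
        order = [self.class_names.index(c) for c in CLASS_LABELS if c in self.class_names]
        names = [self.class_names[i] for i in order]
        return [CellClass(names[int(k)]) for k in np.argmax(scores[:, order], axis=1)]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema_version": 1,
            "feature_names": self.feature_names,
            "class_names": self.class_names,
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "n_per_class": self.n_per_class,
            "seed": self.seed,
            "training_accuracy": self.training_accuracy,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearClassifierModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=d["feature_names"],
            class_names=d["class_names"],
            coef=np.asarray(d["coef"]),
            intercept=np.asarray(d["intercept"]),
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            n_per_class=d["n_per_class"],
            seed=d["seed"],
            training_accuracy=d["training_accuracy"],
        )


def _check_labels(records: Sequence[CellRecord], minimum: int | None) -> dict[str, int]:
    counts = {c: 0 for c in CLASS_LABELS}
    for rec in records:
        if rec.class_label is None:
            raise TrainingError("training requires labeled records")
        counts[rec.class_label] += 1
    if minimum is not None:
        short = {c: n for c, n in counts.items() if n < minimum}
        if short:
            raise TrainingError(
                f"training requires at least {minimum} cells representative of each "
                f"population; short classes: {short}"
            )
    return counts


def _sorted_training(records: Sequence[CellRecord], feature_names) -> list[CellRecord]:
    # canonical row order so permuting the input cannot change the model
    def key(rec: CellRecord):
        return (rec.class_label, tuple(rec.get(f) for f in feature_names),
                rec.plate_id, rec.well, rec.field_index, rec.cell_id)

    return sorted(records, key=key)


def train_linear(
    annotated: Sequence[CellRecord],
    feature_subset: Sequence[str] = LINEAR_FEATURES,
    seed: int = 0,
) -> LinearClassifierModel:
    """Fit a regularized linear discriminant on standardized features.

    Requires at least :data:`MIN_CELLS_PER_CLASS` annotated cells per class
    (hard contract). Deterministic given the seed and the training set,
    regardless of row order.
    """
    counts = _check_labels(annotated, MIN_CELLS_PER_CLASS)
    feature_names = list(feature_subset)
    rows = _sorted_training(annotated, feature_names)
    x = np.nan_to_num(records_to_matrix(rows, feature_names), nan=0.0)
    y = np.array([r.class_label for r in rows])
    means = x.mean(axis=0)
    sds = x.std(axis=0)
    sds[sds == 0] = 1.0
    z = (x - means) / sds
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-4)
    lda.fit(z, y)
    model = LinearClassifierModel(
        feature_names=feature_names,
        class_names=list(lda.classes_),
        coef=np.asarray(lda.coef_, dtype=np.float64),
        intercept=np.asarray(lda.intercept_, dtype=np.float64),
        means=means,
        sds=sds,
        n_per_class=counts,
        seed=seed,
    )
    preds = model.predict(rows)
    model.training_accuracy = float(np.mean([p.value == t for p, t in zip(preds, y)]))
    return model


# ---------------------------------------------------------------------------
# Supervised classifier
# ---------------------------------------------------------------------------

@dataclass
class SupervisedModel:
    """Gradient-boosted trees over the 16 nucleus + 6 cell-body features."""

    feature_names: list[str]
    class_names: list[str]
    estimator: HistGradientBoostingClassifier
    class_priors: dict[str, float]
    seed: int = 0
    training_accuracy: float = math.nan

    def predict(self, records: Sequence[CellRecord]) -> list[CellClass]:
        x = records_to_matrix(records, self.feature_names)
        return [CellClass(v) for v in self.estimator.predict(x)]

    def save(self, path: str | Path) -> None:
        """Serialize to a portable binary file (joblib, schema-versioned)."""
        import joblib

        joblib.dump({"schema_version": 1, "model": self}, path)

    @classmethod
    def load(cls, path: str | Path) -> "SupervisedModel":
        import joblib

        payload = joblib.load(path)
        if payload.get("schema_version") != 1:
            raise ValueError("unsupported supervised-model schema version")
        return payload["model"]


def train_supervised(
    annotated: Sequence[CellRecord],
    seed: int = 0,
    feature_names: Sequence[str] = SUPERVISED_FEATURES,
) -> SupervisedModel:
    """Fit the supervised backend on annotated cells.

    At least two classes must be present. NaN features are handled natively
    by the tree model. Deterministic given seed; training rows are sorted
    canonically first so input order cannot matter.
    """
    counts = _check_labels(annotated, minimum=None)
    present = [c for c, n in counts.items() if n > 0]
    if len(present) < 2:
        raise TrainingError("supervised training needs at least 2 classes present")
    feature_names = list(feature_names)
    if len(feature_names) != 22:
        raise TrainingError(f"expected the 22-feature vector, got {len(feature_names)}")
    rows = _sorted_training(annotated, feature_names)
    x = records_to_matrix(rows, feature_names)
    y = np.array([r.class_label for r in rows])
    est = HistGradientBoostingClassifier(
        max_iter=200, learning_rate=0.1, max_depth=None, random_state=seed
    )
    est.fit(x, y)
    n = len(rows)
    model = SupervisedModel(
        feature_names=feature_names,
        class_names=list(est.classes_),
        estimator=est,
        class_priors={c: counts[c] / n for c in present},
        seed=seed,
    )
    preds = model.predict(rows)
    model.training_accuracy = float(np.mean([p.value == t for p, t in zip(preds, y)]))
    return model


def predict_supervised(model: SupervisedModel, record: CellRecord) -> CellClass:
    return model.predict([record])[0]


# ---------------------------------------------------------------------------
# Post-classification morphology flags
# ---------------------------------------------------------------------------

@dataclass
class MorphologyFlags:
    senescent_like: dict[tuple, bool]
    enlarged_wells: dict[str, bool]
    skipped: bool = False
    warning: str | None = None


def flag_morphology_outliers(
    cells: Sequence[CellRecord],
    healthy_reference: Sequence[CellRecord],
    enlarged_factor: float = 1.5,
    min_reference: int = 50,
) -> MorphologyFlags:
    """Flag healthy-classified cells that are morphologically unlike healthy
    controls.

    A healthy cell whose nucleus area *and* cell area both exceed the
    vehicle-control reference 95th percentiles is ``senescent_like`` (dead
    by no dye, but not normal — e.g. arrested, enlarged phenotypes). A well
    is ``enlarged`` when its median cell area exceeds the reference median
    by ``enlarged_factor``. Reference smaller than ``min_reference`` skips
    flagging with a warning rather than producing unstable percentiles.
    """
    if len(healthy_reference) < min_reference:
        return MorphologyFlags(
            senescent_like={},
            enlarged_wells={},
            skipped=True,
            warning=f"healthy reference has {len(healthy_reference)} cells "
            f"(< {min_reference}); morphology flags skipped",
        )
    ref_nuc = np.array([r.get("nucleus_area_px") for r in healthy_reference])
    ref_cell = np.array([r.get("cell_area_px") for r in healthy_reference])
    nuc95 = float(np.nanpercentile(ref_nuc, 95))
    cell95 = float(np.nanpercentile(ref_cell, 95))
    ref_cell_median = float(np.nanmedian(ref_cell))

    senescent = {}
    by_well: dict[str, list[float]] = {}
    for rec in cells:
        by_well.setdefault(rec.well, []).append(rec.get("cell_area_px"))
        if rec.class_label != CellClass.healthy.value:
            continue
        key = (rec.plate_id, rec.well, rec.field_index, rec.cell_id)
        senescent[key] = bool(
            rec.get("nucleus_area_px") > nuc95 and rec.get("cell_area_px") > cell95
        )
    enlarged = {
        well: bool(np.nanmedian(areas) > enlarged_factor * ref_cell_median)
        for well, areas in by_well.items()
    }
    return MorphologyFlags(senescent_like=senescent, enlarged_wells=enlarged)
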