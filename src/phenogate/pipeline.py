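"""End-to-end orchestration: segment -> features -> classify -> summarize ->
normalize -> fit, with a run manifest for provenance.

The manifest tracks per-stage cell counts and enforces the conservation
rules ``detected = retained + border_removed`` and
``classified + excluded = retained``; every excluded cell carries a reason
code, nothing is dropped silently.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

from . import __version__
from .classify import (
    GatingThresholds,
    LinearClassifierModel,
    SupervisedModel,
    gate_cells,
)
from .doseresponse import (
    DoseResponseFit,
    WellSummary,
    fit_compound,
    normalize_to_control,
    summarize_well,
)
from .features import CellRecord, build_cell_table
from .io import FieldImage, PlateMap
from .segmentation import (
    SegmentationParams,
    derive_regions,
    estimate_background,
    remove_border_cells,
    segment_cytoplasm,
    segment_nuclei,
    split_touching_nuclei,
)


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunManifest:
    """Provenance and bookkeeping of one pipeline run."""

    config_hash: str = ""
    seed: int = 0
    package_version: str = __version__
    inputs: list[str] = field(default_factory=list)
    detected: int = 0
    border_removed: int = 0
    retained: int = 0
    classified: int = 0
    excluded: int = 0
    exclusion_reasons: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        assert self.detected == self.retained + self.border_removed, "count conservation violated"
        assert self.classified + self.excluded == self.retained, "count conservation violated"
        assert self.excluded == sum(self.exclusion_reasons.values())

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def _config_hash(*objs) -> str:
    text = json.dumps([repr(o) for o in objs], sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    cells: list[CellRecord]
    summaries: list[WellSummary]
    fits: list[DoseResponseFit]
    manifest: RunManifest


def run_pipeline(
    fields: Sequence[FieldImage],
    plate_map: PlateMap,
    seg_params: SegmentationParams | None = None,
    method: str = "gating",
    thresholds: GatingThresholds | None = None,
    linear_model: LinearClassifierModel | None = None,
    supervised_model: SupervisedModel | None = None,
    response: str = "percent_healthy",
    fit_curves: bool = True,
    validate_regions: bool = True,
    seed: int = 0,
) -> PipelineResult:
    """Run the full analysis on a set of fields.

    ``method`` selects the classifier backend; linear/supervised require a
    trained model. Cells are pooled across the fields of each well before
    summarization; the 4PL is fitted per compound on wells with positive
    concentration.
    """
    seg_params = seg_params or SegmentationParams()
    thresholds = thresholds or GatingThresholds(
        yopro_region="nuclei_eroded" if seg_params.erosion_fraction > 0 else "nuclei"
    )
    manifest = RunManifest(
        config_hash=_config_hash(seg_params, thresholds, method, response),
        seed=seed,
        inputs=[f"{f.plate_id}/{f.well}/f{f.field_index}" for f in fields],
    )

    all_cells: list[CellRecord] = []
    for image in fields:
        try:
            plate_map.row(image.well)
        except Exception as exc:
            raise PipelineError("plate_map", str(exc))
        try:
            hoechst = image.channels["hoechst"]
            nuclei = segment_nuclei(hoechst, seg_params)
            nuclei = split_touching_nuclei(
                nuclei, hoechst, seg_params.splitting_sensitivity,
                enabled=seg_params.splitting_enabled,
                fragment_max_component_px=seg_params.fragment_max_component_px,
            )
            cell = segment_cytoplasm(hoechst, nuclei, seg_params)
            regions = derive_regions(nuclei, cell, seg_params.erosion_fraction)
            n_detected = len(regions.cell_ids)
            regions = remove_border_cells(regions)
            if validate_regions:
                regions.validate()
            backgrounds = {
                name: estimate_background(raster, cell)
                for name, raster in image.channels.items()
                if name != "brightfield"
            }
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("segmentation", f"{image.well}/f{image.field_index}: {exc}")
        try:
            records = build_cell_table(regions, image, backgrounds)
        except Exception as exc:
            raise PipelineError("features", f"{image.well}/f{image.field_index}: {exc}")
        manifest.detected += n_detected
        manifest.border_removed += n_detected - len(records)
        manifest.retained += len(records)
        all_cells.extend(records)

    try:
        if method == "gating":
            labeled, excluded = gate_cells(all_cells, thresholds)
        elif method == "linear":
            if linear_model is None:
                raise ValueError("method='linear' requires a trained linear model")
            preds = linear_model.predict(all_cells)
            for rec, p in zip(all_cells, preds):
                rec.class_label = p.value
            labeled, excluded = list(all_cells), []
        elif method == "supervised":
            if supervised_model is None:
                raise ValueError("method='supervised' requires a trained supervised model")
            preds = supervised_model.predict(all_cells)
            for rec, p in zip(all_cells, preds):
                rec.class_label = p.value
            labeled, excluded = list(all_cells), []
        else:
            raise ValueError(f"unknown method {method!r}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("classification", str(exc))
    manifest.classified = len(labeled)
    manifest.excluded = len(excluded)
    for _, reason in excluded:
        manifest.exclusion_reasons[reason] = manifest.exclusion_reasons.get(reason, 0) + 1

    try:
        by_well: dict[str, list[CellRecord]] = {}
        for rec in labeled:
            by_well.setdefault(rec.well, []).append(rec)
        summaries = []
        for row in plate_map:
            summaries.append(summarize_well(by_well.get(row.well, []), row))
        summaries = normalize_to_control(summaries, plate_map)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("summarize", str(exc))

    fits: list[DoseResponseFit] = []
    if fit_curves:
        compounds = sorted(
            {r.compound_id for r in plate_map if r.role == "sample" and r.concentration_um > 0}
        )
        for compound in compounds:
            try:
                fits.append(fit_compound(summaries, compound, response=response))
            except ValueError:
                continue  # too few usable doses for this compound

    manifest.validate()
    return PipelineResult(cells=labeled, summaries=summaries, fits=fits, manifest=manifest)
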