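"""Reading and writing of images, plate maps, configuration and tabular outputs.

All on-disk schemas of the pipeline live here:

* single-plane grayscale TIFF per channel, named
  ``{plate}_{well}_f{field}_{channel}.tif`` (or an explicit manifest CSV),
* a plate-map CSV mapping wells to compounds, concentrations (uM) and roles,
* the per-cell feature table CSV and per-well summary CSV,
* YAML pipeline configuration, JSON dose-response exports.

Pixel coordinates are 0-based ``(row, col)``; label masks use 0 for
background and positive integers for cell ids; concentrations are uM
throughout.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

#: Channels the analysis consumes. "brightfield" may be present but is never
#: used in computation.
REQUIRED_CHANNELS = ("hoechst", "annexin", "yopro")

#: Well roles recognized in a plate map.
WELL_ROLES = ("sample", "vehicle_control", "no_vehicle_control")

_FILENAME_RE = re.compile(
    r"^(?P<plate>[^_]+)_(?P<well>[A-Pa-p]\d{2})_f(?P<field>\d+)_(?P<channel>[A-Za-z]+)\.tiff?$"
)


class PlateMapError(ValueError):
    """Raised for malformed or incomplete plate maps."""


@dataclass
class FieldImage:
    """One imaging field: named channel rasters plus well/field identity.

    Channel rasters are 2D float arrays of identical shape with finite,
    non-negative intensities. Intensities are never rescaled on read.
    """

    plate_id: str
    well: str
    field_index: int
    channels: dict[str, np.ndarray]
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if self.field_index < 0:
            raise ValueError("field_index must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = set()
        for name, raster in self.channels.items():
            arr = np.asarray(raster, dtype=np.float64)
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not a single 2D plane")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if arr.min(initial=0.0) < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")
            self.channels[name] = arr
            shapes.add(arr.shape)
        if len(shapes) > 1:
            raise ValueError(f"channel rasters disagree in shape: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.channels.values()))
        return first.shape

    def require_channels(self, names: Iterable[str] = REQUIRED_CHANNELS) -> None:
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise KeyError(f"FieldImage {self.well}/f{self.field_index} missing required channel(s): {missing}")


def _read_single_plane(path: Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.ndim != 2:
        raise ValueError(f"{path}: color TIFFs are not supported; expected grayscale")
    if arr.ndim != 2:
        raise ValueError(f"{path}: multi-plane TIFF rejected; expected a single 2D plane")
    return np.asarray(arr, dtype=np.float64)


def read_field(
    source: str | Path | Mapping[str, str | Path],
    *,
    plate_id: str | None = None,
    well: str | None = None,
    field_index: int | None = None,
    pixel_size_um: float = 1.0,
) -> FieldImage:
    """Assemble a :class:`FieldImage` from per-channel TIFF files.

    ``source`` is either a mapping ``{channel_name: path}`` (identity taken
    from the keyword arguments) or a directory that is scanned for files
    following the ``{plate}_{well}_f{field}_{channel}.tif`` convention, in
    which case ``well`` and ``field_index`` select the field.

    Intensities are widened to float64 without rescaling. A missing required
    channel or a shape mismatch between channels is a hard error.
    """
    if isinstance(source, Mapping):
        channel_paths = {str(k): Path(v) for k, v in source.items()}
        if well is None or field_index is None:
            raise ValueError("well and field_index are required with an explicit channel mapping")
        plate = plate_id or "plate"
    else:
        directory = Path(source)
        if not directory.is_dir():
            raise FileNotFoundError(f"{directory} is not a directory")
        channel_paths = {}
        plate = plate_id
        for path in sorted(directory.iterdir()):
            m = _FILENAME_RE.match(path.name)
            if m is None:
                continue
            if well is not None and m["well"] != well:
                continue
            if field_index is not None and int(m["field"]) != field_index:
                continue
            channel_paths[m["channel"].lower()] = path
            plate = plate or m["plate"]
            well = well or m["well"]
            field_index = int(m["field"]) if field_index is None else field_index
        plate = plate or "plate"
        if well is None or field_index is None:
            raise FileNotFoundError(f"no files matching the naming convention found in {directory}")

    missing = [c for c in REQUIRED_CHANNELS if c not in channel_paths]
    if missing:
        raise KeyError(f"field {well}/f{field_index}: missing required channel(s): {missing}")
    channels = {name: _read_single_plane(p) for name, p in channel_paths.items()}
    return FieldImage(plate_id=plate, well=well, field_index=int(field_index), channels=channels, pixel_size_um=pixel_size_um)


def write_field(image: FieldImage, directory: str | Path, dtype=np.float64) -> list[Path]:
    """Write one TIFF per channel using the filename convention; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, raster in image.channels.items():
        path = directory / f"{image.plate_id}_{image.well}_f{image.field_index}_{name}.tif"
        tifffile.imwrite(str(path), raster.astype(dtype))
        written.append(path)
    return written


def read_field_manifest(manifest_csv: str | Path, well: str, field_index: int, **kwargs) -> FieldImage:
    """Read a field via a manifest CSV with columns file,well,field,channel."""
    df = pd.read_csv(manifest_csv)
    base = Path(manifest_csv).parent
    rows = df[(df["well"] == well) & (df["field"].astype(int) == field_index)]
    mapping = {str(r.channel): base / str(r.file) for r in rows.itertuples()}
    return read_field(mapping, well=well, field_index=field_index, **kwargs)


# ---------------------------------------------------------------------------
# Plate map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateMapRow:
    well: str
    compound_id: str
    concentration_um: float
    role: str
    replicate: int = 1

    def __post_init__(self):
        if self.role not in WELL_ROLES:
            raise PlateMapError(f"unknown well role {self.role!r}; expected one of {WELL_ROLES}")
        if self.concentration_um < 0:
            raise PlateMapError(f"negative concentration for well {self.well}")


@dataclass
class PlateMap:
    """Well -> (compound, concentration uM, role, replicate) table."""

    rows: list[PlateMapRow]

    def __post_init__(self):
        wells = [r.well for r in self.rows]
        dupes = {w for w in wells if wells.count(w) > 1}
        if dupes:
            raise PlateMapError(f"duplicate wells in plate map: {sorted(dupes)}")

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)

    def row(self, well: str) -> PlateMapRow:
        for r in self.rows:
            if r.well == well:
                return r
        raise PlateMapError(f"well {well!r} not present in plate map")

    @property
    def vehicle_wells(self) -> list[str]:
        return [r.well for r in self.rows if r.role == "vehicle_control"]

    def require_vehicle_controls(self) -> None:
        if not self.vehicle_wells:
            raise PlateMapError("plate map contains no vehicle_control wells; normalization impossible")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.rows])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PlateMap":
        rows = [
            PlateMapRow(
                well=str(r.well),
                compound_id=str(r.compound_id),
                concentration_um=float(r.concentration_um),
                role=str(r.role),
                replicate=int(getattr(r, "replicate", 1)),
            )
            for r in df.itertuples()
        ]
        return cls(rows)


def write_plate_map(pm: PlateMap, path: str | Path) -> None:
    pm.to_frame().to_csv(path, index=False)


def read_plate_map(path: str | Path) -> PlateMap:
    return PlateMap.from_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

CLASSIFIER_METHODS = ("gating", "linear", "supervised")


@dataclass
class PipelineConfig:
    """Bag of pipeline parameters with YAML (de)serialization.

    Segmentation and gating parameter dataclasses live in their own modules;
    this holds their values as plain dicts so the config file remains a
    single flat document.
    """

    segmentation: dict = field(default_factory=dict)
    gating: dict = field(default_factory=dict)
    classifier: str = "gating"
    dose_response: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.classifier not in CLASSIFIER_METHODS:
            raise ValueError(f"classifier must be one of {CLASSIFIER_METHODS}")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# Cell table and well summary I/O
# ---------------------------------------------------------------------------

#: Float format preserving >= 12 significant digits on round-trip.
_FLOAT_FMT = "%.17g"


def write_cell_table(cells: Sequence, path: str | Path) -> None:
    """Write CellRecords as CSV, one row per cell, in the documented column order.

    An empty list yields a header-only file. See
    :func:`phenogate.features.cell_records_to_frame` for the schema.
    """
    from .features import cell_records_to_frame

    frame = cell_records_to_frame(cells)
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cell_table(path: str | Path):
    """Read a per-cell CSV back into CellRecords; unknown class labels are a hard error."""
    from .features import frame_to_cell_records

    frame = pd.read_csv(path)
    return frame_to_cell_records(frame)


def write_well_summaries(summaries: Sequence, path: str | Path) -> None:
    from .doseresponse import summaries_to_frame

    summaries_to_frame(summaries).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_well_summaries(path: str | Path):
    from .doseresponse import frame_to_summaries

    return frame_to_summaries(pd.read_csv(path))


def write_fits_json(fits: Sequence, path: str | Path) -> None:
    """Export DoseResponseFit objects as a JSON list."""
    payload = [dataclasses.asdict(f) for f in fits]
    for entry in payload:
        for k, v in entry.items():
            if isinstance(v, float) and not np.isfinite(v):
                entry[k] = None
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_label_mask(mask: np.ndarray, path: str | Path) -> None:
    """Export a label mask as 16-bit TIFF (ids above 65535 rejected)."""
    if mask.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("label mask has ids exceeding 16-bit range")
    tifffile.imwrite(str(path), mask.astype(np.uint16))
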