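"""Per-cell measurement vectors: intensity, morphology and texture per region.

Every classifier backend consumes the same :class:`CellRecord`, holding for
each of the four segmentation regions (nuclei, cytoplasm, cell,
nuclei_eroded) and each dye channel (Hoechst, annexin V, Yo-Pro-3) the
intensity statistics and texture responses, plus nucleus/cell morphology.
``background_ratio`` — region mean divided by the field's non-cell
background for that channel — is the unit in which all "n-fold above
background" gating rules are expressed.

Missing values (empty region, degenerate erosion) are NaN, never silently
dropped rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops

REGIONS = ("nuclei", "cytoplasm", "cell", "nuclei_eroded")
CHANNELS = ("hoechst", "annexin", "yopro")
INTENSITY_STATS = ("mean", "sd", "max", "integrated", "bg_ratio")
SER_STATS = ("ser_spots", "ser_edges", "ser_ridges")

MORPHOLOGY_COLUMNS = (
    "nucleus_area_px",
    "cell_area_px",
    "nucleus_perimeter_px",
    "cell_perimeter_px",
    "nucleus_circularity",
    "cell_circularity",
    "nucleus_roundness",
    "nucleus_equivalent_radius_px",
    "nuclear_cytoplasm_area_ratio",
    "nucleus_fragment_count",
)

#: Recognized class labels, in canonical (tie-breaking) order.
CLASS_LABELS = ("healthy", "initial_apoptotic", "late_apoptotic", "necrotic")


def _intensity_columns() -> list[str]:
    return [f"{r}_{c}_{s}" for r in REGIONS for c in CHANNELS for s in INTENSITY_STATS]


def _texture_columns() -> list[str]:
    return [f"{r}_{c}_{s}" for r in REGIONS for c in CHANNELS for s in SER_STATS]


#: Documented, versioned column order of the per-cell CSV (schema v1).
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    _intensity_columns() + list(MORPHOLOGY_COLUMNS) + _texture_columns()
)

IDENTITY_COLUMNS = ("plate_id", "well", "field_index", "cell_id", "class_label")

#: The 16 nucleus features consumed by the supervised classifier.
NUCLEUS_FEATURES_16 = (
    "nuclei_hoechst_mean",
    "nuclei_hoechst_sd",
    "nuclei_hoechst_max",
    "nuclei_hoechst_integrated",
    "nuclei_yopro_mean",
    "nuclei_yopro_bg_ratio",
    "nucleus_area_px",
    "nucleus_perimeter_px",
    "nucleus_circularity",
    "nucleus_roundness",
    "nucleus_equivalent_radius_px",
    "nucleus_fragment_count",
    "nuclei_hoechst_ser_spots",
    "nuclei_hoechst_ser_edges",
    "nuclei_hoechst_ser_ridges",
    "nuclei_eroded_yopro_bg_ratio",
)

#: The 6 cell-body features consumed by the supervised classifier.
CELL_BODY_FEATURES_6 = (
    "cell_area_px",
    "cell_circularity",
    "cell_annexin_mean",
    "cell_annexin_bg_ratio",
    "cell_yopro_mean",
    "nuclear_cytoplasm_area_ratio",
)

SUPERVISED_FEATURES = NUCLEUS_FEATURES_16 + CELL_BODY_FEATURES_6

#: Compact, gating-adjacent subset for the linear classifier.
LINEAR_FEATURES = (
    "nuclei_eroded_yopro_bg_ratio",
    "nuclei_yopro_bg_ratio",
    "cell_annexin_bg_ratio",
    "nuclei_hoechst_mean",
    "nucleus_area_px",
    "nucleus_circularity",
    "cell_circularity",
    "nuclear_cytoplasm_area_ratio",
    "nucleus_fragment_count",
)


@dataclass
class CellRecord:
    """One cell's feature vector plus identity and (optional) class label."""

    cell_id: int
    well: str
    field_index: int
    plate_id: str = "plate"
    features: dict[str, float] = field(default_factory=dict)
    class_label: str | None = None

    def __post_init__(self):
        if self.class_label is not None and self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"unknown class label {self.class_label!r}; expected one of {CLASS_LABELS}"
            )

    def get(self, name: str) -> float:
        return self.features.get(name, math.nan)


def measure_intensity(
    raster: np.ndarray, mask: np.ndarray, background: float
) -> dict[str, float]:
    """Intensity statistics of a region: mean, population sd, max, integrated,
    and mean/background ratio. An empty region yields NaNs."""
    values = np.asarray(raster, dtype=np.float64)[np.asarray(mask, dtype=bool)]
    if values.size == 0:
        return {s: math.nan for s in INTENSITY_STATS}
    mean = float(values.mean())
    return {
        "mean": mean,
        "sd": float(values.std(ddof=0)),
        "max": float(values.max()),
        "integrated": float(values.sum()),
        "bg_ratio": mean / background,
    }


def measure_morphology(mask: np.ndarray) -> dict[str, float]:
    """Shape descriptors of a (possibly disconnected) region.

    circularity = 4*pi*area / perimeter^2 (perimeter by boundary-step
    counting with diagonal correction); roundness = 4*area /
    (pi*major_axis^2). Rasterization can push circularity slightly above 1;
    values are clipped to 1. fragment_count counts connected components —
    two or more signals nuclear fragmentation.
    """
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        return {
            "area": math.nan,
            "perimeter": math.nan,
            "circularity": math.nan,
            "roundness": math.nan,
            "equivalent_radius": math.nan,
            "fragment_count": 0.0,
        }
    props = regionprops(mask.astype(np.uint8))[0]
    perimeter = float(props.perimeter)
    circularity = 4.0 * math.pi * area / perimeter**2 if perimeter > 0 else 1.0
    major = float(props.axis_major_length)
    roundness = 4.0 * area / (math.pi * major**2) if major > 0 else 1.0
    _, n_frag = ndi.label(mask)
    return {
        "area": float(area),
        "perimeter": perimeter,
        "circularity": min(circularity, 1.0),
        "roundness": min(roundness, 1.0),
        "equivalent_radius": math.sqrt(area / math.pi),
        "fragment_count": float(n_frag),
    }


def ser_responses(raster: np.ndarray, scale_px: float = 2.0) -> dict[str, np.ndarray]:
    """Pixelwise spot/edge/ridge responses at one Gaussian scale.

    edges: gradient magnitude. spots: isotropic second-derivative strength
    sqrt(|det H|) of the Hessian H — large where both principal curvatures
    are large (blobs), small on straight ridges. ridges: curvature
    anisotropy |l_hi| - |l_lo| of the Hessian eigenvalues — large on lines,
    zero on isotropic blobs and flat areas. All responses vanish on constant
    images and are invariant to additive offsets before normalization.
    """
    raster = np.asarray(raster, dtype=np.float64)
    # remove the DC component so constant images give exactly zero response
    # and additive offsets cancel in the filter outputs
    raster = raster - raster.mean()
    g_r = ndi.gaussian_filter(raster, scale_px, order=(1, 0))
    g_c = ndi.gaussian_filter(raster, scale_px, order=(0, 1))
    edges = np.hypot(g_r, g_c)
    h_rr = ndi.gaussian_filter(raster, scale_px, order=(2, 0))
    h_cc = ndi.gaussian_filter(raster, scale_px, order=(0, 2))
    h_rc = ndi.gaussian_filter(raster, scale_px, order=(1, 1))
    # eigenvalues of [[h_rr, h_rc], [h_rc, h_cc]]
    half_trace = 0.5 * (h_rr + h_cc)
    root = np.sqrt(np.maximum(0.25 * (h_rr - h_cc) ** 2 + h_rc**2, 0.0))
    lam1 = np.abs(half_trace + root)
    lam2 = np.abs(half_trace - root)
    lam_hi = np.maximum(lam1, lam2)
    lam_lo = np.minimum(lam1, lam2)
    spots = np.sqrt(lam_hi * lam_lo)
    ridges = lam_hi - lam_lo
    return {"ser_spots": spots, "ser_edges": edges, "ser_ridges": ridges}


def measure_texture_ser(
    raster: np.ndarray, mask: np.ndarray, scale_px: float = 2.0
) -> dict[str, float]:
    """Region-mean spot/edge/ridge responses, normalized by the region mean
    intensity so the features are invariant to illumination scaling.

    Regions smaller than 9 px yield NaNs.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 9:
        return {s: math.nan for s in SER_STATS}
    responses = ser_responses(raster, scale_px)
    return _texture_from_responses(raster, responses, mask)


def _texture_from_responses(
    raster: np.ndarray, responses: dict[str, np.ndarray], mask: np.ndarray
) -> dict[str, float]:
    region_mean = float(np.asarray(raster, dtype=np.float64)[mask].mean())
    out = {}
    for name, resp in responses.items():
        val = float(resp[mask].mean())
        out[name] = val / region_mean if region_mean > 0 else 0.0
    return out


def build_cell_table(
    regions,
    image,
    backgrounds: dict[str, float],
    texture_scale_px: float = 2.0,
) -> list[CellRecord]:
    """One CellRecord per retained cell, ordered by cell id.

    Filter responses are computed once per channel and averaged per region,
    so cost is O(pixels x channels) plus O(cells).
    """
    records: list[CellRecord] = []
    if not regions.cell_ids:
        return records

    rasters = {c: np.asarray(image.channels[c], dtype=np.float64) for c in CHANNELS}
    responses = {c: ser_responses(rasters[c], texture_scale_px) for c in CHANNELS}
    region_masks = {
        "nuclei": regions.nuclei,
        "cytoplasm": regions.cytoplasm,
        "cell": regions.cell,
        "nuclei_eroded": regions.nuclei_eroded,
    }
    slices = ndi.find_objects(regions.cell, max_label=max(regions.cell_ids))

    for cid in regions.cell_ids:
        sl = slices[cid - 1]
        if sl is None:
            continue
        feats: dict[str, float] = {}
        masks_local = {
            name: (mask[sl] == cid) for name, mask in region_masks.items()
        }
        for rname, rmask in masks_local.items():
            for cname in CHANNELS:
                stats = measure_intensity(rasters[cname][sl], rmask, backgrounds[cname])
                for sname, v in stats.items():
                    feats[f"{rname}_{cname}_{sname}"] = v
                if rmask.sum() >= 9:
                    tex = _texture_from_responses(
                        rasters[cname][sl],
                        {k: v[sl] for k, v in responses[cname].items()},
                        rmask,
                    )
                else:
                    tex = {s: math.nan for s in SER_STATS}
                for sname, v in tex.items():
                    feats[f"{rname}_{cname}_{sname}"] = v

        nuc_morph = measure_morphology(masks_local["nuclei"])
        cell_morph = measure_morphology(masks_local["cell"])
        cyto_area = float(masks_local["cytoplasm"].sum())
        feats["nucleus_area_px"] = nuc_morph["area"]
        feats["cell_area_px"] = cell_morph["area"]
        feats["nucleus_perimeter_px"] = nuc_morph["perimeter"]
        feats["cell_perimeter_px"] = cell_morph["perimeter"]
        feats["nucleus_circularity"] = nuc_morph["circularity"]
        feats["cell_circularity"] = cell_morph["circularity"]
        feats["nucleus_roundness"] = nuc_morph["roundness"]
        feats["nucleus_equivalent_radius_px"] = nuc_morph["equivalent_radius"]
        feats["nuclear_cytoplasm_area_ratio"] = (
            nuc_morph["area"] / max(cyto_area, 1.0)
            if not math.isnan(nuc_morph["area"])
            else math.nan
        )
        feats["nucleus_fragment_count"] = nuc_morph["fragment_count"]

        records.append(
            CellRecord(
                cell_id=int(cid),
                well=image.well,
                field_index=image.field_index,
                plate_id=image.plate_id,
                features=feats,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Tabular conversion (CSV schema v1)
# ---------------------------------------------------------------------------

def cell_records_to_frame(cells: Sequence[CellRecord]) -> pd.DataFrame:
    rows = []
    for c in cells:
        row = {
            "plate_id": c.plate_id,
            "well": c.well,
            "field_index": c.field_index,
            "cell_id": c.cell_id,
            "class_label": c.class_label if c.class_label is not None else "",
        }
        for name in FEATURE_COLUMNS:
            row[name] = c.features.get(name, math.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(IDENTITY_COLUMNS) + list(FEATURE_COLUMNS))


def frame_to_cell_records(frame: pd.DataFrame) -> list[CellRecord]:
    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        label = d.get("class_label")
        if label is None or (isinstance(label, float) and math.isnan(label)) or label == "":
            label = None
        elif label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {label!r} in cell table")
        feats = {name: float(d[name]) for name in FEATURE_COLUMNS if name in d}
        records.append(
            CellRecord(
                cell_id=int(d["cell_id"]),
                well=str(d["well"]),
                field_index=int(d["field_index"]),
                plate_id=str(d.get("plate_id", "plate")),
                features=feats,
                class_label=label,
            )
        )
    return records


def records_to_matrix(
    records: Sequence[CellRecord], feature_names: Iterable[str]
) -> np.ndarray:
    names = list(feature_names)
    out = np.empty((len(records), len(names)), dtype=np.float64)
    for i, rec in enumerate(records):
        for j, name in enumerate(names):
            out[i, j] = rec.get(name)
    return out
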