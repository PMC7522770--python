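"""Synthetic multichannel plate renderer with per-cell ground truth.

The generator renders the four cell-death phenotypes as they appear in the
three-dye live-cell assay, so every upstream module can be tested without
microscope data:

* **healthy** — large round nucleus, dim cytoplasmic Hoechst halo, no
  annexin V, Yo-Pro-3 well below the 2-fold gate;
* **initial_apoptotic** — condensed bright nucleus, annexin V membrane
  ring, Yo-Pro-3 still negative, irregular blebbing cell outline;
* **late_apoptotic** — condensed (possibly fragmenting) nucleus, both
  annexin V ring and nuclear Yo-Pro-3 above the gate;
* **necrotic** — nuclear Yo-Pro-3 above the gate without annexin V.

A fifth renderable phenotype, ``fragmented_dye_negative``, emulates the
distinct fragmented, intensely stained but dye-negative nuclei seen with
some ATR inhibitors: gating calls these healthy while an annotation-trained
classifier can learn to call them early apoptotic.

Cell profiles are built from super-Gaussian (flat-top) blobs: nucleus,
larger low-amplitude cytoplasm halo (in the Hoechst channel), an annexin
difference-of-Gaussians ring at the cell boundary, satellite blebs, and
2-5 displaced sub-blobs for fragmentation. Dye amplitudes are quoted as
fold-over-background so the 2-fold gating rules are meaningful by
construction. Channels get a constant background offset plus Gaussian read
noise (and optional Poisson shot noise). Everything is deterministic given
the seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .features import CellRecord
from .io import FieldImage, PlateMap, PlateMapRow

CLASSES = ("healthy", "initial_apoptotic", "late_apoptotic", "necrotic")


@dataclass
class PhenotypeSpec:
    """Rendering parameters of one phenotype.

    Amplitudes are fold-over-background (an amplitude of 3 renders a
    flat-top profile peaking at 3x background above the offset).
    """

    nucleus_radius_mean_px: float = 8.0
    nucleus_radius_sd_px: float = 0.8
    hoechst_amp: float = 3.0
    yopro_amp: float = 0.3
    annexin_pattern: str = "none"  # "none" | "membrane_ring"
    annexin_amp: float = 0.0
    halo_amp: float = 0.5
    shape_irregularity: float = 0.05
    bleb_prob: float = 0.0
    frag_prob: float = 0.0
    frag_count_range: tuple[int, int] = (2, 4)

    def __post_init__(self):
        if self.annexin_pattern not in ("none", "membrane_ring"):
            raise ValueError("annexin_pattern must be 'none' or 'membrane_ring'")


def default_phenotypes() -> dict[str, PhenotypeSpec]:
    """Phenotype defaults encoding the four-population dye/morphology logic."""
    return {
        "healthy": PhenotypeSpec(
            nucleus_radius_mean_px=8.0,
            hoechst_amp=3.0,
            yopro_amp=0.3,
            annexin_pattern="none",
            annexin_amp=0.0,
            halo_amp=0.5,
            shape_irregularity=0.05,
        ),
        "initial_apoptotic": PhenotypeSpec(
            nucleus_radius_mean_px=5.5,
            nucleus_radius_sd_px=0.5,
            hoechst_amp=4.5,  # condensed, intensely stained
            yopro_amp=0.3,
            annexin_pattern="membrane_ring",
            annexin_amp=5.0,
            halo_amp=0.5,
            shape_irregularity=0.35,
            bleb_prob=0.6,
        ),
        "late_apoptotic": PhenotypeSpec(
            nucleus_radius_mean_px=5.5,
            nucleus_radius_sd_px=0.5,
            hoechst_amp=4.5,
            yopro_amp=3.0,
            annexin_pattern="membrane_ring",
            annexin_amp=5.0,
            halo_amp=0.5,
            shape_irregularity=0.35,
            bleb_prob=0.4,
            frag_prob=0.3,
        ),
        "necrotic": PhenotypeSpec(
            nucleus_radius_mean_px=5.5,
            nucleus_radius_sd_px=0.5,
            hoechst_amp=4.5,
            yopro_amp=3.0,
            annexin_pattern="none",
            annexin_amp=0.0,
            halo_amp=0.5,
            shape_irregularity=0.3,
        ),
        # dye-negative fragmented phenotype (gates healthy by construction)
        "fragmented_dye_negative": PhenotypeSpec(
            nucleus_radius_mean_px=7.0,
            hoechst_amp=4.5,
            yopro_amp=0.3,
            annexin_pattern="none",
            annexin_amp=0.0,
            halo_amp=0.5,
            shape_irregularity=0.15,
            frag_prob=1.0,
            frag_count_range=(3, 5),
        ),
    }


@dataclass
class FieldParams:
    """Geometry and noise of one rendered field."""

    shape: tuple[int, int] = (512, 512)
    background: dict[str, float] = field(
        default_factory=lambda: {"hoechst": 100.0, "annexin": 100.0, "yopro": 100.0}
    )
    noise_sd: float = 5.0
    shot_noise: bool = False
    min_separation_px: float = 26.0
    edge_margin_px: float = 0.0
    stuck_fraction: float = 0.0
    halo_radius_factor: float = 1.7
    ring_sigma_px: float = 2.0


@dataclass
class GroundTruthCell:
    """Ground truth for one rendered cell."""

    well: str
    field_index: int
    row: float
    col: float
    cell_class: str
    nucleus_radius_px: float
    touches_border: bool


def _angular_radius_factor(theta: np.ndarray, irregularity: float, rng: np.random.Generator):
    """Low-order Fourier perturbation of the boundary radius."""
    if irregularity <= 0:
        return np.ones_like(theta)
    factor = np.ones_like(theta)
    for k in (2, 3, 4):
        amp = irregularity * rng.normal(0.0, 1.0) / k
        phase = rng.uniform(0, 2 * math.pi)
        factor = factor + amp * np.cos(k * theta + phase)
    return np.clip(factor, 0.6, 1.4)


def _supergauss(d: np.ndarray) -> np.ndarray:
    """Flat-top radial profile: ~1 inside d<1, fast falloff outside."""
    return np.exp(-np.clip(d, 0, 6.0) ** 6)


def _place_centers(
    n: int, shape: tuple[int, int], min_sep: float, margin: float, rng: np.random.Generator
) -> np.ndarray:
    h, w = shape
    usable = (h - 2 * margin) * (w - 2 * margin)
    if n * min_sep**2 * 0.9 > usable:
        raise ValueError(
            f"cannot place {n} cells at separation {min_sep} in a {shape} frame; "
            "reduce n_cells or the separation"
        )
    centers: list[tuple[float, float]] = []
    tries = 0
    max_tries = 400 * max(n, 1)
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError("placement failed; frame too crowded for the separation constraint")
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if all((r - rr) ** 2 + (c - cc) ** 2 >= min_sep**2 for rr, cc in centers):
            centers.append((r, c))
    return np.asarray(centers, dtype=np.float64)


def render_field(
    mixture: dict[str, float],
    n_cells: int,
    params: FieldParams | None = None,
    seed: int | np.random.Generator = 0,
    phenotypes: dict[str, PhenotypeSpec] | None = None,
    well: str = "A01",
    field_index: int = 0,
    plate_id: str = "synthetic",
) -> tuple[FieldImage, list[GroundTruthCell]]:
    """Render one field with the given phenotype mixture and ground truth.

    ``mixture`` maps phenotype names to fractions summing to 1; phenotype
    names outside the four classes (e.g. ``fragmented_dye_negative``) are
    allowed and recorded as such in the truth table.
    """
    params = params or FieldParams()
    phenotypes = phenotypes or default_phenotypes()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = sorted(mixture)
    fracs = np.array([mixture[n] for n in names], dtype=np.float64)
    if n_cells > 0:
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError("mixture fractions must sum to 1")
        if np.any(fracs < 0):
            raise ValueError("mixture fractions must be non-negative")

    h, w = params.shape
    rasters = {
        c: np.full((h, w), params.background[c], dtype=np.float64)
        for c in ("hoechst", "annexin", "yopro")
    }
    truth: list[GroundTruthCell] = []

    if n_cells > 0:
        n_primary = n_cells
        n_stuck = int(round(params.stuck_fraction * n_cells / 2))
        n_primary = n_cells - n_stuck
        centers = _place_centers(
            n_primary, params.shape, params.min_separation_px, params.edge_margin_px, rng
        )
        all_centers = [tuple(c) for c in centers]
        # stuck partners: second nucleus ~2 radii from a placed one — the
        # flat-top footprints still touch at threshold but leave a saddle
        # the watershed can split
        for i in range(n_stuck):
            base = all_centers[i % len(all_centers)]
            ang = rng.uniform(0, 2 * math.pi)
            spec_r = 8.0
            all_centers.append(
                (base[0] + 2.0 * spec_r * math.sin(ang), base[1] + 2.0 * spec_r * math.cos(ang))
            )
        classes = rng.choice(len(names), size=len(all_centers), p=fracs)
        for (cr, cc), ki in zip(all_centers, classes):
            cls = names[int(ki)]
            spec = phenotypes[cls]
            tb = _render_cell(rasters, (cr, cc), spec, params, rng)
            truth.append(
                GroundTruthCell(
                    well=well,
                    field_index=field_index,
                    row=float(cr),
                    col=float(cc),
                    cell_class=cls,
                    nucleus_radius_px=tb[0],
                    touches_border=tb[1],
                )
            )

    for c, arr in rasters.items():
        if params.shot_noise:
            arr = rng.poisson(np.maximum(arr, 0)).astype(np.float64)
        if params.noise_sd > 0:
            arr = arr + rng.normal(0.0, params.noise_sd, size=arr.shape)
        rasters[c] = np.maximum(arr, 0.0)

    image = FieldImage(
        plate_id=plate_id, well=well, field_index=field_index, channels=rasters
    )
    return image, truth


def _render_cell(
    rasters: dict[str, np.ndarray],
    center: tuple[float, float],
    spec: PhenotypeSpec,
    params: FieldParams,
    rng: np.random.Generator,
) -> tuple[float, bool]:
    """Render one cell into the rasters; returns (nucleus radius, touches_border)."""
    h, w = params.shape
    cr, cc = center
    r0 = max(2.5, rng.normal(spec.nucleus_radius_mean_px, spec.nucleus_radius_sd_px))
    rc_cell = params.halo_radius_factor * r0

    half = int(math.ceil(rc_cell + 4 * params.ring_sigma_px + 6))
    r_lo, r_hi = int(math.floor(cr)) - half, int(math.floor(cr)) + half + 1
    c_lo, c_hi = int(math.floor(cc)) - half, int(math.floor(cc)) + half + 1
    rs = np.arange(max(r_lo, 0), min(r_hi, h))
    cs = np.arange(max(c_lo, 0), min(c_hi, w))
    if rs.size == 0 or cs.size == 0:
        return r0, True
    grid_r, grid_c = np.meshgrid(rs - cr, cs - cc, indexing="ij")
    dist = np.hypot(grid_r, grid_c)
    theta = np.arctan2(grid_r, grid_c)
    window = (slice(rs[0], rs[-1] + 1), slice(cs[0], cs[-1] + 1))

    bg = params.background
    nuc_shape = _angular_radius_factor(theta, spec.shape_irregularity, rng)

    fragmented = rng.random() < spec.frag_prob
    if fragmented:
        k = int(rng.integers(spec.frag_count_range[0], spec.frag_count_range[1] + 1))
        sub_r = max(2.0, r0 / math.sqrt(k) * 0.75)
        offset = r0 * 0.85
        nuc_profile = np.zeros_like(dist)
        base_ang = rng.uniform(0, 2 * math.pi)
        for j in range(k):
            ang = base_ang + 2 * math.pi * j / k + rng.normal(0, 0.15)
            fr = grid_r - offset * math.sin(ang)
            fc = grid_c - offset * math.cos(ang)
            nuc_profile = np.maximum(nuc_profile, _supergauss(np.hypot(fr, fc) / sub_r))
        nuc_extent = offset + sub_r
    else:
        nuc_profile = _supergauss(dist / (r0 * nuc_shape))
        nuc_extent = r0 * 1.4

    cell_shape = _angular_radius_factor(theta, spec.shape_irregularity, rng)
    halo_profile = _supergauss(dist / (rc_cell * cell_shape))
    if spec.bleb_prob > 0 and rng.random() < spec.bleb_prob:
        for _ in range(int(rng.integers(1, 4))):
            ang = rng.uniform(0, 2 * math.pi)
            br = cr + rc_cell * math.sin(ang)
            bc = cc + rc_cell * math.cos(ang)
            bd = np.hypot(grid_r - (br - cr), grid_c - (bc - cc))
            halo_profile = np.maximum(halo_profile, _supergauss(bd / (0.35 * r0)))

    rasters["hoechst"][window] += bg["hoechst"] * (
        spec.hoechst_amp * nuc_profile + spec.halo_amp * halo_profile * (1 - nuc_profile)
    )
    rasters["yopro"][window] += bg["yopro"] * spec.yopro_amp * nuc_profile
    if spec.annexin_pattern == "membrane_ring":
        ring = np.exp(
            -((dist - rc_cell * cell_shape) ** 2) / (2 * params.ring_sigma_px**2)
        )
        rasters["annexin"][window] += bg["annexin"] * spec.annexin_amp * ring

    # does the rendered nuclear footprint (profile >= 0.5) touch the frame border?
    touches = bool(
        cr - nuc_extent <= 0 or cr + nuc_extent >= h - 1 or cc - nuc_extent <= 0 or cc + nuc_extent >= w - 1
    )
    return r0, touches


# ---------------------------------------------------------------------------
# Plate simulation
# ---------------------------------------------------------------------------

@dataclass
class KillModel:
    """Hill dose model for one compound's effect on the healthy fraction."""

    true_ic50_um: float = 1.0
    hill: float = 1.0
    top: float = 0.95
    bottom: float = 0.05
    apoptotic_fraction: float = 0.6  # of non-healthy cells; rest necrotic
    early_late_ratio: float = 1.0  # early:late among apoptotic

    def healthy_fraction(self, conc_um: float) -> float:
        if conc_um <= 0:
            return self.top
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (conc_um / self.true_ic50_um) ** self.hill
        )

    def mixture(self, conc_um: float) -> dict[str, float]:
        healthy = self.healthy_fraction(conc_um)
        dead = 1.0 - healthy
        apo = dead * self.apoptotic_fraction
        early = apo * self.early_late_ratio / (1.0 + self.early_late_ratio)
        return {
            "healthy": healthy,
            "initial_apoptotic": early,
            "late_apoptotic": apo - early,
            "necrotic": dead - apo,
        }


def dilution_series(top_um: float = 10.0, n: int = 7, factor: float = 2.0) -> list[float]:
    """An n-point 1:factor serial dilution from top_um, descending."""
    return [top_um / factor**i for i in range(n)]


@dataclass
class SimulatedPlateSpec:
    """Layout and effect model of a simulated plate."""

    compounds: dict[str, KillModel] = field(
        default_factory=lambda: {"cmpdA": KillModel()}
    )
    doses_um: list[float] = field(default_factory=dilution_series)
    replicates: int = 3
    n_vehicle_wells: int = 3
    cells_per_well: int = 500
    fields_per_well: int = 4
    field_params: FieldParams = field(default_factory=FieldParams)
    phenotypes: dict[str, PhenotypeSpec] = field(default_factory=default_phenotypes)
    seed: int = 0

    def __post_init__(self):
        if len(set(self.doses_um)) != len(self.doses_um) or any(d <= 0 for d in self.doses_um):
            raise ValueError("doses must be positive and distinct")


def _well_names(n: int) -> list[str]:
    names = []
    for i in range(n):
        names.append(f"{chr(ord('A') + i // 24)}{i % 24 + 1:02d}")
    return names


def simulate_plate(
    spec: SimulatedPlateSpec,
) -> tuple[list[FieldImage], pd.DataFrame, PlateMap]:
    """Render a full plate: vehicle wells plus compound x dose x replicate wells.

    Per well the expected healthy fraction follows the compound's Hill
    model; non-healthy cells split between early/late apoptotic and
    necrotic per the kill model's terminal mixture. Returns the rendered
    fields, a ground-truth table (one row per rendered cell) and the plate
    map.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[PlateMapRow] = []
    jobs: list[tuple[str, dict[str, float]]] = []

    n_wells = spec.n_vehicle_wells + len(spec.compounds) * len(spec.doses_um) * spec.replicates
    names = _well_names(n_wells)
    idx = 0
    for v in range(spec.n_vehicle_wells):
        well = names[idx]
        idx += 1
        rows.append(PlateMapRow(well=well, compound_id="DMSO", concentration_um=0.0,
                                role="vehicle_control", replicate=v + 1))
        top_mix = next(iter(spec.compounds.values())).mixture(0.0)
        jobs.append((well, top_mix))
    for compound, model in spec.compounds.items():
        for dose in spec.doses_um:
            for rep in range(spec.replicates):
                well = names[idx]
                idx += 1
                rows.append(PlateMapRow(well=well, compound_id=compound,
                                        concentration_um=dose, role="sample", replicate=rep + 1))
                jobs.append((well, model.mixture(dose)))

    plate_map = PlateMap(rows)
    fields: list[FieldImage] = []
    truth_rows: list[GroundTruthCell] = []
    per_field = spec.cells_per_well // spec.fields_per_well
    for well, mixture in jobs:
        for fi in range(spec.fields_per_well):
            n = per_field + (1 if fi < spec.cells_per_well % spec.fields_per_well else 0)
            img, truth = render_field(
                mixture, n, spec.field_params, rng, spec.phenotypes,
                well=well, field_index=fi,
            )
            fields.append(img)
            truth_rows.extend(truth)

    truth_df = pd.DataFrame([dataclasses.asdict(t) for t in truth_rows])
    return fields, truth_df, plate_map


def simulate_well_counts(
    model: KillModel,
    conc_um: float,
    n_cells: int,
    rng: np.random.Generator,
    misclass_rate: float = 0.02,
) -> dict[str, int]:
    """Class counts for one well at the counting level (no rendering).

    Cells are drawn multinomially from the Hill-model mixture; a small
    symmetric misclassification channel stands in for imaging/segmentation
    noise. Used for fast Monte-Carlo studies of the dose-response stage.
    """
    mixture = model.mixture(conc_um)
    probs = np.array([mixture[c] for c in CLASSES])
    probs = probs / probs.sum()
    if misclass_rate > 0:
        k = len(CLASSES)
        confusion = np.full((k, k), misclass_rate / (k - 1))
        np.fill_diagonal(confusion, 1.0 - misclass_rate)
        probs = probs @ confusion
    draw = rng.multinomial(n_cells, probs)
    return {c: int(n) for c, n in zip(CLASSES, draw)}


# ---------------------------------------------------------------------------
# Annotation sets
# ---------------------------------------------------------------------------

def label_records_with_truth(
    records: Sequence[CellRecord],
    regions,
    truth: Sequence[GroundTruthCell],
    max_dist_px: float = 10.0,
    label_map: dict[str, str] | None = None,
) -> list[CellRecord]:
    """Attach ground-truth classes to detected cells by nearest centroid.

    ``label_map`` translates generator phenotype names to class labels
    (e.g. fragmented_dye_negative -> initial_apoptotic for annotation
    sets). Unmatched detections are dropped.
    """
    if not records:
        return []
    ids = [r.cell_id for r in records]
    centroids = ndi.center_of_mass(regions.nuclei > 0, regions.nuclei, ids)
    tpos = np.array([[t.row, t.col] for t in truth])
    labeled = []
    for rec, cen in zip(records, centroids):
        d = np.hypot(tpos[:, 0] - cen[0], tpos[:, 1] - cen[1])
        j = int(np.argmin(d))
        if d[j] > max_dist_px:
            continue
        cls = truth[j].cell_class
        if label_map and cls in label_map:
            cls = label_map[cls]
        if cls in ("healthy", "initial_apoptotic", "late_apoptotic", "necrotic"):
            rec.class_label = cls
            labeled.append(rec)
    return labeled


def make_annotation_set(
    n_per_class: int = 60,
    seed: int = 0,
    include_fragmented: bool = False,
    field_params: FieldParams | None = None,
    phenotypes: dict[str, PhenotypeSpec] | None = None,
    dominant_fraction: float = 0.7,
    cells_per_field: int = 100,
) -> list[CellRecord]:
    """Labeled CellRecords from inducer-like reference fields, via the real
    pipeline.

    Emulates annotating wells treated with reference cell-death inducers:
    each rendered field is *predominantly* one phenotype
    (``dominant_fraction``) with the remainder spread over the other
    classes — inducer compounds drive a predominant, not exclusive, death
    mode, and training on such wells exposes the classifier to realistic
    neighbor contamination. Features come from the real segmentation and
    measurement stages; ground-truth labels are attached by centroid
    matching. With ``include_fragmented``, fragmented dye-negative cells
    are added and annotated as initial_apoptotic (the by-eye call for that
    phenotype).
    """
    from .segmentation import SegmentationParams, segment_field
    from .features import build_cell_table

    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    params = field_params or FieldParams(edge_margin_px=16.0)
    phenos = phenotypes or default_phenotypes()
    seg = SegmentationParams()
    rng = np.random.default_rng(seed)

    targets = {c: c for c in CLASSES}
    if include_fragmented:
        targets["fragmented_dye_negative"] = "initial_apoptotic"
    label_map = dict(targets)

    counts = {c: 0 for c in CLASSES}
    frag_count = 0
    out: list[CellRecord] = []

    def done() -> bool:
        ok = all(counts[c] >= n_per_class for c in CLASSES)
        if include_fragmented:
            ok = ok and frag_count >= n_per_class
        return ok

    attempts = 0
    pheno_cycle = list(targets)
    while not done() and attempts < 40:
        pheno_name = pheno_cycle[attempts % len(pheno_cycle)]
        attempts += 1
        others = [c for c in CLASSES if c != pheno_name]
        mixture = {pheno_name: dominant_fraction}
        for c in others:
            mixture[c] = (1.0 - dominant_fraction) / len(others)
        img, truth = render_field(
            mixture, cells_per_field, params, rng, phenos,
            well=f"T{attempts:02d}", field_index=0, plate_id="annotation",
        )
        regions, backgrounds = segment_field(img, seg)
        records = build_cell_table(regions, img, backgrounds)
        matched = label_records_with_truth(records, regions, truth, label_map=label_map)
        # recover which matched cells came from the fragmented phenotype
        for rec in matched:
            counts[rec.class_label] += 1
        if pheno_name == "fragmented_dye_negative":
            frag_count += sum(1 for t in truth if t.cell_class == "fragmented_dye_negative")
        out.extend(matched)
    return out
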