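"""Segmentation of a multichannel field into per-cell regions.

The workflow mirrors common high-content-screening practice: nuclei are
detected on the Hoechst channel by intensity thresholding and an area
filter, touching ("stuck") nuclei are split by a watershed on the distance
transform, and the cell body is grown outward from each nucleus over the dim
cytoplasmic Hoechst halo (long Hoechst incubation stains the cytoplasm
weakly, so no dedicated cytoplasm dye is needed). Four regions result for
every cell: ``nuclei``, ``cell``, ``cytoplasm`` (cell minus nucleus) and
``nuclei_eroded`` (the nucleus eroded by 5% of its equivalent radius, for
high-confidence nuclear intensity readout). Cells whose nucleus touches the
image border are removed so only whole cells are analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology, segmentation as skseg
from skimage.filters import gaussian, threshold_otsu


class SegmentationError(RuntimeError):
    pass


@dataclass
class SegmentationParams:
    """Tunable parameters of the segmentation stage.

    ``cytoplasm_threshold_factor`` is the fraction of the nuclear intensity
    threshold used to delimit the dim peri-nuclear halo; ``erosion_fraction``
    is the per-nucleus erosion radius as a fraction of its equivalent radius.
    """

    nuclear_threshold_method: str = "otsu"
    fixed_threshold: float = 0.0
    min_nucleus_area_px: int = 20
    smoothing_sigma_px: float = 1.0
    splitting_enabled: bool = True
    splitting_sensitivity: float = 0.5
    fragment_merge_radius_px: int = 4
    fragment_max_component_px: int = 100
    cytoplasm_threshold_factor: float = 0.5
    erosion_fraction: float = 0.05

    def __post_init__(self):
        if self.nuclear_threshold_method not in ("otsu", "fixed"):
            raise ValueError("nuclear_threshold_method must be 'otsu' or 'fixed'")
        if self.nuclear_threshold_method == "fixed" and self.fixed_threshold <= 0:
            raise ValueError("fixed_threshold must be positive when method='fixed'")
        if self.min_nucleus_area_px < 1:
            raise ValueError("min_nucleus_area_px must be >= 1")
        if not 0 < self.splitting_sensitivity <= 1:
            raise ValueError("splitting_sensitivity must be in (0, 1]")
        if self.cytoplasm_threshold_factor <= 0:
            raise ValueError("cytoplasm_threshold_factor must be positive")
        if not 0 <= self.erosion_fraction < 0.5:
            raise ValueError("erosion_fraction must lie in [0, 0.5)")


@dataclass
class RegionSet:
    """Label masks for the four per-cell regions, consistently indexed.

    For every retained id: ``nuclei(id) <= cell(id)``,
    ``nuclei_eroded(id) <= nuclei(id)`` and
    ``cytoplasm(id) = cell(id) \\ nuclei(id)``.
    """

    nuclei: np.ndarray
    cell: np.ndarray
    cytoplasm: np.ndarray
    nuclei_eroded: np.ndarray
    cell_ids: list[int] = field(default_factory=list)
    image_shape: tuple[int, int] = (0, 0)

    def validate(self) -> None:
        """Assert the full region-consistency invariant suite; raises on violation."""
        ids = set(self.cell_ids)
        for name in ("nuclei", "cell", "cytoplasm", "nuclei_eroded"):
            mask = getattr(self, name)
            if mask.shape != self.image_shape:
                raise AssertionError(f"{name} mask shape {mask.shape} != {self.image_shape}")
            present = set(np.unique(mask)) - {0}
            if not present <= ids:
                raise AssertionError(f"{name} contains ids outside cell_ids: {sorted(present - ids)}")
        if np.any((self.nuclei > 0) & (self.cell != self.nuclei)):
            raise AssertionError("nucleus pixels must carry the same id in the cell mask")
        if np.any((self.nuclei_eroded > 0) & (self.nuclei != self.nuclei_eroded)):
            raise AssertionError("eroded-nucleus pixels must lie inside the same nucleus")
        expected_cyto = np.where(self.nuclei > 0, 0, self.cell)
        if not np.array_equal(self.cytoplasm, expected_cyto):
            raise AssertionError("cytoplasm must equal cell minus nuclei per id")
        nucleus_ids = set(np.unique(self.nuclei)) - {0}
        cyto_ids = set(np.unique(self.cytoplasm)) - {0}
        if not cyto_ids <= nucleus_ids:
            raise AssertionError("cytoplasm label without a same-id nucleus")
        border = np.zeros(self.image_shape, dtype=bool)
        border[0, :] = border[-1, :] = True
        border[:, 0] = border[:, -1] = True
        if np.any(self.nuclei[border] > 0):
            raise AssertionError("a retained nucleus touches the image border")


def nuclear_threshold(hoechst: np.ndarray, params: SegmentationParams) -> float:
    """Intensity threshold separating nuclei from background and halo."""
    if params.nuclear_threshold_method == "fixed":
        return float(params.fixed_threshold)
    smoothed = gaussian(hoechst, sigma=params.smoothing_sigma_px, preserve_range=True)
    if smoothed.max() == smoothed.min():
        return float(smoothed.max()) + 1.0  # blank image: nothing passes
    return float(threshold_otsu(smoothed))


def segment_nuclei(hoechst: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Detect nuclei on the Hoechst raster by intensity and area.

    Connected components above the threshold with area >= ``min_nucleus_area_px``
    are labeled 1..K. Small gaps (up to ``fragment_merge_radius_px``) are
    closed *for labeling connectivity only*, so a fragmented nucleus remains
    one object whose region keeps its disconnected pixels; this avoids
    oversegmenting fragmenting apoptotic nuclei. Deterministic; an all-zero
    image yields an empty mask.
    """
    hoechst = np.asarray(hoechst, dtype=np.float64)
    if not np.all(np.isfinite(hoechst)) or hoechst.min(initial=0) < 0:
        raise ValueError("hoechst raster must be finite and non-negative")
    thr = nuclear_threshold(hoechst, params)
    smoothed = gaussian(hoechst, sigma=params.smoothing_sigma_px, preserve_range=True)
    binary = smoothed > thr
    if not binary.any():
        return np.zeros(hoechst.shape, dtype=np.int32)
    if params.nuclear_threshold_method == "otsu" and not binary.all():
        # Otsu on a unimodal (cell-free) field lands inside the noise; only
        # accept the split when foreground clearly separates from background
        fg, bg = smoothed[binary], smoothed[~binary]
        if fg.mean() - bg.mean() < 4.0 * max(bg.std(), 1e-12):
            return np.zeros(hoechst.shape, dtype=np.int32)
    if params.fragment_merge_radius_px > 0:
        closed = ndi.binary_closing(
            binary, structure=morphology.disk(params.fragment_merge_radius_px)
        )
        closed |= binary
    else:
        closed = binary
    closed_labels, _ = ndi.label(closed)
    # region pixels = original (unclosed) mask, grouped by closed component
    labels = np.where(binary, closed_labels, 0)
    labels = _filter_small(labels, params.min_nucleus_area_px)
    return _relabel_consecutive(labels)


def _filter_small(labels: np.ndarray, min_area: int) -> np.ndarray:
    if labels.max() == 0:
        return labels
    counts = np.bincount(labels.ravel())
    kill = np.flatnonzero(counts < min_area)
    out = labels.copy()
    out[np.isin(labels, kill[kill > 0])] = 0
    return out


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1, dtype=np.int32)
    return lut[labels]


def split_touching_nuclei(
    nuclei: np.ndarray,
    hoechst: np.ndarray,
    sensitivity: float,
    enabled: bool = True,
    fragment_max_component_px: int = 100,
) -> np.ndarray:
    """Split stuck nuclei by watershed on the smoothed distance transform.

    The h-maxima suppression depth is ``(1 - sensitivity) * max_distance``
    per component, so a higher sensitivity suppresses less and never yields
    fewer labels on the same input. Each input component is either kept or
    partitioned; the union of output pixels equals the input pixels.

    A label whose pixels are disconnected is ambiguous: small pieces (each
    below ``fragment_max_component_px``) are the sub-lobes of a fragmenting
    nucleus and stay one object; large pieces are whole nuclei bridged by
    gap closing and are separated along their connected components.
    """
    if not enabled or nuclei.max() == 0:
        return nuclei.astype(np.int32)
    out = np.zeros_like(nuclei, dtype=np.int32)
    next_id = 1
    for comp_id, sl in enumerate(ndi.find_objects(nuclei), start=1):
        if sl is None:
            continue
        pad = (slice(max(sl[0].start - 2, 0), sl[0].stop + 2),
               slice(max(sl[1].start - 2, 0), sl[1].stop + 2))
        comp = nuclei[pad] == comp_id
        pieces, n_pieces = ndi.label(comp)
        if n_pieces > 1:
            sizes = np.bincount(pieces.ravel())[1:]
            if sizes.max() <= fragment_max_component_px:
                # fragmenting nucleus: keep whole
                out[pad][comp] = next_id
                next_id += 1
            else:
                # distinct nuclei bridged by gap closing: separate them
                for piece_id in range(1, n_pieces + 1):
                    out[pad][pieces == piece_id] = next_id
                    next_id += 1
            continue
        dist = ndi.distance_transform_edt(comp)
        dist = ndi.gaussian_filter(dist, sigma=1.0)
        dmax = dist.max()
        depth = max((1.0 - sensitivity) * dmax, 1e-9)
        peaks = morphology.h_maxima(dist, depth)
        markers, n_marks = ndi.label(peaks)
        if n_marks <= 1:
            out[pad][comp] = next_id
            next_id += 1
            continue
        ws = skseg.watershed(-dist, markers=markers, mask=comp)
        for w in np.unique(ws):
            if w == 0:
                continue
            out[pad][ws == w] = next_id
            next_id += 1
    return out


def segment_cytoplasm(
    hoechst: np.ndarray, nuclei: np.ndarray, params: SegmentationParams
) -> np.ndarray:
    """Grow cell bodies from nuclear seeds over the dim cytoplasmic halo.

    Pixels above ``cytoplasm_threshold_factor x nuclear_threshold`` form the
    admissible halo; each is assigned to the geodesically nearest nuclear
    seed (watershed on the inverted smoothed intensity restricted to the
    halo). Every cell strictly contains its nucleus; halo pixels not
    geodesically connected to any nucleus stay background.
    """
    nuclei = nuclei.astype(np.int32)
    if nuclei.max() == 0:
        return np.zeros_like(nuclei)
    thr = nuclear_threshold(hoechst, params) * params.cytoplasm_threshold_factor
    smoothed = gaussian(hoechst, sigma=params.smoothing_sigma_px, preserve_range=True)
    halo = (smoothed > thr) | (nuclei > 0)
    # geodesic partition between competing seeds: watershed of the distance
    # transform to the nuclei, restricted to the halo mask
    dist_to_nuc = ndi.distance_transform_edt(nuclei == 0)
    cell = skseg.watershed(dist_to_nuc, markers=nuclei, mask=halo)
    cell = np.where(nuclei > 0, nuclei, cell)  # nuclei always kept
    return cell.astype(np.int32)


def derive_regions(
    nuclei: np.ndarray, cell: np.ndarray, erosion_fraction: float
) -> RegionSet:
    """Build the four-region set from nucleus and cell masks.

    ``nuclei_eroded`` applies, per nucleus, a disc erosion of radius
    ``round(erosion_fraction * equivalent_radius)`` (minimum 1 px whenever
    the fraction is positive). A 1-px nucleus therefore erodes to the empty
    set; the cell is retained and downstream features on the eroded region
    are marked missing.
    """
    nuclei = nuclei.astype(np.int32)
    cell = cell.astype(np.int32)
    nuc_ids = set(np.unique(nuclei)) - {0}
    cell_ids_present = set(np.unique(cell)) - {0}
    orphans = nuc_ids - cell_ids_present
    if orphans:
        raise SegmentationError(f"nucleus ids missing from cell mask: {sorted(orphans)}")

    cytoplasm = np.where(nuclei > 0, 0, cell).astype(np.int32)
    eroded = np.zeros_like(nuclei)
    if erosion_fraction > 0:
        slices = ndi.find_objects(nuclei)
        for idx, sl in enumerate(slices, start=1):
            if sl is None:
                continue
            comp = nuclei[sl] == idx
            area = int(comp.sum())
            eq_radius = np.sqrt(area / np.pi)
            radius = max(int(round(erosion_fraction * eq_radius)), 1)
            er = ndi.binary_erosion(comp, structure=morphology.disk(radius))
            eroded[sl][er] = idx
    else:
        eroded = nuclei.copy()

    ids = sorted(nuc_ids)
    return RegionSet(
        nuclei=nuclei,
        cell=cell,
        cytoplasm=cytoplasm,
        nuclei_eroded=eroded,
        cell_ids=[int(i) for i in ids],
        image_shape=tuple(nuclei.shape),
    )


def remove_border_cells(regions: RegionSet) -> RegionSet:
    """Delete every cell whose *nucleus* touches the image border.

    A cell whose cytoplasm alone reaches the border is retained. Remaining
    ids are unchanged.
    """
    border = np.zeros(regions.image_shape, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    touching = set(np.unique(regions.nuclei[border])) - {0}
    if not touching:
        return regions
    keep = np.array(sorted(set(regions.cell_ids) - touching), dtype=np.int64)

    def _strip(mask: np.ndarray) -> np.ndarray:
        out = np.where(np.isin(mask, list(touching)), 0, mask)
        return out.astype(np.int32)

    return RegionSet(
        nuclei=_strip(regions.nuclei),
        cell=_strip(regions.cell),
        cytoplasm=_strip(regions.cytoplasm),
        nuclei_eroded=_strip(regions.nuclei_eroded),
        cell_ids=[int(i) for i in keep],
        image_shape=regions.image_shape,
    )


def estimate_background(raster: np.ndarray, cell: np.ndarray) -> float:
    """Median intensity of pixels outside every cell region (per field, per channel).

    Requires at least 1% of the field to be background; denser fields must
    either be seeded more sparsely or supply a fixed background in config.
    """
    outside = cell == 0
    if outside.sum() < 0.01 * cell.size:
        raise SegmentationError(
            "fewer than 1% background pixels; lower the seeding density or "
            "configure a fixed background value"
        )
    return float(np.median(np.asarray(raster, dtype=np.float64)[outside]))


def segment_field(image, params: SegmentationParams) -> tuple[RegionSet, dict[str, float]]:
    """Full segmentation of a FieldImage: nuclei -> split -> cell -> regions -> border removal.

    Returns the border-cleaned RegionSet and the per-channel background
    estimates (computed after cell masking).
    """
    image.require_channels()
    hoechst = image.channels["hoechst"]
    nuclei = segment_nuclei(hoechst, params)
    nuclei = split_touching_nuclei(
        nuclei, hoechst, params.splitting_sensitivity,
        enabled=params.splitting_enabled,
        fragment_max_component_px=params.fragment_max_component_px,
    )
    cell = segment_cytoplasm(hoechst, nuclei, params)
    regions = derive_regions(nuclei, cell, params.erosion_fraction)
    regions = remove_border_cells(regions)
    # background from pixels outside *all* cells, including border cells
    # about to be discarded, so bright removed cells cannot inflate it
    backgrounds = {
        name: estimate_background(raster, cell)
        for name, raster in image.channels.items()
        if name != "brightfield"
    }
    return regions, backgrounds
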