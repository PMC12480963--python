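"""Fluorescence-marker quantification over fibres, cells and tissue regions.

Covers the immunofluorescence readouts of dystrophic muscle pathology:
IgM⁺ fibre fraction (sarcolemmal permeability / necrosis), eMyHC⁺ fibre
density per mm² (active regeneration), PDGFRA⁺ cell fraction
(fibro-adipogenic progenitors), macrophage-driven damage/repair/healthy
region classification, and p-SMAD2 positive area locally normalised to each
region class (TGF-β signalling activity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from mdxquant.centronucleation import NucleusRecord
from mdxquant.io_core import ChannelImage, FiberLabelMap, RegionClassMap

__all__ = [
    "MarkerScore",
    "RegionParams",
    "positive_fiber_ids",
    "positive_fiber_fraction",
    "positive_fiber_density",
    "positive_cell_fraction",
    "classify_regions",
    "region_normalized_score",
]


@dataclass
class MarkerScore:
    marker_name: str
    value: float  # fraction in [0, 1] or density per mm²
    unit: str  # "fraction" or "per_mm2"
    positive_ids: frozenset[int]
    denominator: float
    threshold_used: float


def _channel_threshold(
    values: np.ndarray, method: str, fixed: float | None
) -> float:
    if method == "fixed":
        if fixed is None:
            raise ValueError("fixed threshold requires a value")
        return float(fixed)
    if method != "otsu":
        raise ValueError(f"unknown threshold_method {method!r}")
    if values.size == 0 or np.ptp(values) == 0:
        # constant channel: nothing can exceed the threshold
        return float(values.max(initial=0.0))
    return float(threshold_otsu(values))


def _check_calibration(marker: ChannelImage, fibers: FiberLabelMap) -> None:
    if not np.isclose(marker.pixel_size_um, fibers.pixel_size_um):
        raise ValueError("marker channel and fibre map calibrations differ")


def positive_fiber_ids(
    marker: ChannelImage,
    fibers: FiberLabelMap,
    retained_ids: set[int] | None = None,
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
    min_positive_area_fraction: float = 0.3,
) -> tuple[frozenset[int], float]:
    """Fibres whose interior positive-pixel area exceeds the area fraction.

    The intensity threshold defaults to Otsu within the fibre-covered
    pixels. ``min_positive_area_fraction`` (default 0.3) demands whole-fibre
    sarcoplasmic staining rather than edge bleed-through.
    """
    _check_calibration(marker, fibers)
    ids = {int(i) for i in (retained_ids if retained_ids is not None else fibers.ids)}
    if not ids:
        raise ValueError("empty fibre set")
    img = marker.astype_float()
    inside = fibers.labels > 0
    thr = _channel_threshold(img[inside], threshold_method, fixed_threshold)
    pos = img > thr
    n_pos = np.bincount(fibers.labels.ravel(), weights=pos.ravel())
    n_all = np.bincount(fibers.labels.ravel())
    positives = frozenset(
        fid
        for fid in ids
        if n_all[fid] > 0 and n_pos[fid] / n_all[fid] > min_positive_area_fraction
    )
    return positives, thr


def positive_fiber_fraction(
    marker: ChannelImage,
    fibers: FiberLabelMap,
    retained_ids: set[int] | None = None,
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
    min_positive_area_fraction: float = 0.3,
) -> MarkerScore:
    """Fraction of retained fibres positive for a marker (e.g. IgM⁺ fibres)."""
    ids = {int(i) for i in (retained_ids if retained_ids is not None else fibers.ids)}
    positives, thr = positive_fiber_ids(
        marker, fibers, ids, threshold_method, fixed_threshold,
        min_positive_area_fraction,
    )
    return MarkerScore(
        marker_name=marker.channel_name or "marker",
        value=len(positives) / len(ids),
        unit="fraction",
        positive_ids=positives,
        denominator=float(len(ids)),
        threshold_used=thr,
    )


def positive_fiber_density(
    marker: ChannelImage,
    fibers: FiberLabelMap,
    tissue: np.ndarray,
    retained_ids: set[int] | None = None,
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
    min_positive_area_fraction: float = 0.3,
) -> MarkerScore:
    """Positive fibres per mm² of tissue (e.g. eMyHC⁺ regenerating fibres)."""
    positives, thr = positive_fiber_ids(
        marker, fibers, retained_ids, threshold_method, fixed_threshold,
        min_positive_area_fraction,
    )
    tissue_mm2 = int(np.asarray(tissue, bool).sum()) * marker.pixel_size_um**2 * 1e-6
    if tissue_mm2 <= 0:
        raise ValueError("zero tissue area; density undefined")
    return MarkerScore(
        marker_name=marker.channel_name or "marker",
        value=len(positives) / tissue_mm2,
        unit="per_mm2",
        positive_ids=positives,
        denominator=tissue_mm2,
        threshold_used=thr,
    )


def positive_cell_fraction(
    marker: ChannelImage,
    nuclei: list[NucleusRecord],
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
    ring_inner_um: float = 2.0,
    ring_outer_um: float = 5.0,
) -> MarkerScore:
    """Fraction of cells positive for a membrane/cytoplasmic marker.

    A cell is scored on the *median* marker intensity in an annulus around
    its nucleus centroid (the marker, e.g. PDGFRA, stains the cell body, not
    the nucleus); the median is robust to partial bleed-through from an
    adjacent positive cell, which covers only a minority of the ring. With
    Otsu thresholding the cutoff is computed over the per-cell ring medians.
    """
    if not nuclei:
        raise ValueError("zero cells")
    img = marker.astype_float()
    ps = marker.pixel_size_um
    r_in = ring_inner_um / ps
    r_out = ring_outer_um / ps
    h, w = img.shape
    size = int(np.ceil(r_out))
    yy, xx = np.mgrid[-size : size + 1, -size : size + 1]
    ring = (yy**2 + xx**2 >= r_in**2) & (yy**2 + xx**2 <= r_out**2)

    means = np.full(len(nuclei), np.nan)
    for i, rec in enumerate(nuclei):
        r = int(round(rec.centroid_px[0]))
        c = int(round(rec.centroid_px[1]))
        r0, r1 = max(0, r - size), min(h, r + size + 1)
        c0, c1 = max(0, c - size), min(w, c + size + 1)
        sub = img[r0:r1, c0:c1]
        rmask = ring[r0 - (r - size) : r1 - (r - size), c0 - (c - size) : c1 - (c - size)]
        if rmask.any():
            means[i] = np.median(sub[rmask])
    valid = ~np.isnan(means)
    thr = _channel_threshold(means[valid], threshold_method, fixed_threshold)
    pos = valid & (means > thr)
    positives = frozenset(nuclei[i].nucleus_id for i in np.nonzero(pos)[0])
    return MarkerScore(
        marker_name=marker.channel_name or "marker",
        value=float(pos.sum()) / len(nuclei),
        unit="fraction",
        positive_ids=positives,
        denominator=float(len(nuclei)),
        threshold_used=thr,
    )


@dataclass
class RegionParams:
    """Geometry of the damage / repair / healthy partition.

    damage: tissue where the local positive-area fraction of the macrophage
    channel (F4/80), averaged over a disk of ``damage_radius_um``, exceeds
    ``damage_threshold``. repair: remaining tissue within
    ``repair_radius_um`` of an eMyHC⁺ pixel. healthy: the rest. Precedence
    damage > repair > healthy, so the classes partition the tissue mask.
    """

    damage_radius_um: float = 10.0
    damage_threshold: float = 0.5
    repair_radius_um: float = 20.0
    threshold_method: str = "otsu"
    f480_fixed_threshold: float | None = None
    emyhc_fixed_threshold: float | None = None


def _local_fraction(mask: np.ndarray, radius_px: float) -> np.ndarray:
    from mdxquant.stainsep import local_disk_fraction

    return local_disk_fraction(mask, radius_px)


def classify_regions(
    f480: ChannelImage,
    emyhc: ChannelImage,
    tissue: np.ndarray,
    params: RegionParams | None = None,
) -> RegionClassMap:
    """Partition tissue into damage / repair / healthy classes.

    See :class:`RegionParams` for the operational definitions. With both
    marker channels blank, all tissue is healthy.
    """
    params = params or RegionParams()
    tissue = np.asarray(tissue, dtype=bool)
    ps = f480.pixel_size_um
    if not np.isclose(ps, emyhc.pixel_size_um):
        raise ValueError("F4/80 and eMyHC calibrations differ")

    f_img = f480.astype_float()
    f_thr = _channel_threshold(
        f_img[tissue], params.threshold_method, params.f480_fixed_threshold
    )
    f_pos = (f_img > f_thr) & tissue
    damage = (
        _local_fraction(f_pos, params.damage_radius_um / ps) > params.damage_threshold
    ) & tissue

    e_img = emyhc.astype_float()
    e_thr = _channel_threshold(
        e_img[tissue], params.threshold_method, params.emyhc_fixed_threshold
    )
    e_pos = (e_img > e_thr) & tissue
    if e_pos.any():
        near = ndi.distance_transform_edt(~e_pos) <= params.repair_radius_um / ps
    else:
        near = np.zeros_like(tissue)
    repair = near & tissue & ~damage

    classes = np.zeros(tissue.shape, dtype=np.uint8)
    classes[tissue] = RegionClassMap.CODES["healthy"]
    classes[repair] = RegionClassMap.CODES["repair"]
    classes[damage] = RegionClassMap.CODES["damage"]
    return RegionClassMap(classes, ps)


def region_normalized_score(
    psmad2: ChannelImage,
    regions: RegionClassMap,
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
) -> dict[str, float | None]:
    """Marker-positive area fraction within each region class.

    "Locally normalised" means each class's positive area is divided by that
    class's own area, so the score is independent of how large the other
    classes are. Classes with zero area are reported as None (missing),
    never as 0.
    """
    if not np.isclose(psmad2.pixel_size_um, regions.pixel_size_um):
        raise ValueError("p-SMAD2 and region map calibrations differ")
    tissue = regions.tissue_mask()
    if not tissue.any():
        raise ValueError("region map contains no tissue")
    img = psmad2.astype_float()
    thr = _channel_threshold(img[tissue], threshold_method, fixed_threshold)
    pos = img > thr
    out: dict[str, float | None] = {}
    for name in ("damage", "repair", "healthy"):
        cls = regions.mask(name)
        n = int(cls.sum())
        out[name] = None if n == 0 else float(pos[cls].sum()) / n
    return out
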