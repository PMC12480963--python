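"""Ground-truthed synthetic muscle cross-sections and qPCR plates.

The phantom generator builds everything the analysis stages consume —
laminin/DAPI/marker fluorescence channels, Sirius Red/Fast Green and
H&E-like brightfield renderings, and a complete ground truth — so that
every downstream quantity (fibre size, %CNF, collagen %, necrotic %,
marker fractions, region scores) can be checked against known values
without external slide data.

Geometry: a jittered hexagonal lattice of seed points is grown into a
multiplicatively weighted nearest-seed tessellation (convex-ish cells whose
minimum Feret diameter tracks a per-cell size draw), separated by a
laminin-positive boundary band of stated thickness. Nuclei sit peripherally
by default and centrally — at the cell's distance-transform maximum, which
lies beyond half the equivalent radius — for the requested fraction of
fibres. Focal lesions (mononuclear infiltrate) and interstitial collagen
deposits are placed as exact-area disk unions; brightfield images are
rendered through the Beer–Lambert forward model shared with the
stain-separation stage. All randomness flows from one integer seed through
named `numpy` child generators, so the same spec reproduces bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from mdxquant.centronucleation import NucleusRecord
from mdxquant.io_core import ChannelImage, FiberLabelMap, RegionClassMap
from mdxquant import stainsep

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "PhantomGenerationError",
    "preset",
    "PRESET_NAMES",
    "generate_phantom",
    "generate_qpcr_plate",
]

MARGIN_PX = 6  # background margin around the tissue block
NUCLEUS_RADIUS_UM = 2.5
FLUOR_INTENSITY = {"laminin": 200.0, "DAPI": 180.0, "marker": 150.0}


class PhantomGenerationError(ValueError):
    """Raised when a spec cannot be realised (e.g. field too small)."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic muscle cross-section.

    Fibre size is controlled through the target minimum Feret diameter
    (mean and coefficient of variation, µm); fractions are relative to
    fibre counts (cnf, IgM) or tissue area (collagen, necrotic);
    ``marker_snr`` sets the fluorescence signal-to-noise ratio (Gaussian
    noise of SD = signal/SNR).
    """

    field_size_px: tuple[int, int] = (640, 640)
    pixel_size_um: float = 1.0
    n_fibers_target: int = 300
    fiber_minferet_mean_um: float = 30.0
    fiber_minferet_cv: float = 0.15
    boundary_thickness_px: int = 4
    cnf_fraction: float = 0.0
    nuclei_per_fiber_mean: float = 2.0
    collagen_fraction: float = 0.0
    necrotic_fraction: float = 0.0
    igm_positive_fraction: float = 0.0
    emyhc_count_per_mm2: float = 0.0
    marker_snr: float = 10.0
    seed: int = 0
    # secondary knobs with fixed, documented defaults
    pdgfra_positive_fraction: float = 0.25  # of all nucleated cells
    interstitial_cells_per_fiber: float = 2.0
    psmad2_positivity: tuple[float, float, float] = (0.6, 0.3, 0.05)  # damage, repair, healthy
    repair_radius_um: float = 20.0

    def __post_init__(self) -> None:
        for name in (
            "cnf_fraction",
            "collagen_fraction",
            "necrotic_fraction",
            "igm_positive_fraction",
            "pdgfra_positive_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise PhantomGenerationError(f"{name} must be in [0, 1], got {v}")
        if self.pixel_size_um <= 0:
            raise PhantomGenerationError("pixel_size_um must be positive")
        if self.fiber_minferet_mean_um <= 0 or self.fiber_minferet_cv < 0:
            raise PhantomGenerationError("fibre size parameters must be positive")
        if self.marker_snr <= 0:
            raise PhantomGenerationError("marker_snr must be positive")
        if self.n_fibers_target <= 0 or self.boundary_thickness_px <= 0:
            raise PhantomGenerationError("counts and thicknesses must be positive")
        # capacity: the tissue block must hold the requested fibres at the
        # requested size (and never fewer than 25)
        h, w = self.field_size_px
        tissue_px = max(0, h - 2 * MARGIN_PX) * max(0, w - 2 * MARGIN_PX)
        spacing = self.fiber_minferet_mean_um / self.pixel_size_um + self.boundary_thickness_px
        cell_px = (math.sqrt(3) / 2) * spacing**2
        capacity = tissue_px / cell_px
        needed = max(25, self.n_fibers_target)
        if capacity < needed:
            raise PhantomGenerationError(
                f"field {h}x{w} px holds ~{capacity:.0f} fibres of "
                f"{self.fiber_minferet_mean_um} µm but {needed} are required"
            )


# Presets mirror the age/genotype trends of the dystrophic (mdx5Cv) masseter
# model: CNF absent in wild type and ~60/55/50 % at 3/6/12 months; collagen
# content low in wt and rising with age in the dystrophic presets; active
# damage (IgM, necrosis) and regeneration (eMyHC) peaking early.
_PRESETS: dict[str, dict] = {
    "wt": dict(
        field_size_px=(768, 768),
        fiber_minferet_mean_um=38.0,
        fiber_minferet_cv=0.13,
        cnf_fraction=0.0,
        collagen_fraction=0.02,
        necrotic_fraction=0.0,
        igm_positive_fraction=0.0,
        emyhc_count_per_mm2=0.0,
    ),
    "mdx_3m": dict(
        fiber_minferet_mean_um=28.0,
        fiber_minferet_cv=0.25,
        cnf_fraction=0.60,
        collagen_fraction=0.04,
        necrotic_fraction=0.06,
        igm_positive_fraction=0.04,
        emyhc_count_per_mm2=25.0,
    ),
    "mdx_6m": dict(
        fiber_minferet_mean_um=29.0,
        fiber_minferet_cv=0.25,
        cnf_fraction=0.55,
        collagen_fraction=0.08,
        necrotic_fraction=0.04,
        igm_positive_fraction=0.03,
        emyhc_count_per_mm2=15.0,
    ),
    "mdx_12m": dict(
        fiber_minferet_mean_um=30.0,
        fiber_minferet_cv=0.25,
        cnf_fraction=0.50,
        collagen_fraction=0.12,
        necrotic_fraction=0.02,
        igm_positive_fraction=0.02,
        emyhc_count_per_mm2=8.0,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, **overrides) -> PhantomSpec:
    """Named parameter set emulating one study condition.

    ``"wt"`` (no centronucleation, minimal collagen) or ``"mdx_3m"`` /
    ``"mdx_6m"`` / ``"mdx_12m"`` (CNF 0.60/0.55/0.50, collagen rising with
    age). Keyword overrides replace individual fields.
    """
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; valid presets: {sorted(_PRESETS)}")
    spec = PhantomSpec(**_PRESETS[name])
    return replace(spec, **overrides) if overrides else spec


@dataclass
class GroundTruth:
    """Everything the generator knows about a phantom.

    The stored scalar fractions are recomputed from the stored masks/ids at
    construction (self-consistency is an invariant, not a convention).
    """

    fiber_labels: FiberLabelMap
    nucleus_table: list[NucleusRecord]
    tissue_mask: np.ndarray
    collagen_mask: np.ndarray
    infiltrate_mask: np.ndarray
    igm_fiber_ids: frozenset[int]
    emyhc_fiber_ids: frozenset[int]
    cnf_fiber_ids: frozenset[int]
    pdgfra_cell_ids: frozenset[int]
    region_class_map: RegionClassMap
    psmad2_positive_mask: np.ndarray
    true_cnf_fraction: float = field(init=False)
    true_collagen_fraction: float = field(init=False)
    true_necrotic_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        n_tissue = int(self.tissue_mask.sum())
        n_fibers = len(self.fiber_ids)
        self.true_cnf_fraction = len(self.cnf_fiber_ids) / n_fibers if n_fibers else 0.0
        self.true_collagen_fraction = float(self.collagen_mask.sum()) / n_tissue
        self.true_necrotic_fraction = float(self.infiltrate_mask.sum()) / n_tissue

    @property
    def fiber_ids(self) -> np.ndarray:
        return self.fiber_labels.ids

    def nucleus_dataframe(self) -> pd.DataFrame:
        ps = self.fiber_labels.pixel_size_um
        return pd.DataFrame(
            [
                {
                    "nucleus_id": r.nucleus_id,
                    "fiber_id": r.fiber_id,
                    "centroid_row": r.centroid_px[0],
                    "centroid_col": r.centroid_px[1],
                    "centroid_x_um": r.centroid_px[1] * ps,
                    "centroid_y_um": r.centroid_px[0] * ps,
                    "area_um2": r.area_um2,
                    "dist_to_border_um": r.dist_to_border_um,
                    "is_internal": r.is_internal,
                }
                for r in self.nucleus_table
            ]
        )


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _hex_seeds(tissue_box: tuple[int, int, int, int], spacing: float, rng) -> np.ndarray:
    r0, r1, c0, c1 = tissue_box
    dy = spacing * math.sqrt(3) / 2
    rows = np.arange(r0 + spacing / 2, r1 - spacing / 4, dy)
    pts = []
    for i, r in enumerate(rows):
        offset = spacing / 2 if i % 2 else 0.0
        cols = np.arange(c0 + spacing / 2 + offset, c1 - spacing / 4, spacing)
        pts.extend((r, c) for c in cols)
    pts = np.asarray(pts, dtype=float)
    jitter = rng.uniform(-0.18 * spacing, 0.18 * spacing, size=pts.shape)
    return pts + jitter


def _weighted_tessellation(
    shape: tuple[int, int], tissue: np.ndarray, seeds: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Assign each tissue pixel to argmin distance/weight over nearby seeds."""
    tree = cKDTree(seeds)
    rr, cc = np.nonzero(tissue)
    pix = np.column_stack([rr, cc]).astype(float)
    k = min(12, len(seeds))
    dist, idx = tree.query(pix, k=k, workers=1)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    best = np.argmin(dist / weights[idx], axis=1)
    labels = np.zeros(shape, dtype=np.int32)
    labels[rr, cc] = idx[np.arange(len(pix)), best] + 1
    return labels


def _disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(math.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = yy**2 + xx**2 <= radius**2 + 1e-9
    return yy[keep], xx[keep]


def _exact_area_blobs(
    target_px: int,
    allowed: np.ndarray,
    center_pool: np.ndarray,
    radius_range: tuple[float, float],
    rng,
) -> np.ndarray:
    """Union of random disks clipped to ``allowed``, trimmed to exactly
    ``target_px`` pixels (the last disk is shrunk pixel-by-pixel from its rim).
    """
    out = np.zeros(allowed.shape, dtype=bool)
    if target_px <= 0:
        return out
    h, w = allowed.shape
    flat_pool = np.flatnonzero(center_pool)
    if flat_pool.size == 0:
        raise PhantomGenerationError("no valid centre pixels for blob placement")
    n = 0
    for _ in range(10000):
        centre = flat_pool[rng.integers(flat_pool.size)]
        cr, cc = divmod(int(centre), w)
        radius = rng.uniform(*radius_range)
        dy, dx = _disk_offsets(radius)
        rr = cr + dy
        cc_ = cc + dx
        ok = (rr >= 0) & (rr < h) & (cc_ >= 0) & (cc_ < w)
        rr, cc_, dy, dx = rr[ok], cc_[ok], dy[ok], dx[ok]
        new = allowed[rr, cc_] & ~out[rr, cc_]
        need = target_px - n
        if new.sum() > need:
            # keep the innermost pixels of the final disk so it stays compact
            order = np.argsort(dy[new] ** 2 + dx[new] ** 2, kind="stable")[:need]
            rr, cc_ = rr[new][order], cc_[new][order]
            out[rr, cc_] = True
            return out
        out[rr[new], cc_[new]] = True
        n += int(new.sum())
        if n >= target_px:
            return out
    raise PhantomGenerationError("blob placement did not converge")


def _draw_disks(canvas: np.ndarray, centres, radius: float, value: float) -> None:
    h, w = canvas.shape
    dy, dx = _disk_offsets(radius)
    for r, c in centres:
        rr = int(round(r)) + dy
        cc = int(round(c)) + dx
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        canvas[rr[ok], cc[ok]] = value


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[dict[str, ChannelImage], dict[str, np.ndarray], GroundTruth]:
    """Render one synthetic muscle cross-section with full ground truth.

    Returns ``(channels, brightfield, truth)``: named fluorescence channels
    (laminin, DAPI, IgM, eMyHC, F4-80, PDGFRA, p-SMAD2), brightfield RGB
    renderings (``sirius_fastgreen``, ``he``), and the :class:`GroundTruth`.
    """
    ps = spec.pixel_size_um
    h, w = spec.field_size_px
    streams = np.random.SeedSequence(spec.seed).spawn(6)
    rng_geom, rng_lesion, rng_nuc, rng_coll, rng_marker, rng_noise = (
        np.random.default_rng(s) for s in streams
    )

    tissue = np.zeros((h, w), dtype=bool)
    tissue[MARGIN_PX : h - MARGIN_PX, MARGIN_PX : w - MARGIN_PX] = True
    n_tissue = int(tissue.sum())

    # --- tessellation ------------------------------------------------------
    t_band = spec.boundary_thickness_px
    spacing = spec.fiber_minferet_mean_um / ps + t_band
    seeds = _hex_seeds((MARGIN_PX, h - MARGIN_PX, MARGIN_PX, w - MARGIN_PX), spacing, rng_geom)
    cv = spec.fiber_minferet_cv
    sigma2 = math.log(1.0 + cv**2)
    weights = rng_geom.lognormal(mean=-sigma2 / 2, sigma=math.sqrt(sigma2), size=len(seeds))
    cells = _weighted_tessellation((h, w), tissue, seeds, weights)

    # --- focal lesions (mononuclear infiltrate) ----------------------------
    lesion_target = int(round(spec.necrotic_fraction * n_tissue))
    lesion = _exact_area_blobs(lesion_target, tissue, tissue, (15.0, 40.0), rng_lesion)

    # --- laminin band; lesions get their own bounding membrane -------------
    ext = cells.copy()
    ext[~tissue] = -1
    ext[lesion] = -2
    dy, dx = _disk_offsets(t_band / 2)
    size = int(math.ceil(t_band / 2))
    foot = np.zeros((2 * size + 1, 2 * size + 1), dtype=bool)
    foot[dy + size, dx + size] = True
    band = (
        ndi.maximum_filter(ext, footprint=foot) != ndi.minimum_filter(ext, footprint=foot)
    ) & tissue & ~lesion

    interiors = tissue & ~band & ~lesion
    labels, _ = ndi.label(interiors)
    min_px = max(1, int(round(100.0 / ps**2)))  # drop sub-100 µm² slivers
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_px)
    keep = keep[keep > 0]
    remap = np.zeros(counts.size, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    labels = remap[labels]
    fiber_map = FiberLabelMap(labels, ps)
    fiber_ids = fiber_map.ids
    n_fibers = len(fiber_ids)
    if n_fibers < max(25, 1):
        raise PhantomGenerationError("tessellation produced too few fibres")
    areas = np.bincount(labels.ravel())
    edt = ndi.distance_transform_edt(labels > 0)

    # --- CNF assignment ----------------------------------------------------
    r_eq = np.sqrt(areas / math.pi)  # px, indexed by label
    slices = ndi.find_objects(labels)
    d_max_pos: dict[int, tuple[int, int]] = {}
    for fid in fiber_ids:
        sl = slices[fid - 1]
        sub = edt[sl] * (labels[sl] == fid)
        pos = np.unravel_index(np.argmax(sub), sub.shape)
        d_max_pos[int(fid)] = (pos[0] + sl[0].start, pos[1] + sl[1].start)
    candidates = [
        int(fid)
        for fid in fiber_ids
        if edt[d_max_pos[int(fid)]] > 0.5 * r_eq[fid] + 1.0
    ]
    order = rng_nuc.permutation(len(candidates))
    n_central = min(int(round(spec.cnf_fraction * n_fibers)), len(candidates))
    cnf_ids = frozenset(candidates[i] for i in order[:n_central])

    # --- nuclei ------------------------------------------------------------
    r_nuc_px = NUCLEUS_RADIUS_UM / ps
    nuc_area_um2 = math.pi * NUCLEUS_RADIUS_UM**2
    records: list[NucleusRecord] = []
    nid = 0
    for fid in fiber_ids:
        fid = int(fid)
        sl = slices[fid - 1]
        inside = labels[sl] == fid
        d_sub = edt[sl]
        peri_r, peri_c = np.nonzero(inside & (d_sub >= 1.0) & (d_sub <= 2.2))
        n_nuc = max(1, int(rng_nuc.poisson(spec.nuclei_per_fiber_mean)))
        picks = rng_nuc.choice(len(peri_r), size=min(n_nuc, len(peri_r)), replace=False)
        for p in picks:
            nid += 1
            rr, cc = peri_r[p] + sl[0].start, peri_c[p] + sl[1].start
            records.append(
                NucleusRecord(
                    nucleus_id=nid,
                    fiber_id=fid,
                    centroid_px=(float(rr), float(cc)),
                    area_um2=nuc_area_um2,
                    dist_to_border_um=float(edt[rr, cc]) * ps,
                    is_internal=False,
                )
            )
        if fid in cnf_ids:
            nid += 1
            rr, cc = d_max_pos[fid]
            records.append(
                NucleusRecord(
                    nucleus_id=nid,
                    fiber_id=fid,
                    centroid_px=(float(rr), float(cc)),
                    area_um2=nuc_area_um2,
                    dist_to_border_um=float(edt[rr, cc]) * ps,
                    is_internal=True,
                )
            )

    # interstitial cells on the boundary band (FAP candidates)
    band_r, band_c = np.nonzero(band)
    n_inter = int(rng_nuc.poisson(spec.interstitial_cells_per_fiber * n_fibers))
    n_inter = min(n_inter, len(band_r))
    picks = rng_nuc.choice(len(band_r), size=n_inter, replace=False)
    inter_ids = []
    for p in picks:
        nid += 1
        inter_ids.append(nid)
        records.append(
            NucleusRecord(
                nucleus_id=nid,
                fiber_id=0,
                centroid_px=(float(band_r[p]), float(band_c[p])),
                area_um2=nuc_area_um2,
                dist_to_border_um=0.0,
                is_internal=False,
            )
        )
    # FAPs are interstitial: the requested fraction of *all* cells is drawn
    # from the interstitial pool (clamped to its size)
    perm = rng_nuc.permutation(n_inter)
    n_pdgfra = min(
        int(round(spec.pdgfra_positive_fraction * len(records))), n_inter
    )
    pdgfra_ids = frozenset(inter_ids[i] for i in perm[:n_pdgfra])

    # --- marker fibre selections ------------------------------------------
    tissue_mm2 = n_tissue * ps**2 * 1e-6
    fid_perm = rng_marker.permutation(n_fibers)
    n_igm = int(round(spec.igm_positive_fraction * n_fibers))
    igm_ids = frozenset(int(fiber_ids[i]) for i in fid_perm[:n_igm])
    n_emyhc = min(int(round(spec.emyhc_count_per_mm2 * tissue_mm2)), n_fibers)
    by_area = sorted((int(f) for f in fiber_ids), key=lambda f: areas[f])
    emyhc_ids = frozenset(by_area[:n_emyhc])

    # --- collagen deposits -------------------------------------------------
    coll_target = int(round(spec.collagen_fraction * n_tissue))
    centre_pool = band if band.any() else tissue
    collagen = _exact_area_blobs(coll_target, tissue, centre_pool, (3.0, 10.0), rng_coll)

    # --- region classes and p-SMAD2 truth ----------------------------------
    emyhc_mask = np.isin(labels, list(emyhc_ids)) if emyhc_ids else np.zeros_like(tissue)
    damage = lesion
    if emyhc_mask.any():
        near = ndi.distance_transform_edt(~emyhc_mask) <= spec.repair_radius_um / ps
    else:
        near = np.zeros_like(tissue)
    repair = near & tissue & ~damage
    classes = np.zeros((h, w), dtype=np.uint8)
    classes[tissue] = RegionClassMap.CODES["healthy"]
    classes[repair] = RegionClassMap.CODES["repair"]
    classes[damage] = RegionClassMap.CODES["damage"]
    region_map = RegionClassMap(classes, ps)

    psmad2_mask = np.zeros((h, w), dtype=bool)
    u = rng_marker.random((h, w))
    for name, rate in zip(("damage", "repair", "healthy"), spec.psmad2_positivity):
        cls = region_map.mask(name)
        psmad2_mask |= cls & (u < rate)

    truth = GroundTruth(
        fiber_labels=fiber_map,
        nucleus_table=records,
        tissue_mask=tissue,
        collagen_mask=collagen,
        infiltrate_mask=lesion,
        igm_fiber_ids=igm_ids,
        emyhc_fiber_ids=emyhc_ids,
        cnf_fiber_ids=cnf_ids,
        pdgfra_cell_ids=pdgfra_ids,
        region_class_map=region_map,
        psmad2_positive_mask=psmad2_mask,
    )

    # --- render fluorescence ------------------------------------------------
    amp = FLUOR_INTENSITY
    nuc_canvas = np.zeros((h, w))
    _draw_disks(nuc_canvas, [r.centroid_px for r in records], r_nuc_px, amp["DAPI"])
    # dense mononuclear puncta inside lesions
    if lesion.any():
        lr, lc = np.nonzero(lesion)
        n_punct = max(1, int(0.35 * lesion.sum() / (math.pi * r_nuc_px**2)))
        pk = rng_nuc.choice(len(lr), size=min(n_punct, len(lr)), replace=False)
        _draw_disks(nuc_canvas, list(zip(lr[pk], lc[pk])), r_nuc_px, amp["DAPI"])

    pdgfra_canvas = np.zeros((h, w))
    ring_out = r_nuc_px + 3.0
    for rec in records:
        if rec.nucleus_id in pdgfra_ids:
            dy2, dx2 = _disk_offsets(ring_out)
            ring = dy2**2 + dx2**2 >= (r_nuc_px + 0.5) ** 2
            rr = int(round(rec.centroid_px[0])) + dy2[ring]
            cc = int(round(rec.centroid_px[1])) + dx2[ring]
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            pdgfra_canvas[rr[ok], cc[ok]] = amp["marker"]

    planes = {
        "laminin": band.astype(float) * amp["laminin"],
        "DAPI": nuc_canvas,
        "IgM": np.isin(labels, list(igm_ids)).astype(float) * amp["marker"]
        if igm_ids
        else np.zeros((h, w)),
        "eMyHC": emyhc_mask.astype(float) * amp["marker"],
        "F4-80": lesion.astype(float) * amp["marker"],
        "PDGFRA": pdgfra_canvas,
        "p-SMAD2": psmad2_mask.astype(float) * amp["marker"],
    }
    channels: dict[str, ChannelImage] = {}
    base = {"laminin": amp["laminin"], "DAPI": amp["DAPI"]}
    for name in planes:  # fixed order keeps the noise stream reproducible
        sd = base.get(name, amp["marker"]) / spec.marker_snr
        noisy = planes[name] + rng_noise.normal(0.0, sd, size=(h, w))
        arr = np.clip(np.round(noisy), 0, 65535).astype(np.uint16)
        channels[name] = ChannelImage(arr, ps, name)

    # --- render brightfield -------------------------------------------------
    sr = np.where(collagen, 1.0, 0.0)
    fg = np.where(tissue & ~collagen, 0.8, np.where(collagen, 0.15, 0.0))
    od = np.stack([sr, fg], axis=-1) @ stainsep.SIRIUS_FASTGREEN.stain_od_vectors
    od += rng_noise.normal(0.0, 0.01, size=od.shape)
    srfg_rgb = stainsep.od_to_rgb(np.maximum(od, 0), stainsep.SIRIUS_FASTGREEN)

    haem = np.clip(nuc_canvas / amp["DAPI"], 0, 1) * 1.0
    haem = np.maximum(haem, lesion * 0.9)
    eos = np.where(labels > 0, 0.55, np.where(band, 0.35, np.where(lesion, 0.15, 0.0)))
    od_he = np.stack([haem, eos], axis=-1) @ stainsep.H_AND_E.stain_od_vectors
    od_he += rng_noise.normal(0.0, 0.01, size=od_he.shape)
    he_rgb = stainsep.od_to_rgb(np.maximum(od_he, 0), stainsep.H_AND_E)

    brightfield = {"sirius_fastgreen": srfg_rgb, "he": he_rgb}
    return channels, brightfield, truth


# ---------------------------------------------------------------------------
# qPCR plate generator
# ---------------------------------------------------------------------------


def generate_qpcr_plate(
    genes: list[str],
    groups: list[str],
    n_per_group: int,
    efficiencies: dict[str, float],
    base_quantities: dict[str, dict[str, float]],
    noise_sd_ct: float = 0.0,
    dilution_steps: int = 5,
    n_replicates: int = 3,
    intercepts: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a long-format qPCR plate under the log-linear dilution model.

    ``Ct = intercept − log10(quantity)/log10(1 + E) + N(0, noise_sd_ct)``,
    with a 10-fold dilution series of ``dilution_steps`` points per gene for
    standard-curve fitting. ``base_quantities[gene][group]`` sets each
    group's true relative input; deterministic under ``seed``.
    """
    if dilution_steps < 3:
        raise ValueError("dilution_steps must be >= 3")
    for g in genes:
        e = efficiencies[g]
        if not 0.0 < e <= 1.0:
            raise ValueError(f"efficiency for {g!r} must be in (0, 1], got {e}")
    intercepts = intercepts or {}
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    rows = []
    for g in genes:
        slope = -1.0 / math.log10(1.0 + efficiencies[g])
        icpt = intercepts.get(g, 22.0)
        for step in range(dilution_steps):
            dfac = 10.0 ** (-step)
            ct0 = icpt + slope * math.log10(dfac)
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "gene": g,
                        "sample": f"std_{g}_{step}",
                        "group": "standard",
                        "replicate": rep,
                        "ct": ct0 + rng.normal(0.0, noise_sd_ct),
                        "is_dilution_standard": True,
                        "dilution_factor": dfac,
                    }
                )
        for grp in groups:
            q = base_quantities[g][grp]
            if q <= 0:
                raise ValueError(f"nonpositive quantity for gene {g!r}, group {grp!r}")
            ct0 = icpt + slope * math.log10(q)
            for i in range(1, n_per_group + 1):
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        {
                            "gene": g,
                            "sample": f"{grp}_{i}",
                            "group": grp,
                            "replicate": rep,
                            "ct": ct0 + rng.normal(0.0, noise_sd_ct),
                            "is_dilution_standard": False,
                            "dilution_factor": np.nan,
                        }
                    )
    return pd.DataFrame(rows)
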