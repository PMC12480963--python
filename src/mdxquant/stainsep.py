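"""Beer–Lambert optical density, colour deconvolution and fibrosis scoring.

Brightfield chromogenic stains mix linearly in optical-density (OD) space:
``OD_c = -log10(I_c / I0_c)`` per RGB channel ``c``, and a pixel's OD vector
is the stain densities times the unit stain-absorption vectors. Unmixing
("colour deconvolution") inverts that linear system to recover per-stain
density pseudo-channels, from which collagen (Sirius Red) area over tissue
area gives the fibrosis percentage. Haematoxylin density drives the
mononuclear-infiltrate component of the necrosis score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from skimage.filters import threshold_otsu

__all__ = [
    "StainModel",
    "FibrosisResult",
    "SIRIUS_FASTGREEN",
    "H_AND_E",
    "rgb_to_od",
    "od_to_rgb",
    "compose_od",
    "deconvolve",
    "local_disk_fraction",
    "collagen_fraction",
    "infiltrate_mask",
]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length stain vector")
    return v / n


@dataclass
class StainModel:
    """Stain absorption model: unit OD vectors plus background intensity.

    Two-stain models are completed with an orthogonal residual vector before
    inversion so the stain matrix is always 3x3.
    """

    stain_names: list[str]
    stain_od_vectors: np.ndarray  # (n_stains, 3), rows unit-norm
    background_intensity: np.ndarray = field(
        default_factory=lambda: np.array([255.0, 255.0, 255.0])
    )
    od_floor: float = 1.0 / 255.0
    max_condition_number: float = 50.0

    def __post_init__(self) -> None:
        vecs = np.atleast_2d(np.asarray(self.stain_od_vectors, dtype=float))
        self.stain_od_vectors = np.array([_unit(v) for v in vecs])
        self.background_intensity = np.asarray(self.background_intensity, dtype=float)
        if np.any(self.background_intensity <= 0):
            raise ValueError("background_intensity must be positive per channel")
        if len(self.stain_names) != len(self.stain_od_vectors):
            raise ValueError("one OD vector per stain name required")

    def full_matrix(self) -> np.ndarray:
        """Stain matrix with rows = stain vectors, padded to 3 with a residual."""
        m = self.stain_od_vectors
        if m.shape[0] == 3:
            full = m
        elif m.shape[0] == 2:
            resid = _unit(np.cross(m[0], m[1]))
            full = np.vstack([m, resid])
        else:
            raise ValueError("StainModel supports 2 or 3 stains")
        cond = np.linalg.cond(full)
        if cond > self.max_condition_number:
            raise ValueError(
                f"stain vectors nearly parallel (condition number {cond:.1f} > "
                f"{self.max_condition_number}); deconvolution unreliable"
            )
        return full

    def index(self, name: str) -> int:
        return self.stain_names.index(name)


# Published absorption vectors for the two stain pairs this pipeline scores.
# Sirius Red / Fast Green follow the red-collagen / green-counterstain
# chromophores; H&E are the classic Ruifrok–Johnston vectors.
SIRIUS_FASTGREEN = StainModel(
    stain_names=["sirius_red", "fast_green"],
    stain_od_vectors=np.array(
        [
            [0.148, 0.772, 0.618],  # Sirius Red absorbs green/blue
            [0.708, 0.208, 0.675],  # Fast Green absorbs red/blue
        ]
    ),
)

H_AND_E = StainModel(
    stain_names=["haematoxylin", "eosin"],
    stain_od_vectors=np.array(
        [
            [0.650, 0.704, 0.286],
            [0.072, 0.990, 0.105],
        ]
    ),
)


def rgb_to_od(
    rgb: np.ndarray,
    background_intensity: np.ndarray | float = 255.0,
    od_floor: float = 1.0 / 255.0,
) -> np.ndarray:
    """Convert an RGB image to per-channel optical density.

    ``OD_c = -log10(max(I_c, floor·I0_c) / I0_c)``; zero-intensity pixels are
    floored so the result stays finite, and OD is clipped nonnegative.
    """
    i0 = np.broadcast_to(np.asarray(background_intensity, dtype=float), (3,))
    if np.any(i0 <= 0):
        raise ValueError("background_intensity must be positive")
    img = np.asarray(rgb, dtype=float)
    frac = np.maximum(img / i0, od_floor)
    return np.maximum(-np.log10(frac), 0.0)


def compose_od(densities: np.ndarray, model: StainModel) -> np.ndarray:
    """Forward Beer–Lambert mixing: stain densities (..., n_stains) -> OD (..., 3)."""
    return np.asarray(densities, dtype=float) @ model.stain_od_vectors


def od_to_rgb(od: np.ndarray, model: StainModel) -> np.ndarray:
    """Render an OD image to 8-bit RGB against the model's background."""
    i0 = model.background_intensity
    rgb = i0 * np.power(10.0, -np.asarray(od, dtype=float))
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def deconvolve(
    od: np.ndarray, model: StainModel, clip_negative: bool = True
) -> tuple[np.ndarray, float]:
    """Unmix an OD image into per-stain densities.

    Returns ``(densities, clip_fraction)`` where densities has one plane per
    stain (plus a residual plane for two-stain models) and ``clip_fraction``
    is the fraction of pixels whose density went negative before clipping —
    a diagnostic for a wrong stain model, reported rather than hidden.
    """
    full = model.full_matrix()
    inv = np.linalg.inv(full)  # OD @ inv maps OD rows to density rows
    dens = np.asarray(od, dtype=float) @ inv
    n_named = len(model.stain_names)
    named = dens[..., :n_named]
    clip_fraction = float(np.mean(np.any(named < -1e-9, axis=-1)))
    if clip_negative:
        dens = np.maximum(dens, 0.0)
    return dens, clip_fraction


def local_disk_fraction(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Fraction of a disk neighbourhood covered by ``mask`` at each pixel.

    Near the image border the denominator is the in-bounds part of the disk,
    so a fully covered field scores 1 everywhere.
    """
    r = max(1, int(round(radius_px)))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = ((yy**2 + xx**2) <= r**2).astype(float)
    num = fftconvolve(mask.astype(float), disk, mode="same")
    den = fftconvolve(np.ones(mask.shape), disk, mode="same")
    return np.clip(num / den, 0.0, 1.0)


@dataclass
class FibrosisResult:
    tissue_area_um2: float
    collagen_area_um2: float

    @property
    def collagen_percent(self) -> float:
        return 100.0 * self.collagen_area_um2 / self.tissue_area_um2


def _threshold(values: np.ndarray, method: str, fixed: float | None, floor: float) -> float:
    if method == "fixed":
        if fixed is None:
            raise ValueError("fixed threshold_method requires a threshold value")
        return float(fixed)
    if method == "otsu":
        if values.size == 0 or np.ptp(values) == 0:
            return floor
        return max(float(threshold_otsu(values)), floor)
    raise ValueError(f"unknown threshold_method {method!r}")


def collagen_fraction(
    rgb: np.ndarray,
    tissue_mask: np.ndarray,
    pixel_size_um: float,
    model: StainModel = SIRIUS_FASTGREEN,
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
    min_od: float = 0.15,
) -> FibrosisResult:
    """Score collagen-positive area within tissue from a Sirius Red/Fast Green slide.

    The Sirius Red density pseudo-channel is thresholded inside the tissue
    mask (Otsu by default, guarded by ``min_od`` so a collagen-free slide is
    not split on noise) and the positive area is normalised to tissue area.
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    n_tissue = int(tissue_mask.sum())
    if n_tissue == 0:
        raise ValueError("empty tissue mask; collagen fraction undefined")
    od = rgb_to_od(rgb, model.background_intensity, model.od_floor)
    dens, _ = deconvolve(od, model)
    sirius = dens[..., model.index("sirius_red")]
    thr = _threshold(sirius[tissue_mask], threshold_method, fixed_threshold, min_od)
    collagen = (sirius > thr) & tissue_mask
    px2 = pixel_size_um**2
    return FibrosisResult(
        tissue_area_um2=n_tissue * px2,
        collagen_area_um2=int(collagen.sum()) * px2,
    )


def infiltrate_mask(
    rgb: np.ndarray,
    tissue_mask: np.ndarray,
    pixel_size_um: float,
    model: StainModel = H_AND_E,
    nuclear_density_radius_um: float = 10.0,
    density_threshold: float = 0.5,
    haematoxylin_min_od: float = 0.25,
    fragmentation_cv_cutoff: float | None = None,
    fiber_labels: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Detect mononuclear infiltrate (plus optional fragmented fibres) on H&E.

    Infiltrate = tissue where the local fraction of haematoxylin-positive
    pixels, averaged over a disk of ``nuclear_density_radius_um``, exceeds
    ``density_threshold``. When ``fragmentation_cv_cutoff`` and a fibre label
    map are supplied, fibres whose interior eosin density has a coefficient
    of variation above the cutoff are added (fragmented sarcoplasm). Returns
    the binary mask and the necrotic area percentage of tissue.
    """
    if model is None:
        raise ValueError("an H&E stain model is required")
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    n_tissue = int(tissue_mask.sum())
    if n_tissue == 0:
        raise ValueError("empty tissue mask")
    od = rgb_to_od(rgb, model.background_intensity, model.od_floor)
    dens, _ = deconvolve(od, model)
    haem = dens[..., model.index("haematoxylin")]
    nuclei = (haem > haematoxylin_min_od) & tissue_mask

    local = local_disk_fraction(
        nuclei, nuclear_density_radius_um / pixel_size_um
    )
    mask = (local > density_threshold) & tissue_mask

    if fragmentation_cv_cutoff is not None and fiber_labels is not None:
        eosin = dens[..., model.index("eosin")]
        for fid in np.unique(fiber_labels):
            if fid == 0:
                continue
            vals = eosin[fiber_labels == fid]
            m = vals.mean()
            if m > 0 and vals.std() / m > fragmentation_cv_cutoff:
                mask |= fiber_labels == fid

    necrotic_percent = 100.0 * mask.sum() / n_tissue
    return mask, float(necrotic_percent)
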