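"""Calibrated-image data model and file I/O shared by all pipeline stages.

Conventions
-----------
* Images are row-major 2-D arrays indexed ``[row, col]`` with 0-based pixel
  indices; pixel (0, 0) is the top-left corner.
* GeoJSON geometry is written in *pixel* units (x right = column, y down =
  row), with polygon vertices at pixel corners; the micron calibration is
  recorded in each feature's ``properties`` so coordinates stay lossless.
* Areas in µm² are always ``pixel count × pixel_size_um²``; densities per
  mm² are ``count / (tissue pixels × pixel_size_um² × 1e-6)``.
"""

from __future__ import annotations

import hashlib
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ChannelImage",
    "FiberLabelMap",
    "RegionClassMap",
    "CalibrationError",
    "ChannelNotFoundError",
    "read_image",
    "write_multichannel_ome_tiff",
    "write_results",
    "polygons_to_geojson",
    "geojson_to_polygons",
    "area_um2",
    "density_per_mm2",
]

REGION_CLASSES = ("background", "healthy", "damage", "repair")


class CalibrationError(ValueError):
    """Raised when pixel-size metadata is missing and no override is given."""


class ChannelNotFoundError(KeyError):
    """Raised when a requested channel name is absent from a file."""


@dataclass
class ChannelImage:
    """A single calibrated 2-D intensity image (one fluorescence channel).

    Parameters
    ----------
    pixels :
        2-D non-negative intensity array (integer or floating point).
    pixel_size_um :
        Edge length of one pixel in microns; must be positive.
    channel_name :
        Free-text channel identifier, e.g. ``"laminin"`` or ``"DAPI"``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("ChannelImage requires a nonempty 2-D array")
        if not self.pixel_size_um > 0:
            raise CalibrationError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def astype_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64, copy=False)


@dataclass
class FiberLabelMap:
    """Integer-labelled fibre segmentation; label 0 is background/interstitium."""

    labels: np.ndarray
    pixel_size_um: float
    border_touching_ids: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        if not self.pixel_size_um > 0:
            raise CalibrationError("pixel_size_um must be positive")
        self.border_touching_ids = frozenset(int(i) for i in self.border_touching_ids)

    @property
    def ids(self) -> np.ndarray:
        """Sorted positive label ids present in the map."""
        u = np.unique(self.labels)
        return u[u > 0]

    def mask(self, fiber_id: int) -> np.ndarray:
        return self.labels == fiber_id


@dataclass
class RegionClassMap:
    """Per-pixel tissue classification into background / healthy / damage / repair.

    ``classes`` stores small integer codes indexing :data:`REGION_CLASSES`.
    Tissue pixels carry exactly one non-background class, so class areas sum
    to the tissue area by construction.
    """

    classes: np.ndarray
    pixel_size_um: float

    CODES = {name: i for i, name in enumerate(REGION_CLASSES)}

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.uint8)
        if self.classes.max(initial=0) >= len(REGION_CLASSES):
            raise ValueError("unknown region class code")
        if not self.pixel_size_um > 0:
            raise CalibrationError("pixel_size_um must be positive")

    def mask(self, name: str) -> np.ndarray:
        return self.classes == self.CODES[name]

    def tissue_mask(self) -> np.ndarray:
        return self.classes != self.CODES["background"]


def area_um2(n_pixels: int | np.integer, pixel_size_um: float) -> float:
    return float(n_pixels) * float(pixel_size_um) ** 2


def density_per_mm2(count: int, tissue_pixels: int, pixel_size_um: float) -> float:
    tissue_mm2 = tissue_pixels * pixel_size_um**2 * 1e-6
    if tissue_mm2 <= 0:
        raise ValueError("tissue area is zero; density undefined")
    return count / tissue_mm2


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_OME_NS = "{http://www.openmicroscopy.org/Schemas/OME/2016-06}"


def _ome_pixel_size_and_channels(ome_xml: str) -> tuple[float | None, list[str]]:
    root = ET.fromstring(ome_xml)
    pixels = root.find(f"{_OME_NS}Image/{_OME_NS}Pixels")
    if pixels is None:
        return None, []
    psx = pixels.get("PhysicalSizeX")
    names = [
        ch.get("Name") or f"channel_{i}"
        for i, ch in enumerate(pixels.findall(f"{_OME_NS}Channel"))
    ]
    return (float(psx) if psx is not None else None), names


def read_image(
    path: str | Path,
    channel_spec: str | None = None,
    pixel_size_um: float | None = None,
):
    """Read a calibrated image from TIFF/OME-TIFF/PNG.

    Parameters
    ----------
    path :
        Image file. OME-TIFF channel names and pixel size are taken from the
        embedded OME-XML; plain TIFF/PNG require ``pixel_size_um``.
    channel_spec :
        Channel name to extract from a multichannel file. ``None`` returns a
        single-plane image as :class:`ChannelImage`, or an RGB array
        (H, W, 3) together with its pixel size for brightfield input.
    pixel_size_um :
        Explicit calibration override. Missing metadata without an override
        raises :class:`CalibrationError` — never a silent default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta_ps, channel_names = (None, [])
            if tif.ome_metadata:
                meta_ps, channel_names = _ome_pixel_size_and_channels(tif.ome_metadata)
        ps = pixel_size_um if pixel_size_um is not None else meta_ps
        if ps is None:
            raise CalibrationError(
                f"{path}: no pixel-size metadata; pass pixel_size_um explicitly"
            )
        if data.ndim == 3 and channel_spec is not None:
            if channel_spec not in channel_names:
                raise ChannelNotFoundError(
                    f"{path}: channel {channel_spec!r} not found; "
                    f"available: {channel_names}"
                )
            plane = data[channel_names.index(channel_spec)]
            return ChannelImage(plane, ps, channel_spec)
        if data.ndim == 2:
            if channel_spec is not None and channel_names and channel_spec not in channel_names:
                raise ChannelNotFoundError(
                    f"{path}: channel {channel_spec!r} not found; available: {channel_names}"
                )
            name = channel_spec or (channel_names[0] if channel_names else "")
            return ChannelImage(data, ps, name)
        # RGB brightfield (H, W, 3) or unnamed multichannel stack
        if data.ndim == 3 and data.shape[-1] == 3:
            return data, ps
        raise ValueError(f"{path}: cannot interpret array of shape {data.shape}")

    # PNG and friends carry no reliable calibration
    import imageio.v3 as iio

    if pixel_size_um is None:
        raise CalibrationError(
            f"{path}: format carries no pixel size; pass pixel_size_um explicitly"
        )
    data = iio.imread(path)
    if data.ndim == 3:
        return data[..., :3], pixel_size_um
    return ChannelImage(data, pixel_size_um, channel_spec or "")


def write_multichannel_ome_tiff(
    path: str | Path,
    channels: dict[str, np.ndarray],
    pixel_size_um: float,
) -> None:
    """Write named channels as an OME-TIFF with micron pixel-size metadata."""
    names = list(channels)
    stack = np.stack([np.asarray(channels[n]) for n in names])
    tifffile.imwrite(
        str(path),
        stack,
        ome=True,
        photometric="minisblack",  # a trailing dim of 3/4 is not RGB samples
        metadata={
            "axes": "CYX",
            "PhysicalSizeX": pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "Channel": {"Name": names},
        },
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def polygons_to_geojson(
    polygons: dict[int, list[tuple[float, float]]],
    pixel_size_um: float,
    kind: str = "fiber",
) -> dict:
    """Build a GeoJSON FeatureCollection from ``{id: [(x, y), ...]}`` vertex lists.

    Coordinates are pixel units (x right, y down, 0-based, vertices at pixel
    corners); calibration is stored per feature so the file round-trips
    losslessly.
    """
    features = []
    for pid, verts in polygons.items():
        ring = [list(map(float, v)) for v in verts]
        if ring and ring[0] != ring[-1]:
            ring = ring + [ring[0]]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "id": int(pid),
                    "kind": kind,
                    "pixel_size_um": pixel_size_um,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def geojson_to_polygons(gj: dict) -> dict[int, list[tuple[float, float]]]:
    out: dict[int, list[tuple[float, float]]] = {}
    for feat in gj["features"]:
        ring = feat["geometry"]["coordinates"][0]
        verts = [tuple(v) for v in ring]
        if len(verts) > 1 and verts[0] == verts[-1]:
            verts = verts[:-1]
        out[int(feat["properties"]["id"])] = verts
    return out


def config_hash(config: dict) -> str:
    """Stable hash of a JSON-serialisable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(
    out_dir: str | Path,
    tables: dict[str, pd.DataFrame] | None = None,
    masks: dict[str, np.ndarray] | None = None,
    geojson: dict[str, dict] | None = None,
    scalars: dict | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Write result tables, masks and geometry; return the run manifest.

    CSV gets one row per fibre/nucleus/sample; masks go out as TIFF; the
    manifest records package version, config hash and seed for provenance.
    """
    from mdxquant import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config or {}),
        "files": [],
    }
    try:
        for name, df in (tables or {}).items():
            p = out_dir / f"{name}.csv"
            df.to_csv(p, index=False)
            manifest["files"].append(p.name)
        for name, arr in (masks or {}).items():
            p = out_dir / f"{name}.tif"
            tifffile.imwrite(str(p), np.asarray(arr))
            manifest["files"].append(p.name)
        for name, gj in (geojson or {}).items():
            p = out_dir / f"{name}.geojson"
            p.write_text(json.dumps(gj))
            manifest["files"].append(p.name)
        if scalars is not None:
            p = out_dir / "scalars.json"
            p.write_text(json.dumps(scalars, indent=2, default=float))
            manifest["files"].append(p.name)
    except OSError as exc:  # surface the offending path
        raise OSError(f"failed writing results under {out_dir}: {exc}") from exc
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
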