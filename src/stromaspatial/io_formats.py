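"""Readers and writers for the formats the pipeline touches.

Covers multi-channel TIFF images, per-cell measurement tables (a frozen
native CSV schema plus the QuPath tab-separated export dialect), stromal mask
polygons as GeoJSON, and the YAML run configuration.

Coordinate convention (shared with QuPath): lengths are in µm, the origin is
the image's top-left corner, x grows rightward and y downward, and pixel
(0, 0) covers the square ``[0, pixel_size) × [0, pixel_size)``.

Native cell-table schema
------------------------
Fixed columns: ``image_id, cell_id, centroid_x_um, centroid_y_um,
nucleus_area_um2, signed_distance_um, flags``.  Intensity features are stored
one per column as ``<compartment>:<channel-role>:<statistic>`` (e.g.
``nucleus:marker:max``); labels as ``label:<name>`` with values
``positive``/``negative``; any other column round-trips through
``CellRecord.metadata``.  Floats are written with ``repr`` so that
read(write(x)) is bit-exact.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml

from .cells import CellRecord

logger = logging.getLogger(__name__)

#: the four channel roles every analysis run needs
CHANNEL_ROLES = ("nuclei", "cytokeratin", "fibronectin", "marker")

#: default physical pixel size (µm) of the whole-slide scanner this pipeline
#: was designed around; used when TIFF metadata carries no resolution
DEFAULT_PIXEL_SIZE_UM = 0.3215

FIXED_COLUMNS = (
    "image_id", "cell_id", "centroid_x_um", "centroid_y_um",
    "nucleus_area_um2", "signed_distance_um", "flags",
)


class FormatError(ValueError):
    """Raised when an input file does not match its expected format."""


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

@dataclass
class ChannelMap:
    """Maps each channel role to a plane index in the TIFF stack."""

    nuclei: int
    cytokeratin: int
    fibronectin: int
    marker: int

    def __post_init__(self) -> None:
        idx = [self.nuclei, self.cytokeratin, self.fibronectin, self.marker]
        if len(set(idx)) != 4:
            raise FormatError("channel roles must map to four distinct planes")

    def as_dict(self) -> dict[str, int]:
        return {r: getattr(self, r) for r in CHANNEL_ROLES}


@dataclass
class MultiChannelImage:
    """Named 2-D intensity channels sharing one physical pixel size."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise FormatError("pixel_size_um must be positive")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise FormatError(f"channel shapes differ: {shapes}")
        for name, grid in self.channels.items():
            if grid.ndim != 2:
                raise FormatError(f"channel {name!r} is not a 2-D plane")
            if np.nanmin(grid) < 0:
                raise FormatError(f"channel {name!r} holds negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def read_image(path, channel_map: ChannelMap,
               pixel_size_um: float | None = None) -> MultiChannelImage:
    """Read a multi-plane TIFF into a role-named :class:`MultiChannelImage`.

    Pixel size is taken from TIFF resolution metadata when present, else from
    ``pixel_size_um``, else falls back to :data:`DEFAULT_PIXEL_SIZE_UM`.
    """
    path = str(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta_ps = _pixel_size_from_tiff(tif)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected 2-D planes, got array of shape {arr.shape}")
    # accept planes-first (C, Y, X) or samples-last (Y, X, C)
    if arr.shape[0] > 16 and arr.shape[-1] <= 16:
        arr = np.moveaxis(arr, -1, 0)
    channels = {}
    for role, idx in channel_map.as_dict().items():
        if idx >= arr.shape[0]:
            raise FormatError(
                f"{path}: role {role!r} maps to plane {idx} but the file has "
                f"only {arr.shape[0]} plane(s)"
            )
        channels[role] = np.asarray(arr[idx], dtype=float)
    ps = meta_ps or pixel_size_um or DEFAULT_PIXEL_SIZE_UM
    import os

    image_id = os.path.splitext(os.path.basename(path))[0]
    return MultiChannelImage(channels=channels, pixel_size_um=ps, image_id=image_id)


def write_image(image: MultiChannelImage, path,
                roles: tuple[str, ...] = CHANNEL_ROLES) -> None:
    """Write channels as a plane-per-channel TIFF with µm resolution tags."""
    stack = np.stack([image.channels[r] for r in roles]).astype(np.float32)
    px_per_cm = 1e4 / image.pixel_size_um
    tifffile.imwrite(
        str(path), stack, photometric="minisblack",
        resolution=(px_per_cm, px_per_cm), resolutionunit="CENTIMETER",
    )


def _pixel_size_from_tiff(tif: tifffile.TiffFile) -> float | None:
    # OME metadata wins; otherwise X/Y resolution tags in inch or cm
    if tif.ome_metadata:
        try:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tif.ome_metadata)
            for el in root.iter():
                if "PhysicalSizeX" in el.attrib:
                    return float(el.attrib["PhysicalSizeX"])
        except ET.ParseError:  # pragma: no cover - malformed OME block
            pass
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" in tags and "ResolutionUnit" in tags:
        unit = tags["ResolutionUnit"].value
        unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit))
        num, den = tags["XResolution"].value
        if unit_um and num:
            return unit_um * den / num
    return None


# ---------------------------------------------------------------------------
# cell tables
# ---------------------------------------------------------------------------

@dataclass
class QuPathDialect:
    """Header vocabulary of a QuPath measurement export.

    QuPath headers look like ``"Nucleus: CY5 max"``; the channel names are
    instrument-specific, so ``channel_to_role`` must translate them to the
    pipeline's roles.  The defaults match the four-channel panel this
    pipeline targets (DAPI / FITC / TRITC / CY5); override them for exports
    from other QuPath configurations.
    """

    channel_to_role: dict[str, str] = field(default_factory=lambda: {
        "DAPI": "nuclei", "FITC": "cytokeratin", "TRITC": "fibronectin",
        "CY5": "marker",
    })
    compartment_names: dict[str, str] = field(default_factory=lambda: {
        "Nucleus": "nucleus", "Cytoplasm": "cytoplasm", "Cell": "cell",
    })
    statistic_names: dict[str, str] = field(default_factory=lambda: {
        "mean": "mean", "median": "median", "min": "min", "max": "max",
        "std.dev.": "std", "std dev": "std",
    })
    centroid_x: str = "Centroid X µm"
    centroid_y: str = "Centroid Y µm"
    nucleus_area: str = "Nucleus: Area µm^2"
    image_col: str = "Image"
    id_col: str = "Object ID"

    def parse_feature(self, header: str):
        """Return ``(compartment, role, statistic)`` or None if not a feature."""
        if ":" not in header:
            return None
        comp_raw, rest = header.split(":", 1)
        comp = self.compartment_names.get(comp_raw.strip())
        if comp is None:
            return None
        parts = rest.strip().rsplit(" ", 1)
        if len(parts) != 2:
            return None
        channel, stat_raw = parts[0].strip(), parts[1].strip().lower()
        stat = self.statistic_names.get(stat_raw)
        role = self.channel_to_role.get(channel)
        if stat is None or role is None:
            return None
        return comp, role, stat


def read_cell_table(path, dialect: str = "native_csv",
                    qupath: QuPathDialect | None = None) -> list[CellRecord]:
    """Read a per-cell measurement table into :class:`CellRecord` objects.

    ``dialect`` is ``"native_csv"`` (this package's frozen schema) or
    ``"qupath_tsv"`` (QuPath measurement export, translated through a
    :class:`QuPathDialect` mapping table).
    """
    if dialect == "native_csv":
        return _read_native(path)
    if dialect == "qupath_tsv":
        return _read_qupath(path, qupath or QuPathDialect())
    raise FormatError(f"unknown cell-table dialect: {dialect!r}")


def _read_native(path) -> list[CellRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        warnings.warn(f"{path}: empty cell table", stacklevel=3)
        return []
    for col in ("centroid_x_um", "centroid_y_um"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing centroid column {col!r}")
    records = []
    feature_cols = {}
    for col in df.columns:
        if col in FIXED_COLUMNS or col.startswith(("label:", "meta:")):
            continue
        parts = col.split(":")
        if len(parts) != 3:
            raise FormatError(f"{path}: unrecognized column {col!r}")
        feature_cols[col] = tuple(parts)
    for i, row in df.iterrows():
        try:
            rec = CellRecord(
                image_id=str(row.get("image_id", "")),
                cell_id=int(row["cell_id"]) if "cell_id" in df.columns else int(i),
                centroid_x_um=float(row["centroid_x_um"]),
                centroid_y_um=float(row["centroid_y_um"]),
                nucleus_area_um2=float(row.get("nucleus_area_um2", np.nan)),
            )
            for col, key in feature_cols.items():
                rec.features[key] = float(row[col])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric value in row {i}: {exc}") from exc
        sd = row.get("signed_distance_um")
        if sd is not None and np.isfinite(sd):
            rec.signed_distance_um = float(sd)
        flags = row.get("flags")
        if isinstance(flags, str) and flags:
            rec.flags = flags.split(";")
        for col in df.columns:
            if col.startswith("label:"):
                val = row[col]
                if isinstance(val, str):
                    rec.labels[col[6:]] = val == "positive"
            elif col.startswith("meta:"):
                rec.metadata[col[5:]] = row[col]
        records.append(rec)
    return records


def _read_qupath(path, dialect: QuPathDialect) -> list[CellRecord]:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        warnings.warn(f"{path}: empty cell table", stacklevel=3)
        return []
    for col in (dialect.centroid_x, dialect.centroid_y):
        if col not in df.columns:
            raise FormatError(f"{path}: missing centroid column {col!r}")
    feature_cols = {}
    passthrough = []
    for col in df.columns:
        key = dialect.parse_feature(col)
        if key is not None:
            feature_cols[col] = key
        elif col not in (dialect.centroid_x, dialect.centroid_y,
                         dialect.nucleus_area, dialect.image_col, dialect.id_col):
            passthrough.append(col)
    records = []
    for i, row in df.iterrows():
        try:
            rec = CellRecord(
                image_id=str(row.get(dialect.image_col, "")),
                cell_id=i if dialect.id_col not in df.columns else _qupath_id(row[dialect.id_col], i),
                centroid_x_um=float(row[dialect.centroid_x]),
                centroid_y_um=float(row[dialect.centroid_y]),
                nucleus_area_um2=float(row.get(dialect.nucleus_area, np.nan)),
            )
            for col, key in feature_cols.items():
                rec.features[key] = float(row[col])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric value in row {i}: {exc}") from exc
        for col in passthrough:
            rec.metadata[col] = row[col]
        records.append(rec)
    return records


def _qupath_id(value, fallback: int) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        return int(fallback)


def write_cell_table(cells: list[CellRecord], path) -> None:
    """Write cells in the native CSV schema (bit-exact float round trip)."""
    rows = []
    for c in cells:
        row = {
            "image_id": c.image_id,
            "cell_id": c.cell_id,
            "centroid_x_um": c.centroid_x_um,
            "centroid_y_um": c.centroid_y_um,
            "nucleus_area_um2": c.nucleus_area_um2,
            "signed_distance_um": c.signed_distance_um,
            "flags": ";".join(c.flags),
        }
        for key, val in c.features.items():
            row[":".join(key)] = val
        for name, pos in c.labels.items():
            row[f"label:{name}"] = "positive" if pos else "negative"
        for name, val in c.metadata.items():
            row[f"meta:{name}"] = val
        rows.append(row)
    df = pd.DataFrame(rows)
    # repr is the shortest representation that round-trips a float exactly
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# mask polygons (GeoJSON)
# ---------------------------------------------------------------------------

def write_mask_polygons(mask: np.ndarray, pixel_size_um: float, path) -> None:
    """Write a binary mask as a GeoJSON FeatureCollection of µm polygons.

    One feature per connected stromal region (holes preserved).
    Re-rasterizing the polygons reproduces the mask except possibly along a
    one-pixel border band.  An empty mask yields a valid file with zero
    features.
    """
    polys = mask_to_polygons(mask, pixel_size_um)
    features = [
        {
            "type": "Feature",
            "geometry": json.loads(_geom_json(p)),
            "properties": {"object_type": "annotation", "classification": "Stroma"},
        }
        for p in polys
    ]
    doc = {"type": "FeatureCollection",
           "features": features,
           "metadata": {"pixel_size_um": pixel_size_um, "unit": "um"}}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def _geom_json(poly) -> str:
    import shapely

    return shapely.to_geojson(poly)


def mask_to_polygons(mask: np.ndarray, pixel_size_um: float) -> list:
    """Trace a binary mask into shapely polygons in µm coordinates."""
    from shapely.geometry import Polygon
    from skimage import measure

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    rings = []
    for c in contours:
        # (row, col) in padded pixel coords -> (x, y) in µm; pixel centers
        # sit at (index + 0.5) * pixel_size
        xy = np.column_stack([
            (c[:, 1] - 1 + 0.5) * pixel_size_um,
            (c[:, 0] - 1 + 0.5) * pixel_size_um,
        ])
        if len(xy) >= 4:
            rings.append(Polygon(xy))
    if not rings:
        return []
    rings.sort(key=lambda p: p.area, reverse=True)
    shells: list = []
    holes_for: dict[int, list] = {}
    for ring in rings:
        depth = sum(1 for other in rings
                    if other is not ring and other.area > ring.area
                    and other.contains(ring.representative_point()))
        if depth % 2 == 0:
            shells.append(ring)
            holes_for[len(shells) - 1] = []
        else:
            # hole: attach to the smallest shell containing it
            candidates = [i for i, s in enumerate(shells)
                          if s.contains(ring.representative_point())]
            if candidates:
                owner = min(candidates, key=lambda i: shells[i].area)
                holes_for[owner].append(ring.exterior.coords)
    out = []
    for i, shell in enumerate(shells):
        out.append(Polygon(shell.exterior.coords, holes_for.get(i, [])))
    return out


def read_mask_polygons(path, shape: tuple[int, int],
                       pixel_size_um: float) -> np.ndarray:
    """Rasterize a GeoJSON polygon file back onto a pixel grid."""
    from shapely.geometry import shape as shapely_shape

    with open(path) as fh:
        doc = json.load(fh)
    geoms = [shapely_shape(f["geometry"]) for f in doc.get("features", [])]
    return _rasterize_geoms(geoms, shape, pixel_size_um)


def _rasterize_geoms(geoms, shape: tuple[int, int],
                     pixel_size_um: float) -> np.ndarray:
    """Pixel-center containment rasterization of µm-space geometries."""
    import shapely

    out = np.zeros(shape, dtype=bool)
    if not geoms:
        return out
    ii, jj = np.mgrid[0:shape[0], 0:shape[1]]
    xs = (jj.ravel() + 0.5) * pixel_size_um
    ys = (ii.ravel() + 0.5) * pixel_size_um
    hit = np.zeros(xs.shape, dtype=bool)
    for g in geoms:
        hit |= shapely.contains_xy(g, xs, ys)
    return hit.reshape(shape)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: run configuration must be a mapping")
    return data


def dump_yaml(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
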