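"""Nucleus detection, cell-boundary approximation and per-cell feature extraction.

Whole-cell boundaries are approximated by radially expanding each nucleus by a
fixed distance (default 5 µm), the standard construction when no membrane
stain is available.  Where two expansions would overlap, each contested pixel
is assigned to the nucleus whose boundary is nearest (ties go to the lower
label id), so cells never overlap.  Intensity features (mean, median, min,
max, std) are then measured per subcellular compartment — nucleus, cytoplasm
(expansion ring) and whole cell — for every channel.

The nucleus segmenter shipped here is a classical pipeline (Gaussian blur,
global threshold, hole filling, distance-transform watershed, small-object
removal).  Label masks produced by external tools (e.g. a StarDist model run
elsewhere) can be imported instead via :func:`import_labels`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

#: compartments a cell is decomposed into; ``cell = nucleus ∪ cytoplasm``
COMPARTMENTS = ("nucleus", "cytoplasm", "cell")
#: per-compartment intensity statistics recorded for every channel
STATISTICS = ("mean", "median", "min", "max", "std")

FeatureKey = tuple[str, str, str]  # (compartment, channel-role, statistic)


class SegmentationError(ValueError):
    """Raised when a label mask or segmentation input is invalid."""


@dataclass
class LabelMask:
    """Integer label image: 0 = background, k > 0 = object k."""

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise SegmentationError("label mask must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise SegmentationError("label mask must be integer-typed")
        if self.pixel_size_um <= 0:
            raise SegmentationError("pixel_size_um must be positive")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class CellRecord:
    """One cell: centroid, nuclear area, intensity features, labels, distance.

    ``features`` maps ``(compartment, channel_role, statistic)`` to a value,
    e.g. ``("nucleus", "marker", "max")``.  ``labels`` maps a label name to
    True (positive) / False (negative).  ``signed_distance_um`` is negative
    inside the stromal mask, positive outside, and ``None`` until assigned.
    """

    image_id: str
    cell_id: int
    centroid_x_um: float
    centroid_y_um: float
    nucleus_area_um2: float
    features: dict[FeatureKey, float] = field(default_factory=dict)
    labels: dict[str, bool] = field(default_factory=dict)
    signed_distance_um: float | None = None
    flags: list[str] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    def feature(self, key: FeatureKey) -> float:
        return self.features[key]


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_nuclei(
    dapi: np.ndarray,
    pixel_size_um: float,
    *,
    sigma_um: float = 1.0,
    threshold: float | None = None,
    min_area_um2: float = 4.0,
    min_distance_um: float = 3.0,
) -> LabelMask:
    """Segment nuclei in a DAPI channel with a classical watershed pipeline.

    Steps: Gaussian blur (``sigma_um``), global threshold (Otsu when
    ``threshold`` is None), hole filling, distance-transform watershed seeded
    at local maxima at least ``min_distance_um`` apart (splits touching
    nuclei), and removal of objects below ``min_area_um2``.
    """
    dapi = np.asarray(dapi, dtype=float)
    if dapi.ndim != 2:
        raise SegmentationError("DAPI channel must be 2-D")
    if dapi.max() <= 0:
        warnings.warn("blank DAPI channel: no nuclei detected", stacklevel=2)
        return LabelMask(np.zeros(dapi.shape, dtype=np.int32), pixel_size_um)

    smoothed = gaussian(dapi, sigma=sigma_um / pixel_size_um, preserve_range=True)
    if threshold is None:
        threshold = float(threshold_otsu(smoothed))
    fg = ndimage.binary_fill_holes(smoothed > threshold)
    if not fg.any():
        warnings.warn("threshold above image maximum: no nuclei detected", stacklevel=2)
        return LabelMask(np.zeros(dapi.shape, dtype=np.int32), pixel_size_um)

    dist = ndimage.distance_transform_edt(fg)
    from skimage.feature import peak_local_max

    min_distance_px = max(1, int(round(min_distance_um / pixel_size_um)))
    peaks = peak_local_max(dist, min_distance=min_distance_px, labels=fg)
    markers = np.zeros(dapi.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    markers, _ = ndimage.label(markers > 0)
    lab = watershed(-dist, markers, mask=fg)

    min_area_px = min_area_um2 / pixel_size_um**2
    areas = np.bincount(lab.ravel())
    small = np.flatnonzero(areas < min_area_px)
    lab[np.isin(lab, small[small > 0])] = 0
    lab = _relabel(lab)
    return LabelMask(lab.astype(np.int32), pixel_size_um)


def _relabel(lab: np.ndarray) -> np.ndarray:
    ids = np.unique(lab)
    ids = ids[ids > 0]
    out = np.zeros_like(lab)
    for new, old in enumerate(ids, start=1):
        out[lab == old] = new
    return out


def import_labels(path, pixel_size_um: float) -> LabelMask:
    """Import an external segmentation (integer TIFF or GeoJSON polygons)."""
    path = str(path)
    if path.endswith((".json", ".geojson")):
        return _labels_from_geojson(path, pixel_size_um)
    arr = tifffile.imread(path)
    if not np.issubdtype(arr.dtype, np.integer):
        if np.allclose(arr, np.round(arr)):
            arr = arr.astype(np.int32)
        else:
            raise SegmentationError(f"{path}: label image must hold integers")
    return LabelMask(arr.astype(np.int32), pixel_size_um)


def _labels_from_geojson(path: str, pixel_size_um: float) -> LabelMask:
    from shapely.geometry import shape as shapely_shape

    with open(path) as fh:
        doc = json.load(fh)
    geoms = [shapely_shape(feat["geometry"]) for feat in doc.get("features", [])]
    if not geoms:
        raise SegmentationError(f"{path}: no polygon features")
    minx, miny, maxx, maxy = (
        min(g.bounds[0] for g in geoms),
        min(g.bounds[1] for g in geoms),
        max(g.bounds[2] for g in geoms),
        max(g.bounds[3] for g in geoms),
    )
    ny = int(np.ceil(maxy / pixel_size_um)) + 1
    nx = int(np.ceil(maxx / pixel_size_um)) + 1
    from .io_formats import _rasterize_geoms

    out = np.zeros((ny, nx), dtype=np.int32)
    for k, geom in enumerate(geoms, start=1):
        hit = _rasterize_geoms([geom], (ny, nx), pixel_size_um)
        overlap = (out > 0) & hit
        if overlap.any():
            ij = np.argwhere(overlap)[0]
            raise SegmentationError(
                f"{path}: overlapping polygons at pixel (row={ij[0]}, col={ij[1]})"
            )
        out[hit] = k
    return LabelMask(out, pixel_size_um)


# ---------------------------------------------------------------------------
# radial expansion
# ---------------------------------------------------------------------------

def expand_cells(
    nuclei: LabelMask, radius_um: float = 5.0
) -> tuple[LabelMask, LabelMask]:
    """Expand each nucleus radially by ``radius_um`` into non-overlapping cells.

    Returns ``(cell_mask, cytoplasm_mask)`` where the cytoplasm of cell *k* is
    its expanded region minus the nucleus.  A background pixel joins the cell
    whose nuclear boundary is nearest (Euclidean, exact), provided that
    distance is at most ``radius_um``; equidistant pixels go to the lower
    label id so the partition is deterministic.
    """
    if radius_um <= 0:
        raise SegmentationError("radius_um must be positive")
    ps = nuclei.pixel_size_um
    radius_px = int(round(radius_um / ps))
    if radius_px < 1:
        warnings.warn(
            f"expansion radius {radius_um} µm is below one pixel "
            f"({ps} µm): cytoplasm will be empty",
            stacklevel=2,
        )
    lab = nuclei.labels
    best_dist = np.full(lab.shape, np.inf)
    best_label = np.zeros(lab.shape, dtype=np.int32)

    objects = ndimage.find_objects(lab)
    pad = radius_px + 1
    for k, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        rows = slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, lab.shape[0]))
        cols = slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, lab.shape[1]))
        local = lab[rows, cols] == k
        # exact Euclidean distance to the nearest pixel of nucleus k
        d = ndimage.distance_transform_edt(~local)
        within = d <= radius_px
        sub_dist = best_dist[rows, cols]
        sub_lab = best_label[rows, cols]
        take = within & ((d < sub_dist) | ((d == sub_dist) & (k < sub_lab)))
        sub_dist[take] = d[take]
        sub_lab[take] = k
        best_dist[rows, cols] = sub_dist
        best_label[rows, cols] = sub_lab

    cell = best_label
    cell[lab > 0] = lab[lab > 0]  # nuclei always belong to their own cell
    cyto = cell.copy()
    cyto[lab > 0] = 0
    return LabelMask(cell, ps), LabelMask(cyto.astype(np.int32), ps)


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def extract_features(image, nuclei: LabelMask, cell: LabelMask, cytoplasm: LabelMask,
                     ) -> list[CellRecord]:
    """Measure per-compartment intensity statistics for every cell and channel.

    ``image`` is a :class:`~stromaspatial.io_formats.MultiChannelImage`; the
    three masks must be congruent with it.  Cells whose cytoplasm is empty get
    NaN statistics for that compartment and a ``"empty:cytoplasm"`` flag.
    """
    ps = nuclei.pixel_size_um
    shape = nuclei.labels.shape
    for name, m in (("cell", cell), ("cytoplasm", cytoplasm)):
        if m.labels.shape != shape:
            raise SegmentationError(f"{name} mask shape differs from nucleus mask")
    for cname, grid in image.channels.items():
        if grid.shape != shape:
            raise SegmentationError(f"channel {cname!r} shape differs from masks")

    ids = nuclei.ids()
    records: list[CellRecord] = []
    masks = {"nucleus": nuclei.labels, "cytoplasm": cytoplasm.labels,
             "cell": cell.labels}
    # centroid and area from the nucleus mask
    centroids = ndimage.center_of_mass(np.ones(shape), nuclei.labels, ids)
    areas = ndimage.sum_labels(np.ones(shape), nuclei.labels, ids)

    # per-compartment: flat pixel indices grouped by label via one argsort
    indices: dict[str, dict[int, np.ndarray]] = {}
    for comp, m in masks.items():
        flat = m.ravel()
        order = np.argsort(flat, kind="stable")
        sorted_labels = flat[order]
        starts = np.searchsorted(sorted_labels, ids, side="left")
        stops = np.searchsorted(sorted_labels, ids, side="right")
        indices[comp] = {int(k): order[a:b] for k, a, b in zip(ids, starts, stops)}

    for i, k in enumerate(ids):
        cy, cx = centroids[i]
        rec = CellRecord(
            image_id=image.image_id,
            cell_id=int(k),
            centroid_x_um=(cx + 0.5) * ps,
            centroid_y_um=(cy + 0.5) * ps,
            nucleus_area_um2=float(areas[i]) * ps**2,
        )
        for comp in masks:
            idx = indices[comp][int(k)]
            for role, grid in image.channels.items():
                if idx.size == 0:
                    for stat in STATISTICS:
                        rec.features[(comp, role, stat)] = float("nan")
                    continue
                vals = grid.ravel()[idx]
                rec.features[(comp, role, "mean")] = float(vals.mean())
                rec.features[(comp, role, "median")] = float(np.median(vals))
                rec.features[(comp, role, "min")] = float(vals.min())
                rec.features[(comp, role, "max")] = float(vals.max())
                rec.features[(comp, role, "std")] = float(vals.std())
            if idx.size == 0:
                rec.flags.append(f"empty:{comp}")
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

def filter_by_nuclear_area(
    cells: list[CellRecord], low_pct: float = 5.0, high_pct: float = 99.0
) -> list[CellRecord]:
    """Drop cells whose nuclear area falls strictly outside per-image percentiles.

    Percentiles are linearly interpolated and computed separately for each
    image.  A cell is discarded only if its area is strictly smaller than the
    ``low_pct`` percentile or strictly larger than the ``high_pct``
    percentile; boundary-equal areas are kept.
    """
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    if len(cells) < 2:
        raise ValueError("need at least two cells to compute area percentiles")
    by_image: dict[str, list[CellRecord]] = {}
    for c in cells:
        by_image.setdefault(c.image_id, []).append(c)
    kept: list[CellRecord] = []
    for image_id, group in by_image.items():
        areas = np.array([c.nucleus_area_um2 for c in group])
        lo, hi = np.percentile(areas, [low_pct, high_pct])
        keep = [c for c, a in zip(group, areas) if lo <= a <= hi]
        logger.info(
            "area filter %s: kept %d of %d cells (bounds %.3f–%.3f µm²)",
            image_id, len(keep), len(group), lo, hi,
        )
        kept.extend(keep)
    if not kept:
        raise ValueError("nuclear-area filter removed every cell")
    return kept
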