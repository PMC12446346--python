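"""Synthetic phantoms with known ground truth for every pipeline stage.

Real inputs are gigapixel whole-slide scans; testing the pipeline's
statistical machinery does not need them.  The phantoms here provide the
three properties the downstream stages actually consume:

* a stromal region with known geometry (vertical band, annulus or random
  blobs), so true signed distances are known analytically or from the mask;
* per-cell marker intensities drawn log-normal with the distance effect
  entering the *log-location* — a multiplicative intensity effect, the
  regime real fluorescence batches live in;
* per-image multiplicative batch scales c, for which percentile mapping has
  the exact closed-form answer t_j = c_j · t_ref, enabling exact
  parameter-recovery tests.

Two generators are provided: full four-channel images with matched ground
truth (:func:`generate_phantom_image`), and measurement-table-only batches
at arbitrary cell counts (:func:`generate_cell_table_batch`).  All output is
deterministic under a fixed seed.

Default geometry: 512 × 512 px at 1.286 µm/px (the 0.3215 µm scanner pixel
scaled up 4×, so ~300 cells and a 5 µm expansion stay resolvable at phantom
size) with a vertical stromal band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .cells import CellRecord, FeatureKey
from .io_formats import MultiChannelImage

#: reference marker feature the table phantom populates
DEFAULT_MARKER_FEATURE: FeatureKey = ("cell", "marker", "max")
DEFAULT_KER_FEATURE: FeatureKey = ("cytoplasm", "cytokeratin", "median")

#: fraction of the baseline marker distribution that defines the generating
#: positivity threshold (top 10% of the reference distribution)
TRUE_POSITIVE_QUANTILE = 0.90


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap."""


def g_none(d):
    return np.zeros_like(np.asarray(d, dtype=float))


def g_peak(d, amplitude: float = 1.0, width_um: float = 30.0):
    """Log-location bump centred on the stromal border (d = 0)."""
    d = np.asarray(d, dtype=float)
    return amplitude * np.exp(-(d**2) / (2.0 * width_um**2))


def g_decreasing(d, slope_per_um: float = 0.01):
    """Log-location falling linearly with signed distance."""
    return -slope_per_um * np.asarray(d, dtype=float)


DISTANCE_EFFECTS = {"none": g_none, "peak": g_peak, "decreasing": g_decreasing}


@dataclass
class PhantomConfig:
    """All knobs of the phantom generators.

    ``marker_mu`` and ``marker_sigma`` are the baseline log-scale location
    and spread of the marker intensity; the distance effect g(d) is *added*
    to the log-location; ``batch_scale`` multiplies the resulting intensity.
    """

    image_size_px: int = 512
    pixel_size_um: float = 0.3215 * 4
    stroma_geometry: str = "band"           # band | annulus | blobs
    band_frac: tuple[float, float] = (0.35, 0.65)  # x extent of the band
    annulus_frac: tuple[float, float] = (0.18, 0.32)
    n_blobs: int = 5
    blob_radius_frac: float = 0.12
    n_cells: int = 300
    nucleus_radius_um_mean: float = 3.5
    nucleus_radius_um_sd: float = 0.5
    marker_mu: float = 5.0
    marker_sigma: float = 0.5
    distance_effect: str = "peak"
    effect_params: dict = field(default_factory=dict)
    batch_scale: float = 1.0
    noise_sd: float = 2.0
    cancer_fraction: float = 0.7
    fibronectin_amplitude: float = 150.0
    fibronectin_sigma_px: float = 2.0
    dapi_amplitude: float = 200.0
    ker_high: float = 150.0
    ker_low: float = 20.0
    table_distance_range_um: tuple[float, float] = (-50.0, 250.0)
    marker_feature: FeatureKey = DEFAULT_MARKER_FEATURE
    seed: int = 0
    allow_empty: bool = False

    def __post_init__(self) -> None:
        if self.n_cells <= 0 and not self.allow_empty:
            raise ValueError("n_cells must be positive (or set allow_empty)")
        if self.marker_sigma <= 0:
            raise ValueError("marker_sigma must be positive")
        if self.batch_scale <= 0:
            raise ValueError("batch_scale must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.stroma_geometry not in ("band", "annulus", "blobs"):
            raise ValueError(f"unknown stroma geometry {self.stroma_geometry!r}")
        if self.distance_effect not in DISTANCE_EFFECTS:
            raise ValueError(f"unknown distance effect {self.distance_effect!r}")

    def g(self, d):
        return DISTANCE_EFFECTS[self.distance_effect](d, **self.effect_params)

    @property
    def true_reference_threshold(self) -> float:
        """Generating positivity threshold of the *baseline* (c = 1) image.

        The top-``(1 − q)`` quantile of log-normal(marker_mu, marker_sigma);
        image k's true threshold is ``batch_scale_k`` times this value.
        """
        from scipy import stats

        return float(stats.lognorm(self.marker_sigma,
                                   scale=math.exp(self.marker_mu)
                                   ).ppf(TRUE_POSITIVE_QUANTILE))


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    stroma_mask: np.ndarray | None = None
    true_distance_um: np.ndarray | None = None
    is_cancer: np.ndarray | None = None
    marker_values: np.ndarray | None = None
    marker_positive: np.ndarray | None = None
    scale: float = 1.0
    true_threshold: float = float("nan")
    centers_px: np.ndarray | None = None
    nucleus_radii_px: np.ndarray | None = None


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _stroma_mask_and_distance(config: PhantomConfig, rng: np.random.Generator):
    """Build the truth mask and an analytic signed-distance function (µm)."""
    n = config.image_size_px
    ps = config.pixel_size_um
    yy, xx = np.mgrid[0:n, 0:n]
    # pixel centers in µm
    xc = (xx + 0.5) * ps
    yc = (yy + 0.5) * ps
    size_um = n * ps
    if config.stroma_geometry == "band":
        x0, x1 = (f * size_um for f in config.band_frac)
        mask = (xc >= x0) & (xc < x1)

        def signed_distance(px_um, py_um):
            px_um = np.asarray(px_um, dtype=float)
            inside = (px_um >= x0) & (px_um < x1)
            d_in = -np.minimum(px_um - x0, x1 - px_um)
            d_out = np.maximum(x0 - px_um, px_um - x1)
            return np.where(inside, d_in, d_out)

        return mask, signed_distance
    if config.stroma_geometry == "annulus":
        r0, r1 = (f * size_um for f in config.annulus_frac)
        cx = cy = size_um / 2.0
        rr = np.hypot(xc - cx, yc - cy)
        mask = (rr >= r0) & (rr < r1)

        def signed_distance(px_um, py_um):
            r = np.hypot(np.asarray(px_um) - cx, np.asarray(py_um) - cy)
            inside = (r >= r0) & (r < r1)
            d_in = -np.minimum(r - r0, r1 - r)
            d_out = np.where(r < r0, r0 - r, r - r1)
            return np.where(inside, d_in, d_out)

        return mask, signed_distance
    # random blobs: no closed form; distances come from the exact EDT
    mask = np.zeros((n, n), dtype=bool)
    radius = config.blob_radius_frac * n
    for _ in range(config.n_blobs):
        bx, by = rng.uniform(radius, n - radius, size=2)
        mask |= (xx - bx) ** 2 + (yy - by) ** 2 <= radius**2
    outside = ndimage.distance_transform_edt(~mask) * ps
    inside = ndimage.distance_transform_edt(mask) * ps
    signed = np.where(mask, -inside, outside)

    def signed_distance(px_um, py_um):
        j = np.clip((np.asarray(px_um) / ps).astype(int), 0, n - 1)
        i = np.clip((np.asarray(py_um) / ps).astype(int), 0, n - 1)
        return signed[i, j]

    return mask, signed_distance


def _place_cells(config: PhantomConfig, rng: np.random.Generator):
    """Rejection-sample non-overlapping nucleus centers; bounded retries."""
    n = config.image_size_px
    ps = config.pixel_size_um
    radii_px = np.maximum(
        rng.normal(config.nucleus_radius_um_mean, config.nucleus_radius_um_sd,
                   config.n_cells) / ps,
        1.5,
    )
    margin = radii_px.max() + 2
    centers: list[tuple[float, float]] = []
    max_tries = 200 * config.n_cells
    tries = 0
    placed_r: list[float] = []
    while len(centers) < config.n_cells:
        if tries >= max_tries:
            raise PlacementError(
                f"placed only {len(centers)} of {config.n_cells} cells after "
                f"{max_tries} tries; lower the cell density or image size"
            )
        tries += 1
        x = rng.uniform(margin, n - margin)
        y = rng.uniform(margin, n - margin)
        r = radii_px[len(centers)]
        ok = True
        for (px, py), pr in zip(centers, placed_r):
            if (x - px) ** 2 + (y - py) ** 2 < (r + pr + 1.0) ** 2:
                ok = False
                break
        if ok:
            centers.append((x, y))
            placed_r.append(r)
    return np.array(centers), radii_px


def _paint_disks(shape, centers, radii, values):
    img = np.zeros(shape, dtype=float)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (cx, cy), r, v in zip(centers, radii, values):
        sl = (slice(max(int(cy - r) - 1, 0), min(int(cy + r) + 2, shape[0])),
              slice(max(int(cx - r) - 1, 0), min(int(cx + r) + 2, shape[1])))
        disk = (xx[sl] - cx) ** 2 + (yy[sl] - cy) ** 2 <= r**2
        img[sl][disk] = v
    return img


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_phantom_image(
    config: PhantomConfig, image_id: str = "phantom",
) -> tuple[MultiChannelImage, GroundTruth]:
    """Generate one four-channel phantom image with matched ground truth.

    Channels: DAPI (nucleus disks), fibronectin (smoothed stroma mask ×
    amplitude), cytokeratin (high on the designated cancer subset), marker
    (per-cell disks at the drawn log-normal intensity).  Gaussian noise of
    ``noise_sd`` is added everywhere and clipped at zero.  Byte-identical
    under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.image_size_px
    ps = config.pixel_size_um
    mask, signed_distance = _stroma_mask_and_distance(config, rng)

    if config.n_cells == 0:
        zero = np.zeros((n, n), dtype=float)
        image = MultiChannelImage(
            channels={r: zero.copy() for r in
                      ("nuclei", "cytokeratin", "fibronectin", "marker")},
            pixel_size_um=ps, image_id=image_id)
        return image, GroundTruth(stroma_mask=mask, scale=config.batch_scale)

    centers, radii_px = _place_cells(config, rng)
    cx_um = centers[:, 0] * ps
    cy_um = centers[:, 1] * ps
    d_true = signed_distance(cx_um, cy_um)

    is_cancer = rng.random(config.n_cells) < config.cancer_fraction
    z = rng.standard_normal(config.n_cells)
    marker = config.batch_scale * np.exp(
        config.marker_mu + config.g(d_true) + config.marker_sigma * z
    )
    t_true = config.batch_scale * config.true_reference_threshold

    dapi = _paint_disks((n, n), centers, radii_px,
                        np.full(config.n_cells, config.dapi_amplitude))
    cyto_radii = radii_px + 3.0
    ker = _paint_disks((n, n), centers, cyto_radii,
                       np.where(is_cancer, config.ker_high, config.ker_low))
    mk = _paint_disks((n, n), centers, cyto_radii, marker)
    fib = ndimage.gaussian_filter(
        mask.astype(float) * config.fibronectin_amplitude,
        config.fibronectin_sigma_px,
    )
    channels = {}
    for name, base in (("nuclei", dapi), ("cytokeratin", ker),
                       ("fibronectin", fib), ("marker", mk)):
        noisy = base + rng.normal(0.0, config.noise_sd, size=base.shape)
        channels[name] = np.clip(noisy, 0.0, None)

    image = MultiChannelImage(channels=channels, pixel_size_um=ps,
                              image_id=image_id)
    truth = GroundTruth(
        stroma_mask=mask,
        true_distance_um=d_true,
        is_cancer=is_cancer,
        marker_values=marker,
        marker_positive=marker > t_true,
        scale=config.batch_scale,
        true_threshold=t_true,
        centers_px=centers,
        nucleus_radii_px=radii_px,
    )
    return image, truth


def generate_cell_table_batch(
    config: PhantomConfig,
    n_images: int,
    scales: list[float] | None = None,
) -> tuple[dict[str, list[CellRecord]], dict[str, GroundTruth]]:
    """Generate a batch of per-image cell tables without rendering images.

    Image k's marker feature values are ``c_k × exp(mu + g(d) + sigma·z)``
    with cell distances drawn uniformly over ``table_distance_range_um``, so
    the ground-truth positivity threshold of image k is exactly ``c_k``
    times the reference threshold.  Returns ``(tables, truths)`` keyed by
    image id (``image_1`` … ``image_<n>``).
    """
    if n_images < 1:
        raise ValueError("n_images must be at least 1")
    if scales is None:
        scales = [config.batch_scale] * n_images
    if len(scales) != n_images:
        raise ValueError("scales must have one entry per image")
    master = np.random.default_rng(config.seed)
    tables: dict[str, list[CellRecord]] = {}
    truths: dict[str, GroundTruth] = {}
    t_ref = config.true_reference_threshold
    lo, hi = config.table_distance_range_um
    for k, c in enumerate(scales, start=1):
        image_id = f"image_{k}"
        rng = np.random.default_rng(master.integers(2**31))
        d = rng.uniform(lo, hi, config.n_cells)
        z = rng.standard_normal(config.n_cells)
        marker = c * np.exp(config.marker_mu + config.g(d)
                            + config.marker_sigma * z)
        is_cancer = rng.random(config.n_cells) < config.cancer_fraction
        ker = np.where(
            is_cancer,
            rng.lognormal(math.log(config.ker_high), 0.3, config.n_cells),
            rng.lognormal(math.log(config.ker_low), 0.3, config.n_cells),
        )
        area = rng.normal(math.pi * config.nucleus_radius_um_mean**2,
                          10.0, config.n_cells).clip(5.0)
        cells = []
        for i in range(config.n_cells):
            rec = CellRecord(
                image_id=image_id,
                cell_id=i + 1,
                centroid_x_um=float(rng.uniform(0, 1000)),
                centroid_y_um=float(rng.uniform(0, 1000)),
                nucleus_area_um2=float(area[i]),
                signed_distance_um=float(d[i]),
            )
            rec.features[config.marker_feature] = float(marker[i])
            rec.features[DEFAULT_KER_FEATURE] = float(ker[i])
            cells.append(rec)
        tables[image_id] = cells
        truths[image_id] = GroundTruth(
            true_distance_um=d,
            is_cancer=is_cancer,
            marker_values=marker,
            marker_positive=marker > c * t_ref,
            scale=c,
            true_threshold=c * t_ref,
        )
    return tables, truths


def phantom_batch_configs(config: PhantomConfig, scales: list[float]
                          ) -> list[PhantomConfig]:
    """Per-image configs for an image batch with given scales and seeds."""
    master = np.random.default_rng(config.seed)
    return [
        replace(config, batch_scale=c, seed=int(master.integers(2**31)))
        for c in scales
    ]
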