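"""Threshold calibration across images by percentile mapping.

Staining and acquisition differences shift per-image intensity distributions,
so one absolute classification threshold is not portable across a batch.
This module fits a pool of non-negative continuous distributions (log-normal,
Wald, Burr, beta, gamma) to each image's feature histogram, then translates
an expert threshold t_ref chosen on a reference image *i* to every other
image *j* by preserving its percentile rank:

    t_j = F_j^{-1}(F_i(t_ref))

where F is the fitted CDF.  When the batch effect is a pure multiplicative
intensity scale c (log-normal location shifted by ln c), the mapped threshold
is exactly c·t_ref, which is what parameter-recovery tests exploit.

Parameters are estimated per family by maximum likelihood with the location
pinned at zero (the distributions model non-negative intensities); the beta
family keeps a free scale so its support covers the observed range.  Family
*selection* uses the least-squares criterion: the sum over histogram bins of
squared differences between the density-normalized histogram and the fitted
pdf at bin centers.  Direct top-N% empirical thresholds are also provided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cells import CellRecord, FeatureKey

logger = logging.getLogger(__name__)

#: candidate families: name -> (scipy distribution, fixed fit kwargs)
FAMILIES: dict[str, tuple] = {
    "lognormal": (stats.lognorm, {"floc": 0}),
    "wald": (stats.wald, {"floc": 0}),
    "burr": (stats.burr, {"floc": 0}),
    "beta": (stats.beta, {"floc": 0}),
    "gamma": (stats.gamma, {"floc": 0}),
}

DEFAULT_N_BINS = 200  # histogram bins used for the least-squares score


class FitError(ValueError):
    """Raised when no candidate distribution can be fitted."""


@dataclass
class DistributionFit:
    """Best-fit non-negative distribution for one image/feature.

    Carries the frozen CDF / inverse-CDF pair used for percentile mapping,
    the least-squares score of the winning family and the scores of every
    candidate that converged.
    """

    family: str
    params: tuple[float, ...]
    sse: float
    sse_by_family: dict[str, float]
    n_bins: int
    n_values: int
    value_range: tuple[float, float]

    def _frozen(self):
        dist, _ = FAMILIES[self.family]
        return dist(*self.params)

    def cdf(self, x):
        return self._frozen().cdf(x)

    def ppf(self, q):
        return self._frozen().ppf(q)

    def pdf(self, x):
        return self._frozen().pdf(x)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": list(self.params),
            "sse": self.sse,
            "sse_by_family": self.sse_by_family,
            "n_bins": self.n_bins,
            "n_values": self.n_values,
            "value_range": list(self.value_range),
        }


@dataclass
class ThresholdSet:
    """Per-image thresholds mapped from one reference threshold."""

    reference_image_id: str
    feature_key: FeatureKey
    t_ref: float
    thresholds: dict[str, float]
    fits: dict[str, DistributionFit] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "reference_image_id": self.reference_image_id,
            "feature_key": list(self.feature_key),
            "t_ref": self.t_ref,
            "thresholds": self.thresholds,
            "fits": {k: f.to_dict() for k, f in self.fits.items()},
            "excluded": self.excluded,
        }


def fit_distribution(
    values,
    n_bins: int = DEFAULT_N_BINS,
    families: tuple[str, ...] = tuple(FAMILIES),
) -> DistributionFit:
    """Fit candidate families to a sample and keep the least-squares winner.

    Each family is fitted by MLE, then scored by the SSE between the
    density-normalized histogram (``n_bins`` equal-width bins) and the fitted
    pdf evaluated at bin centers.  Families that fail to converge are skipped
    with a warning; the fit with minimal SSE wins.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 100:
        raise FitError(f"need at least 100 finite values, got {values.size}")
    if (values < 0).any():
        raise FitError("values must be non-negative")
    if n_bins < 10:
        raise FitError("need at least 10 histogram bins")
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise FitError("degenerate sample: all values identical")

    density, edges = np.histogram(values, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    sse_by_family: dict[str, float] = {}
    params_by_family: dict[str, tuple[float, ...]] = {}
    for name in families:
        if name not in FAMILIES:
            raise FitError(f"unknown family {name!r}; choose from {sorted(FAMILIES)}")
        dist, fixed = FAMILIES[name]
        try:
            with warnings.catch_warnings(), np.errstate(all="ignore"):
                warnings.simplefilter("ignore")
                params = dist.fit(values, **fixed)
                pdf = dist(*params).pdf(centers)
            sse = float(np.sum((density - pdf) ** 2))
            if not np.isfinite(sse):
                raise ValueError("non-finite SSE")
        except Exception as exc:  # family-level failure is not fatal
            warnings.warn(f"family {name!r} failed to fit: {exc}", stacklevel=2)
            continue
        sse_by_family[name] = sse
        params_by_family[name] = tuple(float(p) for p in params)
    if not sse_by_family:
        raise FitError("no candidate family converged")
    best = min(sse_by_family, key=sse_by_family.get)
    return DistributionFit(
        family=best,
        params=params_by_family[best],
        sse=sse_by_family[best],
        sse_by_family=sse_by_family,
        n_bins=n_bins,
        n_values=int(values.size),
        value_range=(vmin, vmax),
    )


def map_threshold(fit_src: DistributionFit, fit_dst: DistributionFit,
                  t_src: float) -> float:
    """Translate a threshold between two fitted distributions.

    Returns ``t_dst = F_dst^{-1}(F_src(t_src))``, the value holding the same
    percentile rank under the destination fit as ``t_src`` holds under the
    source fit.
    """
    p = float(fit_src.cdf(t_src))
    if p <= 0.0 or p >= 1.0:
        raise ValueError(
            f"threshold {t_src} sits at CDF {p} of the source fit: "
            "tail percentiles cannot be mapped"
        )
    return float(fit_dst.ppf(p))


def propagate_thresholds(
    tables_by_image: dict[str, object],
    feature: FeatureKey,
    reference_image: str,
    t_ref: float,
    n_bins: int = DEFAULT_N_BINS,
    families: tuple[str, ...] = tuple(FAMILIES),
) -> ThresholdSet:
    """Map a reference threshold onto every image of a batch.

    ``tables_by_image`` maps image id to either a list of
    :class:`CellRecord` or a 1-D array of feature values.  Images with fewer
    than 100 values are excluded with a warning; the reference image's own
    threshold is ``t_ref`` by construction.
    """
    if reference_image not in tables_by_image:
        raise ValueError(f"reference image {reference_image!r} not in batch")
    values_by_image: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for image_id, table in tables_by_image.items():
        vals = _feature_values(table, feature)
        if vals.size < 100:
            warnings.warn(
                f"image {image_id!r} excluded: only {vals.size} cells", stacklevel=2
            )
            excluded.append(image_id)
            continue
        values_by_image[image_id] = vals
    if reference_image not in values_by_image:
        raise ValueError(f"reference image {reference_image!r} has too few cells")

    fits = {
        image_id: fit_distribution(vals, n_bins=n_bins, families=families)
        for image_id, vals in values_by_image.items()
    }
    ref_fit = fits[reference_image]
    thresholds = {}
    for image_id, fit in fits.items():
        if image_id == reference_image:
            thresholds[image_id] = float(t_ref)
        else:
            thresholds[image_id] = map_threshold(ref_fit, fit, t_ref)
    logger.info("propagated t_ref=%.6g from %s to %d images",
                t_ref, reference_image, len(thresholds) - 1)
    return ThresholdSet(
        reference_image_id=reference_image,
        feature_key=feature,
        t_ref=float(t_ref),
        thresholds=thresholds,
        fits=fits,
        excluded=excluded,
    )


def percentile_threshold(values, top_fraction: float) -> float:
    """Empirical threshold marking the top ``top_fraction`` of a sample.

    Returns the linearly interpolated ``1 - top_fraction`` quantile; a value
    is called positive when strictly above the threshold, so on continuous
    data ``round(n * top_fraction)`` values land above it.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("cannot take a percentile of an empty sample")
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must lie strictly between 0 and 1")
    return float(np.quantile(values, 1.0 - top_fraction))


def _feature_values(table, feature: FeatureKey) -> np.ndarray:
    if isinstance(table, (list, tuple)) and table and isinstance(table[0], CellRecord):
        vals = np.array([c.features[feature] for c in table], dtype=float)
    else:
        vals = np.asarray(table, dtype=float)
    return vals[np.isfinite(vals)]
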