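"""Sensitivity of spatial results to the stroma-mask parameters.

The stromal mask depends on two tunables — the Gaussian smoothing sigma and
the fibronectin intensity threshold.  This module grid-searches both: for
every (σ, t) combination it rebuilds the mask, recomputes signed distances,
and recomputes the Pearson correlation between marker intensity and distance
separately for cells inside and outside the stroma, per image.  Because both
correlations of a pair come from the same image under identical conditions,
inside-vs-outside differences are tested with a two-sided Wilcoxon
signed-rank test (exact null enumeration up to n = 25 pairs, normal
approximation above), and per-side means are summarized with a bootstrap
across images (default 500 iterations).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cells import CellRecord, FeatureKey
from .spatial import correlation_by_side
from .stroma import BorderError, assign_cell_distances, build_stroma_mask, \
    signed_distance_map

logger = logging.getLogger(__name__)

EXACT_WILCOXON_MAX_N = 25  # exact null enumeration up to this many pairs


@dataclass
class GridPoint:
    """Results of one (sigma, threshold) combination."""

    sigma: float
    threshold: float
    r_inside: dict[str, float]
    r_outside: dict[str, float]
    median_r_inside: float = float("nan")
    median_r_outside: float = float("nan")
    p_value: float = float("nan")
    boot_inside: tuple[float, float] = (float("nan"), float("nan"))
    boot_outside: tuple[float, float] = (float("nan"), float("nan"))
    flagged: bool = False
    note: str = ""


@dataclass
class SensitivityResult:
    """Grid of (sigma, threshold) points with per-image correlations."""

    points: list[GridPoint]
    image_ids: list[str]
    overall_p_value: float = float("nan")
    n_pairs: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (sigma, threshold, image, side)."""
        rows = []
        for pt in self.points:
            for image_id in self.image_ids:
                for side, rs in (("inside", pt.r_inside), ("outside", pt.r_outside)):
                    rows.append({
                        "sigma": pt.sigma, "threshold": pt.threshold,
                        "image_id": image_id, "side": side,
                        "r": rs.get(image_id, float("nan")),
                        "flagged": pt.flagged,
                    })
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "overall_p_value": self.overall_p_value,
            "n_pairs": self.n_pairs,
            "points": [
                {
                    "sigma": pt.sigma, "threshold": pt.threshold,
                    "median_r_inside": pt.median_r_inside,
                    "median_r_outside": pt.median_r_outside,
                    "p_value": pt.p_value,
                    "boot_inside_mean": pt.boot_inside[0],
                    "boot_inside_se": pt.boot_inside[1],
                    "boot_outside_mean": pt.boot_outside[0],
                    "boot_outside_se": pt.boot_outside[1],
                    "flagged": pt.flagged, "note": pt.note,
                }
                for pt in self.points
            ],
        }


def run_grid(
    images: list[tuple],
    sigmas: list[float],
    thresholds: list[float],
    feature_key: FeatureKey,
    sigma_units: str = "um",
    n_boot: int = 500,
    seed: int | None = None,
) -> SensitivityResult:
    """Evaluate side-wise correlations over a (sigma, threshold) grid.

    ``images`` is a list of ``(MultiChannelImage, cells)`` pairs.  A grid
    point whose mask comes out empty or full on any image is flagged rather
    than fatal.  Per-point statistics pair (r_inside, r_outside) across
    images; the overall Wilcoxon p-value pools pairs across all grid points.
    """
    if not images:
        raise ValueError("need at least one image")
    if not sigmas or not thresholds:
        raise ValueError("sigma and threshold lists must be non-empty")
    image_ids = [img.image_id for img, _ in images]
    points: list[GridPoint] = []
    pooled_pairs: list[tuple[float, float]] = []
    rng = np.random.default_rng(seed)
    for sigma in sigmas:
        for thr in thresholds:
            r_in: dict[str, float] = {}
            r_out: dict[str, float] = {}
            flagged = False
            note = ""
            for img, cells in images:
                mask = _quiet_mask(img.channels["fibronectin"], sigma, thr,
                                   img.pixel_size_um, sigma_units)
                try:
                    dmap = signed_distance_map(mask)
                except BorderError:
                    flagged = True
                    note = f"empty or full mask on image {img.image_id!r}"
                    continue
                assign_cell_distances(cells, dmap)
                ri, ro = correlation_by_side(cells, feature_key)
                r_in[img.image_id] = ri
                r_out[img.image_id] = ro
            pt = GridPoint(sigma=sigma, threshold=thr, r_inside=r_in,
                           r_outside=r_out, flagged=flagged, note=note)
            pairs = [(r_in[i], r_out[i]) for i in r_in
                     if i in r_out and np.isfinite(r_in[i]) and np.isfinite(r_out[i])]
            if pairs:
                ins, outs = map(np.asarray, zip(*pairs))
                pt.median_r_inside = float(np.median(ins))
                pt.median_r_outside = float(np.median(outs))
                pooled_pairs.extend(pairs)
                diffs = ins - outs
                if len(diffs) >= 5 and np.any(diffs != 0):
                    pt.p_value = paired_wilcoxon(diffs)
                if len(ins) >= 2:
                    pt.boot_inside = bootstrap_mean_se(
                        ins, n_boot=n_boot, seed=int(rng.integers(2**31)))
                    pt.boot_outside = bootstrap_mean_se(
                        outs, n_boot=n_boot, seed=int(rng.integers(2**31)))
            points.append(pt)
    result = SensitivityResult(points=points, image_ids=image_ids)
    if pooled_pairs:
        ins, outs = map(np.asarray, zip(*pooled_pairs))
        diffs = ins - outs
        result.n_pairs = len(diffs)
        if len(diffs) >= 5 and np.any(diffs != 0):
            result.overall_p_value = paired_wilcoxon(diffs)
    return result


def _quiet_mask(channel, sigma, threshold, pixel_size_um, sigma_units):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_stroma_mask(channel, sigma, threshold, pixel_size_um,
                                 sigma_units=sigma_units)


# ---------------------------------------------------------------------------
# paired Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def paired_wilcoxon(x, y=None) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired data.

    Pass differences directly, or two paired samples.  Zero differences are
    dropped before ranking and tied magnitudes receive mid-ranks.  For up to
    25 non-zero pairs the p-value comes from exact enumeration of the
    signed-rank null (every sign pattern equally likely); larger samples use
    the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    diffs = x - np.asarray(y, dtype=float) if y is not None else x
    if diffs.size < 5:
        raise ValueError("need at least 5 pairs")
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        raise ValueError("all paired differences are zero")
    ranks = _midranks(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    n = diffs.size
    if n <= EXACT_WILCOXON_MAX_N:
        return _exact_signed_rank_p(ranks, w_plus)
    return _normal_signed_rank_p(ranks, w_plus)


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j < len(values) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j + 1)  # mid-rank of the tie block
        i = j
    return ranks


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    # W+ distribution under the null by convolution over doubled ranks
    # (doubling makes mid-ranks integral)
    doubled = np.round(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: len(counts) - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _normal_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    from scipy import stats as sps

    n = len(ranks)
    mean = n * (n + 1) / 4.0
    var = np.sum(ranks**2) / 4.0  # equals n(n+1)(2n+1)/24 without ties
    z = (w_plus - mean) / math.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def bootstrap_mean_se(values_by_image, n_boot: int = 500,
                      seed: int | None = None) -> tuple[float, float]:
    """Bootstrap mean and standard error of image-level values.

    Resamples the per-image values with replacement ``n_boot`` times and
    returns the mean of the resampled means and their standard deviation.
    """
    values = np.asarray(values_by_image, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two images to bootstrap across images")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    return float(means.mean()), float(means.std())
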