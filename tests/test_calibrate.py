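import numpy as np
import pytest

from stromaspatial import (
    fit_distribution,
    map_threshold,
    percentile_threshold,
    propagate_thresholds,
)
from stromaspatial.calibrate import FAMILIES, DistributionFit, FitError


def random_fit(family, rng):
    """A synthetic DistributionFit with plausible parameters (not fitted)."""
    params = {
        "lognormal": lambda: (rng.uniform(0.3, 1.0), 0.0,
                              np.exp(rng.uniform(0.0, 3.0))),
        "wald": lambda: (0.0, rng.uniform(1.0, 50.0)),
        "burr": lambda: (rng.uniform(2.0, 6.0), rng.uniform(0.5, 3.0), 0.0,
                         rng.uniform(1.0, 50.0)),
        "beta": lambda: (rng.uniform(1.0, 5.0), rng.uniform(2.0, 8.0), 0.0,
                         rng.uniform(50.0, 500.0)),
        "gamma": lambda: (rng.uniform(1.0, 6.0), 0.0, rng.uniform(1.0, 20.0)),
    }[family]()
    return DistributionFit(family=family, params=params, sse=0.0,
                           sse_by_family={family: 0.0}, n_bins=0, n_values=0,
                           value_range=(0.0, np.inf))


class TestFitDistribution:
    def test_lognormal_parameters_recovered(self):
        rng = np.random.default_rng(21)
        values = rng.lognormal(2.0, 0.5, 50_000)
        fit = fit_distribution(values)
        assert fit.family == "lognormal"
        sigma, loc, scale = fit.params
        assert sigma == pytest.approx(0.5, rel=0.02)
        assert np.log(scale) == pytest.approx(2.0, rel=0.02)
        assert loc == 0.0

    def test_restricted_pool_returns_that_family(self):
        rng = np.random.default_rng(21)
        values = rng.lognormal(2.0, 0.5, 5_000)
        fit = fit_distribution(values, families=("gamma",))
        assert fit.family == "gamma"
        assert set(fit.sse_by_family) == {"gamma"}
        assert fit.sse > 0

    def test_all_family_sses_reported(self):
        rng = np.random.default_rng(3)
        fit = fit_distribution(rng.lognormal(1.0, 0.4, 2_000))
        assert set(fit.sse_by_family) <= set(FAMILIES)
        assert fit.sse == min(fit.sse_by_family.values())

    def test_cdf_ppf_are_inverse(self):
        rng = np.random.default_rng(5)
        fit = fit_distribution(rng.lognormal(1.0, 0.4, 2_000))
        for t in np.quantile(rng.lognormal(1.0, 0.4, 500), [0.1, 0.5, 0.9]):
            assert fit.ppf(fit.cdf(t)) == pytest.approx(t, rel=1e-9)

    def test_degenerate_sample_is_error(self):
        with pytest.raises(FitError, match="degenerate"):
            fit_distribution(np.full(500, 3.0))

    def test_too_few_values_is_error(self):
        with pytest.raises(FitError, match="100"):
            fit_distribution(np.arange(50, dtype=float))

    def test_negative_values_rejected(self):
        with pytest.raises(FitError):
            fit_distribution(np.linspace(-1, 10, 500))


class TestMapThreshold:
    def test_identity_mapping(self, rng):
        fit = random_fit("lognormal", rng)
        t = fit.ppf(0.8)
        assert map_threshold(fit, fit, t) == pytest.approx(t, rel=1e-9)

    def test_scaled_lognormal_closed_form(self):
        """dst = src scaled by c in log-location => t_dst = c * t_src."""
        mu, sigma = 1.5, 0.6
        for c in (0.5, 1.3, 2.0):
            src = DistributionFit("lognormal", (sigma, 0.0, np.exp(mu)), 0.0,
                                  {}, 0, 0, (0, np.inf))
            dst = DistributionFit("lognormal",
                                  (sigma, 0.0, np.exp(mu + np.log(c))), 0.0,
                                  {}, 0, 0, (0, np.inf))
            t = float(src.ppf(0.85))
            assert map_threshold(src, dst, t) == pytest.approx(c * t, rel=1e-9)

    @pytest.mark.parametrize("fam_src", list(FAMILIES))
    @pytest.mark.parametrize("fam_dst", list(FAMILIES))
    def test_round_trip_every_family_pair(self, fam_src, fam_dst):
        rng = np.random.default_rng(hash((fam_src, fam_dst)) % 2**31)
        src = random_fit(fam_src, rng)
        dst = random_fit(fam_dst, rng)
        t = float(src.ppf(rng.uniform(0.1, 0.9)))
        back = map_threshold(dst, src, map_threshold(src, dst, t))
        assert abs(back - t) / t < 1e-6

    def test_monotone_in_source_threshold(self, rng):
        src = random_fit("gamma", rng)
        dst = random_fit("burr", rng)
        ts = [float(src.ppf(q)) for q in (0.2, 0.4, 0.6, 0.8)]
        mapped = [map_threshold(src, dst, t) for t in ts]
        assert np.all(np.diff(mapped) > 0)

    def test_tail_threshold_unmappable(self, rng):
        fit = random_fit("lognormal", rng)
        with pytest.raises(ValueError, match="tail"):
            map_threshold(fit, fit, 0.0)


class TestPropagateThresholds:
    def _batch(self, scales, n=2_000, seed=8):
        rng = np.random.default_rng(seed)
        return {
            f"im{k}": c * rng.lognormal(2.0, 0.5, n)
            for k, c in enumerate(scales, start=1)
        }

    def test_multiplicative_batch_recovered(self):
        scales = [1.0, 1.5, 0.8]
        tables = self._batch(scales, n=20_000)
        t_ref = float(np.exp(2.0 + 0.5 * 1.2816))  # ~90th percentile
        ts = propagate_thresholds(tables, ("cell", "marker", "max"), "im1",
                                  t_ref)
        for key, c in zip(ts.thresholds, scales):
            assert ts.thresholds[key] == pytest.approx(c * t_ref, rel=0.05)

    def test_reference_threshold_is_exact(self):
        tables = self._batch([1.0, 1.1])
        ts = propagate_thresholds(tables, ("cell", "marker", "max"), "im1", 10.0)
        assert ts.thresholds["im1"] == 10.0

    def test_identical_images_map_to_t_ref(self):
        tables = self._batch([1.0, 1.0, 1.0], n=20_000)
        ts = propagate_thresholds(tables, ("cell", "marker", "max"), "im1", 12.0)
        for t in ts.thresholds.values():
            assert t == pytest.approx(12.0, rel=0.05)

    def test_missing_reference_is_error(self):
        with pytest.raises(ValueError, match="reference"):
            propagate_thresholds(self._batch([1.0]), ("cell", "marker", "max"),
                                 "nope", 10.0)

    def test_small_images_excluded_with_warning(self):
        tables = self._batch([1.0, 1.2])
        tables["tiny"] = np.ones(20) * 5
        with pytest.warns(UserWarning, match="tiny"):
            ts = propagate_thresholds(tables, ("cell", "marker", "max"),
                                      "im1", 10.0)
        assert "tiny" in ts.excluded
        assert "tiny" not in ts.thresholds


class TestPercentileThreshold:
    def test_top_ten_percent_of_1_to_1000(self):
        values = np.arange(1, 1001, dtype=float)
        t = percentile_threshold(values, 0.10)
        assert t == pytest.approx(900.1)
        assert int((values > t).sum()) == 100

    def test_matches_brute_force_order_statistics(self, rng):
        values = rng.uniform(0, 1, 777)
        for frac in (0.05, 0.25, 0.5):
            t = percentile_threshold(values, frac)
            # brute force: linear-interpolated order statistic
            s = np.sort(values)
            pos = (1 - frac) * (len(s) - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            expected = s[lo] + (pos - lo) * (s[hi] - s[lo])
            assert t == pytest.approx(expected, rel=1e-12)

    def test_near_one_fraction_puts_threshold_at_minimum(self, rng):
        values = rng.uniform(1, 2, 100)
        t = percentile_threshold(values, 0.999999)
        assert t == pytest.approx(values.min(), rel=1e-4)

    def test_all_equal_values_none_positive(self):
        values = np.full(50, 7.0)
        t = percentile_threshold(values, 0.1)
        assert t == 7.0
        assert int((values > t).sum()) == 0  # strict inequality rule

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            percentile_threshold([], 0.1)
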