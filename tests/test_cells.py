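import numpy as np
import pytest
from scipy import ndimage

from stromaspatial import (
    CellRecord,
    LabelMask,
    MultiChannelImage,
    expand_cells,
    extract_features,
    filter_by_nuclear_area,
    import_labels,
    segment_nuclei,
)
from stromaspatial.cells import SegmentationError


def _disk_image(shape, centers, radius, value=200.0):
    img = np.zeros(shape)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for cx, cy in centers:
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2] = value
    return img


class TestSegmentNuclei:
    def test_phantom_disks_recovered_with_centroids(self, band_phantom):
        cfg, image, truth = band_phantom
        mask = segment_nuclei(image.channels["nuclei"], cfg.pixel_size_um)
        assert mask.n_labels == cfg.n_cells
        # match each true center to the nearest detected centroid
        ids = mask.ids()
        centroids = np.array(ndimage.center_of_mass(
            np.ones(mask.labels.shape), mask.labels, ids))
        detected_xy = centroids[:, ::-1]  # (x, y) pixel coords
        for cx, cy in truth.centers_px:
            d = np.hypot(detected_xy[:, 0] - cx, detected_xy[:, 1] - cy)
            assert d.min() <= 1.0

    def test_touching_pair_split_by_watershed(self):
        img = _disk_image((40, 40), [(14, 20), (26, 20)], radius=7)
        mask = segment_nuclei(img, pixel_size_um=1.0, min_distance_um=5.0)
        assert mask.n_labels == 2

    def test_blank_image_warns_empty(self):
        with pytest.warns(UserWarning, match="blank"):
            mask = segment_nuclei(np.zeros((32, 32)), pixel_size_um=1.0)
        assert mask.n_labels == 0


class TestImportLabels:
    def test_labeled_tiff(self, tmp_path):
        import tifffile

        lab = np.zeros((16, 16), dtype=np.int32)
        for k in range(1, 43):
            lab[k // 8, (2 * k) % 16] = k
        tifffile.imwrite(tmp_path / "lab.tif", lab)
        mask = import_labels(tmp_path / "lab.tif", pixel_size_um=1.0)
        assert mask.n_labels == 42

    def test_non_integer_tiff_rejected(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "bad.tif",
                         np.random.default_rng(0).random((8, 8)).astype(np.float32))
        with pytest.raises(SegmentationError, match="integer"):
            import_labels(tmp_path / "bad.tif", pixel_size_um=1.0)

    def test_geojson_polygons(self, tmp_path):
        import json

        def square(x0, y0, s):
            return {"type": "Feature", "properties": {},
                    "geometry": {"type": "Polygon", "coordinates": [[
                        [x0, y0], [x0 + s, y0], [x0 + s, y0 + s],
                        [x0, y0 + s], [x0, y0]]]}}

        doc = {"type": "FeatureCollection",
               "features": [square(1, 1, 4), square(10, 1, 4), square(1, 10, 4)]}
        path = tmp_path / "rois.geojson"
        path.write_text(json.dumps(doc))
        mask = import_labels(path, pixel_size_um=1.0)
        assert mask.n_labels == 3

    def test_overlapping_polygons_report_coordinates(self, tmp_path):
        import json

        def square(x0, y0, s):
            return {"type": "Feature", "properties": {},
                    "geometry": {"type": "Polygon", "coordinates": [[
                        [x0, y0], [x0 + s, y0], [x0 + s, y0 + s],
                        [x0, y0 + s], [x0, y0]]]}}

        doc = {"type": "FeatureCollection",
               "features": [square(1, 1, 6), square(4, 4, 6)]}
        path = tmp_path / "rois.geojson"
        path.write_text(json.dumps(doc))
        with pytest.raises(SegmentationError, match="overlap"):
            import_labels(path, pixel_size_um=1.0)


class TestExpandCells:
    def test_isolated_disk_grows_by_radius(self):
        lab = np.zeros((64, 64), dtype=np.int32)
        yy, xx = np.mgrid[0:64, 0:64]
        lab[(xx - 32) ** 2 + (yy - 32) ** 2 <= 10**2] = 1
        cell, cyto = expand_cells(LabelMask(lab, 1.0), radius_um=5.0)
        rr = np.hypot(xx - 32, yy - 32)[cell.labels == 1]
        assert rr.max() == pytest.approx(15.0, abs=1.0)
        # cytoplasm is the ring between r=10 and r=15
        ring = np.hypot(xx - 32, yy - 32)[cyto.labels == 1]
        assert ring.min() > 10 - 1e-9

    def test_two_nuclei_partition_matches_brute_force(self):
        lab = np.zeros((40, 64), dtype=np.int32)
        yy, xx = np.mgrid[0:40, 0:64]
        c1, c2 = (26, 20), (38, 20)  # 12 px apart
        lab[(xx - c1[0]) ** 2 + (yy - c1[1]) ** 2 <= 3**2] = 1
        lab[(xx - c2[0]) ** 2 + (yy - c2[1]) ** 2 <= 3**2] = 2
        cell, _ = expand_cells(LabelMask(lab, 1.0), radius_um=5.0)

        # brute force: per pixel, exact distance to the nearest pixel of each
        # nucleus; assign within radius, tie -> lower label
        pix1 = np.argwhere(lab == 1)
        pix2 = np.argwhere(lab == 2)
        expected = np.zeros_like(lab)
        for i in range(40):
            for j in range(64):
                d1 = np.sqrt(((pix1 - (i, j)) ** 2).sum(axis=1)).min()
                d2 = np.sqrt(((pix2 - (i, j)) ** 2).sum(axis=1)).min()
                if min(d1, d2) <= 5.0:
                    expected[i, j] = 1 if d1 <= d2 else 2
        np.testing.assert_array_equal(cell.labels, expected)

    def test_subpixel_radius_warns_empty_cytoplasm(self):
        lab = np.zeros((16, 16), dtype=np.int32)
        lab[8, 8] = 1
        with pytest.warns(UserWarning, match="cytoplasm"):
            cell, cyto = expand_cells(LabelMask(lab, 1.0), radius_um=0.4)
        assert (cyto.labels == 1).sum() == 0

    def test_expansion_is_monotone_in_radius(self):
        rng = np.random.default_rng(1)
        lab = np.zeros((48, 48), dtype=np.int32)
        yy, xx = np.mgrid[0:48, 0:48]
        for k, (cx, cy) in enumerate(rng.integers(8, 40, size=(4, 2)), start=1):
            lab[(xx - cx) ** 2 + (yy - cy) ** 2 <= 3**2] = k
        small, _ = expand_cells(LabelMask(lab, 1.0), radius_um=3.0)
        large, _ = expand_cells(LabelMask(lab, 1.0), radius_um=6.0)
        for k in range(1, 5):
            assert np.all(large.labels[small.labels == k] == k)

    def test_compartments_partition_each_cell(self):
        lab = np.zeros((48, 48), dtype=np.int32)
        yy, xx = np.mgrid[0:48, 0:48]
        lab[(xx - 15) ** 2 + (yy - 15) ** 2 <= 4**2] = 1
        lab[(xx - 30) ** 2 + (yy - 30) ** 2 <= 4**2] = 2
        cell, cyto = expand_cells(LabelMask(lab, 1.0), radius_um=5.0)
        overlap = (lab > 0) & (cyto.labels > 0)
        assert not overlap.any()
        for k in (1, 2):
            union = (lab == k) | (cyto.labels == k)
            np.testing.assert_array_equal(union, cell.labels == k)


class TestExtractFeatures:
    def _image(self, channels, ps=1.0):
        return MultiChannelImage(channels=channels, pixel_size_um=ps,
                                 image_id="t")

    def test_uniform_channel_statistics(self):
        lab = np.zeros((16, 16), dtype=np.int32)
        lab[4:8, 4:8] = 1
        nuc = LabelMask(lab, 1.0)
        cell, cyto = expand_cells(nuc, radius_um=2.0)
        img = self._image({"marker": np.full((16, 16), 7.0)})
        rec = extract_features(img, nuc, cell, cyto)[0]
        for comp in ("nucleus", "cytoplasm", "cell"):
            assert rec.features[(comp, "marker", "mean")] == 7.0
            assert rec.features[(comp, "marker", "median")] == 7.0
            assert rec.features[(comp, "marker", "max")] == 7.0
            assert rec.features[(comp, "marker", "std")] == 0.0

    def test_four_pixel_nucleus_statistics(self):
        lab = np.zeros((8, 8), dtype=np.int32)
        lab[2:4, 2:4] = 1
        grid = np.zeros((8, 8))
        grid[2, 2], grid[2, 3], grid[3, 2], grid[3, 3] = 1, 2, 3, 10
        nuc = LabelMask(lab, 1.0)
        cell, cyto = expand_cells(nuc, radius_um=1.0)
        rec = extract_features(self._image({"m": grid}), nuc, cell, cyto)[0]
        assert rec.features[("nucleus", "m", "max")] == 10
        assert rec.features[("nucleus", "m", "median")] == 2.5
        assert rec.features[("nucleus", "m", "mean")] == 4.0
        assert rec.features[("nucleus", "m", "min")] == 1.0
        assert rec.nucleus_area_um2 == 4.0

    def test_matches_brute_force_pixel_loop(self, rng):
        lab = np.zeros((32, 32), dtype=np.int32)
        yy, xx = np.mgrid[0:32, 0:32]
        lab[(xx - 10) ** 2 + (yy - 10) ** 2 <= 3**2] = 1
        lab[(xx - 22) ** 2 + (yy - 22) ** 2 <= 3**2] = 2
        nuc = LabelMask(lab, 0.5)
        cell, cyto = expand_cells(nuc, radius_um=1.5)
        grid = rng.uniform(0, 50, (32, 32))
        recs = extract_features(self._image({"m": grid}, ps=0.5), nuc, cell, cyto)
        for rec in recs:
            for comp, mask in (("nucleus", nuc), ("cytoplasm", cyto),
                               ("cell", cell)):
                vals = [grid[i, j] for i in range(32) for j in range(32)
                        if mask.labels[i, j] == rec.cell_id]
                assert rec.features[(comp, "m", "mean")] == pytest.approx(np.mean(vals))
                assert rec.features[(comp, "m", "median")] == pytest.approx(np.median(vals))
                assert rec.features[(comp, "m", "std")] == pytest.approx(np.std(vals))


class TestAreaFilter:
    def _cells(self, areas, image_id="im"):
        return [CellRecord(image_id=image_id, cell_id=i, centroid_x_um=0,
                           centroid_y_um=0, nucleus_area_um2=float(a))
                for i, a in enumerate(areas)]

    def test_matches_brute_force_percentile_filter(self, rng):
        areas = rng.gamma(5.0, 8.0, size=1000)
        kept = filter_by_nuclear_area(self._cells(areas), 5, 99)
        lo, hi = np.percentile(areas, [5, 99])
        expected = [a for a in areas if not (a < lo or a > hi)]
        assert len(kept) == len(expected)
        assert sorted(c.nucleus_area_um2 for c in kept) == sorted(expected)

    def test_identical_areas_all_kept(self):
        kept = filter_by_nuclear_area(self._cells([12.0] * 10), 5, 99)
        assert len(kept) == 10

    def test_full_range_is_identity(self, rng):
        areas = rng.uniform(10, 60, 100)
        kept = filter_by_nuclear_area(self._cells(areas), 0, 100)
        assert len(kept) == 100

    def test_percentiles_are_per_image(self, rng):
        small = self._cells(rng.normal(20, 1, 500), "a")
        big = self._cells(rng.normal(200, 10, 500), "b")
        kept = filter_by_nuclear_area(small + big, 5, 99)
        # pooled percentiles would wipe out one image; per-image keeps both
        assert sum(c.image_id == "a" for c in kept) > 400
        assert sum(c.image_id == "b" for c in kept) > 400

    def test_all_filtered_is_error(self):
        with pytest.raises(ValueError):
            filter_by_nuclear_area(self._cells([1.0]), 5, 99)
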