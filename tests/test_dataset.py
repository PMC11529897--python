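"""Crown cropping, labeling, balancing and splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beetlegan import (ClassLabel, FieldScores, MultispectralCrop,
                       WindowOutOfBoundsError, balance_classes, crop_crown,
                       extract_crops, score_to_class, split_dataset)
from beetlegan.dataset import geo_to_pixel, read_crop, write_crop

from conftest import make_crops, record


class TestGeoTransform:
    GEO = {"pixel_scale": (0.08, 0.08, 0.0),
           "tiepoint": (0.0, 0.0, 0.0, 500000.0, 6900000.0, 0.0)}

    def test_tiepoint_maps_to_origin(self):
        assert geo_to_pixel(500000.0, 6900000.0, self.GEO) == (0, 0)

    def test_north_up_axes(self):
        # east -> +x, south (lower northing) -> +y
        x, y = geo_to_pixel(500000.0 + 8.0, 6900000.0 - 4.0, self.GEO)
        assert (x, y) == (100, 50)

    def test_missing_geotransform_is_hard_error(self):
        with pytest.raises(ValueError, match="geotransform"):
            geo_to_pixel(1.0, 2.0, {})


class TestScoreToClass:
    @pytest.mark.parametrize("scores,dead,expected", [
        ((0, 0, 0, 0, 0), False, 0),          # zero total
        ((1, 1, 0, 0, 0), False, 1),          # 1.5*(1+1) = 3 > 2
        ((0, 0, 1, 1, 0), False, 0),          # unweighted total exactly 2
        ((0, 0, 1, 1, 1), False, 1),          # 3 > 2
        ((1, 0, 0, 0, 0), False, 0),          # 1.5 <= 2
        ((0, 0, 0, 0, 0), True, 2),           # visually dead wins
        ((5, 4, 1, 2, 2), True, 2),
    ])
    def test_weighted_total_rule(self, scores, dead, expected):
        fs = FieldScores(*scores)
        assert score_to_class(fs, dead).value == expected

    @pytest.mark.parametrize("field,bad", [
        ("crown_color", 6), ("defoliation", 5), ("crown_size", 2),
        ("resin_flow", 3), ("bark_damage", -1),
    ])
    def test_out_of_range_score_names_field(self, field, bad):
        kwargs = dict(crown_color=0, defoliation=0, crown_size=0,
                      resin_flow=0, bark_damage=0)
        kwargs[field] = bad
        with pytest.raises(ValueError, match=field):
            FieldScores(**kwargs)

    @given(st.integers(0, 5), st.integers(0, 4), st.integers(0, 1),
           st.integers(0, 2), st.integers(0, 2))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_every_score(self, cc, df, cs, rf, bd):
        """Raising any single symptom score never moves declining -> healthy."""
        base = score_to_class(FieldScores(cc, df, cs, rf, bd), False).value
        bumps = [(min(cc + 1, 5), df, cs, rf, bd),
                 (cc, min(df + 1, 4), cs, rf, bd),
                 (cc, df, min(cs + 1, 1), rf, bd),
                 (cc, df, cs, min(rf + 1, 2), bd),
                 (cc, df, cs, rf, min(bd + 1, 2))]
        for bumped in bumps:
            assert score_to_class(FieldScores(*bumped), False).value >= base


class TestCropCrown:
    def test_center_pixel_identity(self, rng):
        raster = rng.random((256, 256, 5))
        crop = crop_crown(raster, record(128, 128), size=64)
        assert crop.pixels.shape == (64, 64, 5)
        np.testing.assert_array_equal(crop.pixels[32, 32], raster[128, 128])

    def test_near_edge_window_rejected(self, rng):
        raster = rng.random((256, 256, 5))
        with pytest.raises(WindowOutOfBoundsError):
            crop_crown(raster, record(10, 10), size=64)

    def test_extract_skips_out_of_bounds(self, rng):
        raster = rng.random((256, 256, 5))
        records = [record(128, 128, "ok"), record(10, 10, "edge")]
        crops = extract_crops(raster, records)
        assert [c.tree_id for c in crops] == ["ok"]

    def test_constant_raster_gives_constant_crop(self):
        raster = np.full((128, 128, 5), 0.37)
        crop = crop_crown(raster, record(64, 64), size=64)
        assert np.all(crop.pixels == 0.37)

    def test_wrong_band_count_is_hard_error(self, rng):
        with pytest.raises(ValueError, match="5"):
            crop_crown(rng.random((256, 256, 3)), record(128, 128))

    @pytest.mark.parametrize("size", [0, -2, 63])
    def test_bad_size_rejected(self, rng, size):
        with pytest.raises(ValueError):
            crop_crown(rng.random((256, 256, 5)), record(128, 128), size=size)

    def test_tiff_round_trip_bit_exact(self, rng, tmp_path):
        crop = MultispectralCrop(rng.random((64, 64, 5)), "rt", ClassLabel(1))
        path = tmp_path / "rt.tif"
        write_crop(path, crop)
        back = read_crop(path, "rt", ClassLabel(1))
        np.testing.assert_array_equal(back.pixels, crop.pixels)


class TestBalanceClasses:
    def test_downsamples_to_minority(self):
        crops = make_crops((114, 190, 150))
        out = balance_classes(crops, seed=0)
        assert len(out) == 342
        counts = np.bincount([c.label.value for c in out], minlength=3)
        assert list(counts) == [114, 114, 114]

    def test_already_balanced_keeps_multiset(self):
        crops = make_crops((5, 5, 5))
        out = balance_classes(crops, seed=3)
        assert sorted(c.tree_id for c in out) == sorted(c.tree_id for c in crops)

    def test_deterministic_under_seed(self):
        crops = make_crops((6, 9, 7))
        a = balance_classes(crops, seed=11)
        b = balance_classes(crops, seed=11)
        assert [c.tree_id for c in a] == [c.tree_id for c in b]

    def test_missing_class_is_hard_error(self):
        with pytest.raises(ValueError, match="2"):
            balance_classes(make_crops((3, 3, 0)), seed=0)


class TestSplitDataset:
    def test_published_sizes(self):
        crops = make_crops((114, 114, 114))
        train, test = split_dataset(crops, 0.2, seed=42)
        assert (len(train), len(test)) == (273, 69)
        counts = np.bincount([c.label.value for c in test], minlength=3)
        assert list(counts) == [23, 23, 23]

    def test_partition_disjoint_and_covering(self):
        crops = make_crops((10, 12, 9))
        train, test = split_dataset(crops, 0.3, seed=7)
        train_ids = {c.tree_id for c in train}
        test_ids = {c.tree_id for c in test}
        assert not train_ids & test_ids
        assert train_ids | test_ids == {c.tree_id for c in crops}

    def test_symmetric_half_split(self):
        train, test = split_dataset(make_crops((10, 10, 10)), 0.5, seed=1)
        for side in (train, test):
            counts = np.bincount([c.label.value for c in side], minlength=3)
            assert list(counts) == [5, 5, 5]

    def test_deterministic_under_seed(self):
        crops = make_crops((8, 8, 8))
        a = split_dataset(crops, 0.25, seed=5)
        b = split_dataset(crops, 0.25, seed=5)
        assert [c.tree_id for c in a[0]] == [c.tree_id for c in b[0]]
        assert [c.tree_id for c in a[1]] == [c.tree_id for c in b[1]]

    def test_tiny_class_is_hard_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            split_dataset(make_crops((1, 5, 5)), 0.2, seed=0)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.1])
    def test_bad_fraction_rejected(self, frac):
        with pytest.raises(ValueError):
            split_dataset(make_crops((5, 5, 5)), frac, seed=0)
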