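import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import clahe_oracle
from idcc.clahe import (
    ClaheParams,
    Histogram,
    apply_clahe,
    clip_histogram,
    cumulative_mapping,
    tile_histogram,
    tile_partition,
)
from idcc.exceptions import ValidationError


class TestTilePartition:
    def test_exact_multiple_no_padding(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        grid = tile_partition(img, ClaheParams())
        assert (grid.n_rows, grid.n_cols) == (2, 2)
        assert (grid.pad_bottom, grid.pad_right) == (0, 0)

    def test_ceil_partition_with_padding(self, rng):
        img = rng.integers(0, 256, (10, 10)).astype(np.uint8)
        grid = tile_partition(img, ClaheParams())
        assert (grid.n_rows, grid.n_cols) == (2, 2)
        assert (grid.pad_bottom, grid.pad_right) == (6, 6)
        assert grid.padded.shape == (16, 16)

    def test_tiny_image_reflect_padded(self):
        img = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9]], dtype=np.uint8)
        grid = tile_partition(img, ClaheParams())
        assert (grid.n_rows, grid.n_cols) == (1, 1)
        # reflect without edge repetition: [1,2,3] -> [1,2,3,2,1,2,3,2]
        np.testing.assert_array_equal(grid.padded[0], [1, 2, 3, 2, 1, 2, 3, 2])
        np.testing.assert_array_equal(grid.padded[:, 0], [1, 4, 7, 4, 1, 4, 7, 4])


class TestTileHistogram:
    def test_constant_tile(self):
        tile = np.full((8, 8), 7, dtype=np.uint8)
        hist = tile_histogram(tile, ClaheParams())
        assert hist.counts[7] == 64
        assert hist.counts.sum() == 64

    def test_distinct_values_one_per_bin(self):
        tile = np.arange(64, dtype=np.uint8).reshape(8, 8)
        hist = tile_histogram(tile, ClaheParams())
        assert (hist.counts[:64] == 1).all() and hist.counts[64:].sum() == 0

    def test_checkerboard_split(self):
        tile = np.indices((8, 8)).sum(axis=0) % 2 * 255
        hist = tile_histogram(tile.astype(np.uint8), ClaheParams())
        assert hist.counts[0] == 32 and hist.counts[255] == 32


class TestClipHistogram:
    def test_hand_computed_redistribution(self):
        # beta = max(1, 0.5*16/4) = 2; excess 3 spread as 0.75 per bin
        params = ClaheParams(tile_size=4, clip_limit=0.5, n_levels=4, p_max=3)
        hist = Histogram(counts=np.array([5.0, 1.0, 0.0, 0.0]), n_tile=16)
        clipped = clip_histogram(hist, params)
        np.testing.assert_allclose(clipped.counts, [2.75, 1.75, 0.75, 0.75])

    def test_uniform_histogram_unchanged_up_to_zero_excess(self):
        params = ClaheParams(tile_size=8, clip_limit=1.0)
        hist = Histogram(counts=np.full(256, 0.25), n_tile=64)
        np.testing.assert_allclose(clip_histogram(hist, params).counts, 0.25)

    @given(st.lists(st.integers(0, 64), min_size=256, max_size=256),
           st.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_sum_conserved(self, counts, c):
        params = ClaheParams(clip_limit=c)
        hist = Histogram(counts=np.array(counts, dtype=float), n_tile=64)
        clipped = clip_histogram(hist, params)
        assert abs(clipped.counts.sum() - hist.counts.sum()) < 1e-9
        assert (clipped.counts >= 0).all()


class TestCumulativeMapping:
    def test_uniform_four_level_lut(self):
        params = ClaheParams(tile_size=2, n_levels=4, p_max=3)
        hist = Histogram(counts=np.array([1.0, 1.0, 1.0, 1.0]), n_tile=4)
        lut = cumulative_mapping(hist, params).lut
        np.testing.assert_allclose(lut, [0.75, 1.5, 2.25, 3.0])

    def test_all_mass_at_top_level(self):
        params = ClaheParams(tile_size=2, n_levels=4, p_max=3)
        hist = Histogram(counts=np.array([0.0, 0.0, 0.0, 4.0]), n_tile=4)
        np.testing.assert_allclose(
            cumulative_mapping(hist, params).lut, [0.0, 0.0, 0.0, 3.0]
        )

    def test_all_zero_histogram_rejected(self):
        with pytest.raises(ValidationError):
            cumulative_mapping(Histogram(counts=np.zeros(256), n_tile=64),
                               ClaheParams())

    @given(st.lists(st.integers(0, 20), min_size=8, max_size=8).filter(sum))
    @settings(max_examples=50, deadline=None)
    def test_lut_monotone_and_tops_out_at_pmax(self, counts):
        params = ClaheParams(tile_size=4, n_levels=8, p_max=255)
        lut = cumulative_mapping(
            Histogram(counts=np.array(counts, dtype=float), n_tile=16), params
        ).lut
        assert (np.diff(lut) >= -1e-12).all()
        assert lut[-1] == pytest.approx(255.0)


class TestApplyClahe:
    def test_constant_image_stays_constant(self):
        img = np.full((20, 20), 130, dtype=np.uint8)
        out = apply_clahe(img)
        assert (out == out[0, 0]).all()
        assert out.shape == img.shape

    def test_two_tone_matches_oracle(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        img[:, 8:] = 200
        params = ClaheParams(clip_limit=1.0)
        np.testing.assert_array_equal(
            apply_clahe(img, params), clahe_oracle(img, clip_limit=1.0)
        )

    @pytest.mark.parametrize("shape", [(8, 8), (10, 13), (32, 32), (5, 29)])
    def test_matches_oracle_on_random_images(self, shape, rng):
        img = rng.integers(0, 256, shape).astype(np.uint8)
        np.testing.assert_array_equal(apply_clahe(img), clahe_oracle(img))

    @pytest.mark.parametrize("shape", [(7, 7), (100, 101), (1, 40), (33, 1)])
    def test_shape_preserved_and_range_bounded(self, shape, rng):
        img = rng.integers(0, 256, shape).astype(np.uint8)
        out = apply_clahe(img)
        assert out.shape == shape
        assert out.min() >= 0 and out.max() <= 255

    def test_default_params_full_range_output(self, rng):
        img = rng.integers(0, 256, (64, 48)).astype(np.uint8)
        out = apply_clahe(img, ClaheParams(tile_size=8, clip_limit=0.8))
        assert out.dtype == np.uint8
        assert out.shape == img.shape
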