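import numpy as np
import pytest
from hypothesis import given, strategies as st

from morphseg import (
    InvalidElementError,
    OrderingError,
    StructuringElement,
    close_,
    dilate,
    erode,
    geodesic_dilate,
    geodesic_erode,
    median_filter,
    open_,
    openclose_reconstruction_filter,
    reconstruct_by_dilation,
    reconstruct_by_erosion,
)
from oracles import (
    brute_dilate,
    brute_erode,
    brute_median,
    brute_reconstruct_dilation,
    brute_reconstruct_erosion,
)

CONN8 = StructuringElement.square(3).offsets


def random_se(rng):
    """A random SE with support inside a 5x5 box, origin always included."""
    while True:
        mask = rng.random((5, 5)) < 0.4
        mask[2, 2] = True
        offs = np.argwhere(mask) - 2
        if len(offs):
            return StructuringElement(offs)


class TestStructuringElement:
    def test_disk1_is_plus_shape(self):
        se = StructuringElement.disk(1)
        assert sorted(map(tuple, se.offsets)) == [(-1, 0), (0, -1), (0, 0), (0, 1), (1, 0)]

    def test_point_is_identity_support(self):
        assert len(StructuringElement.point()) == 1

    def test_empty_support_rejected(self):
        with pytest.raises(InvalidElementError):
            StructuringElement(np.empty((0, 2), dtype=int))

    def test_origin_must_be_in_support(self):
        with pytest.raises(InvalidElementError):
            StructuringElement(np.array([[1, 0]]))


class TestDilateErode:
    def test_dilate_spreads_peak_to_plus(self):
        f = np.zeros((5, 5))
        f[2, 2] = 9
        out = dilate(f, StructuringElement.disk(1))
        np.testing.assert_array_equal(out, brute_dilate(f, StructuringElement.disk(1).offsets))
        assert out[2, 2] == 9 and out[1, 2] == 9 and out[2, 1] == 9 and out[0, 0] == 0

    def test_erode_spreads_pit_to_plus(self):
        f = np.full((5, 5), 255.0)
        f[2, 2] = 0
        out = erode(f, StructuringElement.disk(1))
        np.testing.assert_array_equal(out, brute_erode(f, StructuringElement.disk(1).offsets))
        assert out[1, 2] == 0 and out[0, 0] == 255

    def test_constant_invariance(self):
        f = np.full((6, 6), 7.0)
        se = StructuringElement.disk(2)
        np.testing.assert_array_equal(dilate(f, se), f)
        np.testing.assert_array_equal(erode(f, se), f)

    def test_point_se_is_identity(self, rng):
        f = rng.integers(0, 256, (8, 8)).astype(float)
        np.testing.assert_array_equal(dilate(f, StructuringElement.point()), f)

    def test_matches_bruteforce_on_random_images(self, rng):
        for _ in range(25):
            f = rng.integers(0, 256, (16, 16)).astype(float)
            se = random_se(rng)
            np.testing.assert_array_equal(dilate(f, se), brute_dilate(f, se.offsets))
            np.testing.assert_array_equal(erode(f, se), brute_erode(f, se.offsets))

    def test_duality_with_reflected_element(self, rng):
        for _ in range(10):
            f = rng.integers(0, 256, (12, 12)).astype(float)
            se = random_se(rng)
            np.testing.assert_array_equal(
                dilate(f, se), 255.0 - erode(255.0 - f, se.reflected)
            )


class TestOpenClose:
    @given(seed=st.integers(0, 10_000))
    def test_ordering_chain(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.integers(0, 256, (10, 10)).astype(float)
        se = StructuringElement.disk(rng.integers(1, 3))
        e, o, c, d = erode(f, se), open_(f, se), close_(f, se), dilate(f, se)
        assert np.all(e <= o) and np.all(o <= f) and np.all(f <= c) and np.all(c <= d)

    def test_open_close_idempotent(self, rng):
        f = rng.integers(0, 256, (12, 12)).astype(float)
        se = StructuringElement.disk(1)
        np.testing.assert_array_equal(open_(open_(f, se), se), open_(f, se))
        np.testing.assert_array_equal(close_(close_(f, se), se), close_(f, se))

    def test_open_removes_bright_impulse(self):
        f = np.zeros((7, 7))
        f[3, 3] = 200
        assert open_(f, StructuringElement.disk(1)).max() == 0

    def test_close_fills_dark_impulse(self):
        f = np.full((7, 7), 200.0)
        f[3, 3] = 0
        assert close_(f, StructuringElement.disk(1)).min() == 200


class TestGeodesicAndReconstruction:
    def test_marker_equal_mask_is_fixed_point(self, rng):
        f = rng.integers(0, 256, (8, 8)).astype(float)
        np.testing.assert_array_equal(geodesic_dilate(f, f, iterations=5), f)
        np.testing.assert_array_equal(reconstruct_by_dilation(f, f), f)

    def test_single_iteration_definition(self, rng):
        mask = rng.integers(0, 256, (8, 8)).astype(float)
        marker = np.minimum(mask, rng.integers(0, 256, (8, 8)).astype(float))
        one = geodesic_dilate(marker, mask, iterations=1)
        np.testing.assert_array_equal(
            one, np.minimum(dilate(marker, StructuringElement.square(3)), mask)
        )

    def test_ordering_violation_raises(self):
        with pytest.raises(OrderingError):
            geodesic_dilate(np.ones((3, 3)), np.zeros((3, 3)))
        with pytest.raises(OrderingError):
            geodesic_erode(np.zeros((3, 3)), np.ones((3, 3)))

    def test_seed_fills_flat_plateau(self):
        mask = np.zeros((5, 5))
        mask[1:4, 1:4] = 10
        marker = np.zeros((5, 5))
        marker[2, 2] = 10
        out = reconstruct_by_dilation(marker, mask)
        np.testing.assert_array_equal(out, mask)

    def test_reconstruction_matches_bruteforce(self, rng):
        for _ in range(15):
            mask = rng.integers(0, 100, (8, 8)).astype(float)
            marker = np.minimum(mask, rng.integers(0, 100, (8, 8)).astype(float))
            got = reconstruct_by_dilation(marker, mask)
            want = brute_reconstruct_dilation(marker, mask, CONN8)
            np.testing.assert_array_equal(got, want)
            got_e = reconstruct_by_erosion(mask + 5, mask)
            want_e = brute_reconstruct_erosion(mask + 5, mask, CONN8)
            np.testing.assert_array_equal(got_e, want_e)

    def test_reconstruction_monotone_and_bounded(self, rng):
        mask = rng.integers(0, 100, (8, 8)).astype(float)
        m1 = np.minimum(mask, rng.integers(0, 50, (8, 8)).astype(float))
        m2 = np.minimum(mask, m1 + rng.integers(0, 30, (8, 8)).astype(float))
        r1 = reconstruct_by_dilation(m1, mask)
        r2 = reconstruct_by_dilation(m2, mask)
        assert np.all(m1 <= r1) and np.all(r1 <= mask)
        assert np.all(r1 <= r2)


class TestOpenCloseReconstructionFilter:
    def test_constant_unchanged(self):
        f = np.full((6, 6), 33.0)
        np.testing.assert_array_equal(
            openclose_reconstruction_filter(f, StructuringElement.disk(1)), f
        )

    def test_idempotent_on_own_output(self, rng):
        f = rng.integers(0, 256, (12, 12)).astype(float)
        se = StructuringElement.disk(1)
        once = openclose_reconstruction_filter(f, se)
        np.testing.assert_array_equal(openclose_reconstruction_filter(once, se), once)

    def test_removes_isolated_impulses(self):
        f = np.full((9, 9), 100.0)
        f[2, 2] = 255  # bright speck
        f[6, 6] = 0  # dark speck
        out = openclose_reconstruction_filter(f, StructuringElement.disk(1))
        np.testing.assert_array_equal(out, np.full((9, 9), 100.0))


class TestMedianFilter:
    def test_constant_unchanged(self):
        f = np.full((5, 5), 9.0)
        np.testing.assert_array_equal(median_filter(f, 3), f)

    def test_impulse_removed(self):
        f = np.zeros((5, 5))
        f[2, 2] = 255
        assert median_filter(f, 3).max() == 0

    def test_unit_window_is_identity(self, rng):
        f = rng.integers(0, 256, (6, 6)).astype(float)
        np.testing.assert_array_equal(median_filter(f, 1), f)

    def test_matches_sort_oracle(self, rng):
        for size in (3, 5):
            f = rng.integers(0, 256, (10, 10)).astype(float)
            np.testing.assert_array_equal(median_filter(f, size), brute_median(f, size))
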