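import numpy as np
import pytest

from morphseg import (
    ConfigError,
    DegenerateHistogramError,
    NoMarkerError,
    extended_minima,
    extract_markers,
    histogram,
    hminima,
    otsu_threshold,
    regional_minima,
    scale_union_markers,
)
from morphseg.markers import Histogram, binarize_gradient, label_markers
from oracles import brute_otsu, flood_regional_minima, minima_dynamics


def hist_from_counts(d):
    counts = np.zeros(256, dtype=np.int64)
    for k, v in d.items():
        counts[k] = v
    return Histogram(counts)


class TestHistogram:
    def test_constant_image_single_bin(self):
        h = histogram(np.full((2, 5), 7, dtype=np.uint8))
        assert h.counts[7] == 10 and h.total == 10
        assert h.counts.sum() == 10

    def test_matches_counting_oracle(self, rng):
        f = rng.integers(0, 256, (20, 20)).astype(np.uint8)
        h = histogram(f)
        for level in range(256):
            assert h.counts[level] == np.count_nonzero(f == level)

    def test_rejects_out_of_range(self):
        with pytest.raises(ConfigError):
            histogram(np.array([[300]]))


class TestOtsu:
    def test_two_extreme_spikes(self):
        res = otsu_threshold(hist_from_counts({0: 50, 255: 50}))
        assert res.threshold == 0  # every split ties; smallest wins
        assert res.theta1 == pytest.approx(0.5)
        assert res.sigma2_profile[0] == pytest.approx(0.25 * 255**2)

    def test_two_spike_tie_broken_low(self):
        res = otsu_threshold(hist_from_counts({50: 10, 200: 10}))
        assert res.threshold == 50

    def test_degenerate_histogram_raises(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(hist_from_counts({128: 99}))

    def test_matches_bruteforce_argmax(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 40, 256)
            counts[rng.integers(0, 256)] += 100
            if np.count_nonzero(counts) < 2:
                continue
            res = otsu_threshold(Histogram(counts))
            t_ref, sigma_ref = brute_otsu(counts)
            assert res.threshold == t_ref
            np.testing.assert_allclose(
                res.sigma2_profile, sigma_ref, rtol=1e-12, atol=1e-9, equal_nan=True
            )

    def test_mixture_identity_at_every_candidate(self, rng):
        counts = rng.integers(0, 30, 256)
        counts[[10, 200]] += 50
        h = Histogram(counts)
        n = counts.sum()
        levels = np.arange(256)
        u = (levels * counts).sum() / n
        for t in range(0, 255):
            n1 = counts[: t + 1].sum()
            n2 = n - n1
            if n1 == 0 or n2 == 0:
                continue
            u1 = (levels[: t + 1] * counts[: t + 1]).sum() / n1
            u2 = (levels[t + 1 :] * counts[t + 1 :]).sum() / n2
            assert u == pytest.approx(u1 * (n1 / n) + u2 * (n2 / n), abs=1e-9)
        res = otsu_threshold(h)
        assert res.u == pytest.approx(res.u1 * res.theta1 + res.u2 * res.theta2, abs=1e-9)


class TestHMinima:
    def test_zero_depth_is_identity(self, rng):
        f = rng.integers(0, 256, (6, 6)).astype(float)
        np.testing.assert_array_equal(hminima(f, 0), f)

    def test_shallow_minimum_suppressed_deep_retained(self):
        f = np.array([[5.0, 2.0, 5.0, 4.0, 5.0]])
        out = hminima(f, 2)
        np.testing.assert_array_equal(out, np.array([[5.0, 4.0, 5.0, 5.0, 5.0]]))
        marked = extended_minima(f, 2)
        np.testing.assert_array_equal(marked, np.array([[False, True, False, False, False]]))

    def test_depth_beyond_dynamic_flattens(self):
        f = np.array([[9.0, 1.0, 9.0], [9.0, 9.0, 9.0]])
        out = hminima(f, 100)
        assert out.min() == out.max()

    def test_negative_depth_rejected(self):
        with pytest.raises(ConfigError):
            hminima(np.zeros((2, 2)), -1)

    def test_monotone_in_depth(self, rng):
        f = rng.integers(0, 100, (8, 8)).astype(float)
        assert np.all(hminima(f, 3) <= hminima(f, 7))

    def test_survivors_trace_to_deep_original_minima(self, rng):
        from scipy import ndimage

        for _ in range(20):
            f = rng.integers(0, 40, (8, 8)).astype(float)
            h = 5
            out_minima = regional_minima(hminima(f, h))
            orig = minima_dynamics(f)
            lab, n = ndimage.label(out_minima, structure=np.ones((3, 3)))
            for k in range(1, n + 1):
                comp_out = lab == k
                dyns = [dyn for comp, dyn in orig if (comp & comp_out).any()]
                assert dyns and max(dyns) >= h


class TestRegionalMinima:
    def test_convex_bowl_center_only(self):
        rows, cols = np.mgrid[0:7, 0:7]
        f = (rows - 3) ** 2 + (cols - 3) ** 2
        mask = regional_minima(f)
        assert mask[3, 3] and mask.sum() == 1

    def test_constant_image_single_plateau(self):
        mask = regional_minima(np.full((4, 6), 3.0))
        assert mask.all()

    def test_matches_flood_oracle(self, rng):
        for conn in (4, 8):
            for _ in range(20):
                f = rng.integers(0, 10, (8, 8)).astype(float)
                np.testing.assert_array_equal(
                    regional_minima(f, conn), flood_regional_minima(f, conn)
                )

    def test_extended_minima_zero_depth(self, rng):
        f = rng.integers(0, 50, (8, 8)).astype(float)
        np.testing.assert_array_equal(extended_minima(f, 0), regional_minima(f))

    def test_marker_count_non_increasing_in_depth(self, rng):
        f = rng.integers(0, 100, (12, 12)).astype(float)
        counts = [label_markers(extended_minima(f, h))[1] for h in (0, 5, 15, 40)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestScaleUnionMarkers:
    def test_single_scale_reduces_to_filtered_extended_minima(self, rng):
        from morphseg import StructuringElement, openclose_reconstruction_filter

        f = rng.integers(0, 100, (10, 10)).astype(float)
        got = scale_union_markers(f, scales=[1], t=3)
        filt = openclose_reconstruction_filter(f, StructuringElement.disk(1))
        np.testing.assert_array_equal(got, extended_minima(filt, 3))

    def test_union_monotone_in_scales(self, rng):
        f = rng.integers(0, 100, (12, 12)).astype(float)
        one = scale_union_markers(f, scales=[1], t=5)
        two = scale_union_markers(f, scales=[1, 2], t=5)
        assert np.all(one <= two)


class TestExtractMarkers:
    @staticmethod
    def two_basin_gradient():
        """A gradient surface with two deep basins split by a high ridge."""
        f = np.full((9, 9), 200.0)
        f[2:4, 2:4] = 5.0
        f[6:8, 6:8] = 10.0
        return f

    def test_otsu_mode_finds_two_basins(self):
        mask = extract_markers(self.two_basin_gradient(), mode="otsu_hmin")
        assert label_markers(mask)[1] == 2

    def test_flat_gradient_raises(self):
        with pytest.raises((DegenerateHistogramError, NoMarkerError)):
            extract_markers(np.full((8, 8), 3.0))

    def test_manual_depth_beyond_dynamic_single_global_marker(self):
        mask = extract_markers(self.two_basin_gradient(), mode="manual", h_manual=500)
        assert label_markers(mask)[1] == 1

    def test_binarize_gradient_is_strict_threshold(self):
        f = np.array([[1.0, 2.0, 3.0]])
        np.testing.assert_array_equal(binarize_gradient(f, 2), [[False, False, True]])
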