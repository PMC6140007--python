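"""Chromatic histogram thresholding, non-maxima filtering, and aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dinosarc import (
    DomainError,
    ParameterError,
    SarcParams,
    axis_threshold,
    chromatic_histogram,
    compute_thresholds,
    nonmax_filter,
    sarc_map,
    split_axes,
    threshold_maps,
)
from dinosarc.sarc import ChromaticHistogram

from .conftest import make_lab


def brute_force_second_difference_argmax(p):
    """Independent oracle: enumerate central second differences over all
    interior bins; ties toward the margin (largest k)."""
    p = np.asarray(p, dtype=float)
    if len(p) < 3 or p.sum() <= 0:
        return None
    best_k, best_val = None, -np.inf
    for k in range(1, len(p) - 1):
        val = p[k + 1] - 2 * p[k] + p[k - 1]
        if val >= best_val:
            best_k, best_val = k, val
    return best_k


class TestChromaticHistogram:
    def test_constant_channel_single_bin(self):
        h = chromatic_histogram(np.full((10, 10), 5.0), np.ones((10, 10), bool))
        assert h.probabilities.tolist() == [1.0]
        assert h.bin_edges[0] == 5.0 and h.bin_edges[-1] == 6.0

    def test_two_value_channel(self):
        channel = np.r_[np.full(50, -2.0), np.full(50, 3.0)].reshape(10, 10)
        h = chromatic_histogram(channel, np.ones((10, 10), bool))
        nz = h.probabilities[h.probabilities > 0]
        assert np.allclose(nz, [0.5, 0.5])

    def test_matches_per_pixel_count_oracle(self, rng):
        channel = rng.normal(2.0, 6.0, size=(40, 40))
        mask = rng.uniform(size=(40, 40)) > 0.3
        h = chromatic_histogram(channel, mask)
        vals = channel[mask]
        counts = np.array(
            [
                ((vals >= lo) & ((vals < hi) | (i == len(h.probabilities) - 1) & (vals <= hi))).sum()
                for i, (lo, hi) in enumerate(zip(h.bin_edges[:-1], h.bin_edges[1:]))
            ]
        )
        assert np.allclose(h.probabilities, counts / counts.sum())
        assert abs(h.probabilities.sum() - 1.0) < 1e-9

    def test_empty_mask_rejected(self):
        with pytest.raises(DomainError):
            chromatic_histogram(np.zeros((4, 4)), np.zeros((4, 4), bool))


class TestSplitAxes:
    @staticmethod
    def _hist(edges, probs):
        return ChromaticHistogram("a", np.asarray(edges, float), np.asarray(probs, float))

    def test_all_positive_mass(self):
        h = self._hist([4, 5, 6], [0.3, 0.7])
        pos, neg = split_axes(h)
        assert pos.probabilities.tolist() == [0.3, 0.7]
        assert neg.probabilities.size == 0

    def test_symmetric_histogram_mirrors(self):
        h = self._hist([-3, -2, -1, 0, 1, 2, 3], [0.1, 0.2, 0.2, 0.2, 0.2, 0.1])
        pos, neg = split_axes(h)
        assert np.allclose(pos.probabilities, neg.probabilities)

    def test_sign_partition_oracle(self, rng):
        edges = np.arange(-7, 9, dtype=float)
        probs = rng.dirichlet(np.ones(len(edges) - 1))
        h = self._hist(edges, probs)
        pos, neg = split_axes(h)
        centers = h.centers
        assert np.allclose(pos.probabilities, probs[centers >= 0])
        assert np.allclose(neg.probabilities, probs[centers < 0][::-1])
        # inner edges map a selected bin back to an inclusive threshold
        assert np.allclose(pos.inner_edges, edges[:-1][centers >= 0])
        assert np.allclose(neg.inner_edges, edges[1:][centers < 0][::-1])


class TestAxisThreshold:
    def test_worked_sequence(self):
        assert axis_threshold([0.5, 0.2, 0.15, 0.1, 0.05, 0.0]) == 1

    def test_geometric_decay(self):
        p = 0.5 ** (np.arange(8) + 1)
        assert axis_threshold(p) == 1

    @pytest.mark.parametrize("p", [[0.6, 0.4], [], [0.0, 0.0, 0.0, 0.0]])
    def test_degenerate_sequences_absent(self, p):
        assert axis_threshold(p) is None

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=3, max_size=40))
    def test_oracle_equivalence(self, raw):
        p = np.asarray(raw) + 1e-6  # ensure mass
        assert axis_threshold(p) == brute_force_second_difference_argmax(p)

    def test_ties_break_toward_margin(self):
        p = np.array([0.25, 0.25, 0.25, 0.25])  # all second differences zero
        assert axis_threshold(p) == 2


class TestThresholdMapsAndAggregation:
    def test_uniform_image_all_zero(self):
        img = make_lab(np.full((30, 30), 4.0), np.full((30, 30), -2.0))
        sal = sarc_map(img)
        assert not sal.values.any()

    def test_positive_blob_isolated_in_a_positive_map(self, rng):
        a = rng.uniform(0, 5, size=(60, 60))
        blob = np.zeros((60, 60), bool)
        blob[20:30, 25:35] = True
        a[blob] = rng.uniform(15, 20, size=blob.sum())
        img = make_lab(a, rng.uniform(-1, 1, size=(60, 60)))
        thr = compute_thresholds(img, SarcParams(smoothing_radius=0))
        maps = threshold_maps(img, thr)
        nonzero = maps[0] > 0
        assert nonzero.any() and not nonzero[~blob].any()

    def test_negative_blob_mirrors_to_a_negative_map(self, rng):
        a = rng.uniform(-5, 0, size=(60, 60))
        blob = np.zeros((60, 60), bool)
        blob[10:20, 5:15] = True
        a[blob] = rng.uniform(-20, -15, size=blob.sum())
        img = make_lab(a, np.zeros((60, 60)))
        thr = compute_thresholds(img, SarcParams(smoothing_radius=0))
        maps = threshold_maps(img, thr)
        assert maps[1][blob].any() and not (maps[1] > 0)[~blob].any()
        assert not maps[0].any() or (maps[0] > 0)[blob].all()

    def test_raising_threshold_never_adds_pixels(self, rng):
        from dinosarc.sarc import AxisThresholds

        a = rng.normal(0, 8, size=(40, 40))
        img = make_lab(a, np.zeros((40, 40)))
        lo = threshold_maps(img, AxisThresholds(2.0, None, None, None))[0] > 0
        hi = threshold_maps(img, AxisThresholds(6.0, None, None, None))[0] > 0
        assert (hi <= lo).all()

    def test_map_magnitudes_and_fov_zeroing(self, rng):
        from dinosarc.sarc import AxisThresholds

        a = rng.normal(0, 8, size=(40, 40))
        fov = rng.uniform(size=(40, 40)) > 0.4
        img = make_lab(a, np.zeros((40, 40)), fov=fov)
        m = threshold_maps(img, AxisThresholds(3.0, -3.0, None, None))
        assert not m[0][~fov].any() and not m[1][~fov].any()
        keep = (a >= 3.0) & fov
        assert np.allclose(m[0][keep], np.abs(a[keep]))

    def test_sarc_nonzero_subset_of_thresholded_union(self, small_frame):
        img = small_frame.to_lab()
        sal = sarc_map(img)
        thr = compute_thresholds(img)
        union = np.zeros(img.shape, bool)
        for m in threshold_maps(img, thr):
            union |= m > 0
        assert (sal.values >= 0).all()
        assert not (sal.values > 0)[~union].any()
        assert not sal.values[~img.fov_mask].any()

    def test_thresholds_are_position_invariant(self, rng):
        a = rng.normal(1, 6, size=(30, 30))
        b = rng.normal(-2, 5, size=(30, 30))
        img = make_lab(a, b)
        perm = rng.permutation(a.size)
        img_p = make_lab(a.ravel()[perm].reshape(a.shape), b.ravel()[perm].reshape(b.shape))
        t1, t2 = compute_thresholds(img), compute_thresholds(img_p)
        assert (t1.t_a_pos, t1.t_a_neg, t1.t_b_pos, t1.t_b_neg) == (
            t2.t_a_pos, t2.t_a_neg, t2.t_b_pos, t2.t_b_neg,
        )


class TestNonmaxFilter:
    def test_constant_map_unchanged(self):
        m = np.full((12, 12), 3.0)
        assert (nonmax_filter(m, 5) == m).all()

    def test_single_peak_unchanged(self):
        m = np.zeros((9, 9))
        m[4, 4] = 2.5
        assert (nonmax_filter(m, 3) == m).all()

    @pytest.mark.parametrize("n", [3, 5, 7])
    def test_matches_exhaustive_window_oracle(self, rng, n):
        m = rng.uniform(0, 1, size=(32, 32)) * (rng.uniform(size=(32, 32)) > 0.5)
        got = nonmax_filter(m, n)
        h = n // 2
        expected = np.zeros_like(m)
        for i in range(32):
            for j in range(32):
                win = m[max(0, i - h): i + h + 1, max(0, j - h): j + h + 1]
                if m[i, j] > 0 and m[i, j] == win.max():
                    expected[i, j] = m[i, j]
        assert (got == expected).all()

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            nonmax_filter(np.zeros((5, 5)), 4)
        with pytest.raises(ParameterError):
            SarcParams(nonmax_window_n=4)
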