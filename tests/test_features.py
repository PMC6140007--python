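"""9-D local color descriptors and the BoVW encoder."""

import io

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from dinosarc import (
    DESCRIPTOR_FIELDS,
    BovwEncoder,
    ParameterError,
    SalientPoint,
    VisualVocabulary,
    bovw_histogram,
    build_vocabulary,
    local_descriptor,
)
from dinosarc.regions import SalientRegion, SuperpixelSegmentation

from .conftest import make_lab


def _region(labels, label, rep):
    seg = SuperpixelSegmentation(labels=labels, n_segments=int(labels.max()),
                                 target_segments=int(labels.max()), compactness=10.0)
    point = SalientPoint(row=rep[0], col=rep[1], score=1.0, window_s=10)
    region = SalientRegion(superpixel_label=label, member_points=(point,),
                           representative=point, pixel_count=int((labels == label).sum()))
    return seg, region


class TestLocalDescriptor:
    def test_uniform_region(self):
        img = make_lab(np.full((4, 4), 10.0), np.full((4, 4), -5.0), L=np.full((4, 4), 50.0))
        seg, region = _region(np.ones((4, 4), int), 1, (2, 2))
        d = local_descriptor(img, seg, region)
        assert d.vector.tolist() == [50, 10, -5, 50, 50, 10, 10, -5, -5]

    def test_two_pixel_region(self):
        L = np.array([[40.0, 60.0]])
        a = np.array([[0.0, 4.0]])
        b = np.array([[0.0, -2.0]])
        img = make_lab(a, b, L=L)
        seg, region = _region(np.ones((1, 2), int), 1, (0, 0))
        d = local_descriptor(img, seg, region)
        assert d.vector.tolist() == [40, 0, 0, 40, 60, 0, 4, -2, 0]

    def test_matches_per_pixel_extrema_oracle(self, rng):
        shape = (20, 20)
        img = make_lab(rng.normal(size=shape), rng.normal(size=shape),
                       L=rng.uniform(0, 100, size=shape))
        labels = rng.integers(1, 5, size=shape)
        lab = 3
        rows, cols = np.nonzero(labels == lab)
        rep = (int(rows[0]), int(cols[0]))
        seg, region = _region(labels, lab, rep)
        d = local_descriptor(img, seg, region)
        pix = labels == lab
        expected = [
            img.L[rep], img.a[rep], img.b[rep],
            img.L[pix].min(), img.L[pix].max(),
            img.a[pix].min(), img.a[pix].max(),
            img.b[pix].min(), img.b[pix].max(),
        ]
        assert np.allclose(d.vector, expected)
        # contract: min <= point value <= max per channel
        for lo, val, hi in ((3, 0, 4), (5, 1, 6), (7, 2, 8)):
            assert d.vector[lo] <= d.vector[val] <= d.vector[hi]

    def test_csv_round_trip_is_exact(self, rng):
        mat = rng.normal(size=(12, 9))
        df = pd.DataFrame(mat, columns=list(DESCRIPTOR_FIELDS))
        buf = io.StringIO()
        df.to_csv(buf, index=False, float_format="%.17g")
        back = pd.read_csv(io.StringIO(buf.getvalue()), float_precision="round_trip")
        assert list(back.columns) == list(DESCRIPTOR_FIELDS)
        assert (back.to_numpy() == mat).all()


class TestVocabulary:
    def test_exact_clusters_recovered(self, rng):
        centers = rng.normal(scale=20, size=(5, 9))
        data = np.repeat(centers, 10, axis=0)
        vocab = build_vocabulary(data, k=5, seed=0)
        # match centers by nearest-pair assignment
        from scipy.spatial.distance import cdist

        d = cdist(vocab.words, centers)
        assert np.allclose(d.min(axis=1), 0.0, atol=1e-8)
        assert sorted(d.argmin(axis=1).tolist()) == [0, 1, 2, 3, 4]

    def test_seed_invariance_for_well_separated_data(self, rng):
        centers = rng.normal(scale=50, size=(4, 9))
        data = np.repeat(centers, 12, axis=0) + rng.normal(scale=0.01, size=(48, 9))
        from scipy.spatial.distance import cdist

        v1 = build_vocabulary(data, k=4, seed=1)
        v2 = build_vocabulary(data, k=4, seed=2)
        assert cdist(v1.words, v2.words).min(axis=1).max() < 1e-6

    def test_k_equals_n_descriptors(self, rng):
        data = rng.normal(size=(6, 9))
        vocab = build_vocabulary(data, k=6, seed=0)
        from scipy.spatial.distance import cdist

        assert np.allclose(cdist(vocab.words, data).min(axis=1), 0.0, atol=1e-8)

    def test_too_few_descriptors_rejected(self, rng):
        with pytest.raises(ParameterError):
            build_vocabulary(rng.normal(size=(3, 9)), k=5, seed=0)

    def test_quantization_error_non_increasing_in_k(self, rng):
        data = rng.normal(size=(300, 9)) * np.linspace(1, 10, 9)
        errors = []
        for k in (8, 16, 32):
            vocab = build_vocabulary(data, k=k, seed=0)
            from scipy.spatial.distance import cdist

            errors.append(cdist(data, vocab.words).min(axis=1).mean())
        assert errors[0] >= errors[1] >= errors[2]


class TestBovwHistogram:
    def test_descriptors_on_a_word_are_one_hot(self, rng):
        words = rng.normal(size=(6, 9))
        vocab = VisualVocabulary(words=words, seed=0, inertia=0.0)
        h = bovw_histogram(np.repeat(words[[3]], 7, axis=0), vocab)
        expected = np.zeros(6)
        expected[3] = 1.0
        assert np.allclose(h.frequencies, expected)
        assert h.n_descriptors == 7

    def test_matches_brute_force_nearest_center(self, rng):
        words = rng.normal(size=(8, 9))
        vocab = VisualVocabulary(words=words, seed=0, inertia=0.0)
        descs = rng.normal(size=(10, 9))
        h = bovw_histogram(descs, vocab)
        counts = np.zeros(8)
        for d in descs:
            counts[int(np.argmin([np.linalg.norm(d - w) for w in words]))] += 1
        assert np.allclose(h.frequencies, counts / 10)
        assert abs(h.frequencies.sum() - 1.0) < 1e-9

    def test_order_invariance(self, rng):
        words = rng.normal(size=(5, 9))
        vocab = VisualVocabulary(words=words, seed=0, inertia=0.0)
        descs = rng.normal(size=(30, 9))
        h1 = bovw_histogram(descs, vocab)
        h2 = bovw_histogram(descs[::-1], vocab)
        assert np.allclose(h1.frequencies, h2.frequencies)

    def test_empty_set_warns_and_zeroes(self, rng):
        vocab = VisualVocabulary(words=rng.normal(size=(4, 9)), seed=0, inertia=0.0)
        with pytest.warns(UserWarning, match="no descriptors"):
            h = bovw_histogram(np.zeros((0, 9)), vocab)
        assert not h.frequencies.any() and h.n_descriptors == 0


class TestBovwEncoder:
    def test_fit_transform_shapes_and_clone(self, rng):
        pool = rng.normal(size=(60, 9))
        enc = BovwEncoder(k=6, random_state=0)
        assert clone(enc).get_params()["k"] == 6
        enc.fit(pool)
        H = enc.transform([pool[:10], pool[10:30], np.zeros((0, 9))])
        assert H.shape == (3, 6)
        assert np.allclose(H[:2].sum(axis=1), 1.0)
        assert not H[2].any()
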