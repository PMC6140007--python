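"""Local 9-D color descriptors and the Bag-of-Visual-Words global descriptor.

Each salient region yields a 9-dimensional vector: the CIE-Lab values at
the representative salient point followed by the per-channel minimum and
maximum over the region's pixels, in the frozen order

    [L_p, a_p, b_p, min_L, max_L, min_a, max_a, min_b, max_b].

This captures the regional color differentiations a human reviewer relies
on when triaging frames.  For whole-image representation, the descriptors
are quantized against a k-means visual vocabulary (hard assignment to the
Euclidean-nearest word) and accumulated into a normalized histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .errors import DomainError, FormatError, ParameterError
from .image_core import LabImage
from .regions import SalientRegion, SuperpixelSegmentation

__all__ = [
    "DESCRIPTOR_FIELDS",
    "LocalDescriptor",
    "VisualVocabulary",
    "BoVWHistogram",
    "local_descriptor",
    "build_vocabulary",
    "bovw_histogram",
    "BovwEncoder",
]

#: Frozen order of the 9 descriptor dimensions.
DESCRIPTOR_FIELDS = (
    "L", "a", "b",
    "min_L", "max_L", "min_a", "max_a", "min_b", "max_b",
)


@dataclass(frozen=True)
class LocalDescriptor:
    """A 9-D color vector for one salient region."""

    vector: np.ndarray
    region_ref: int  # superpixel label
    point_ref: tuple[int, int]  # representative (row, col)

    def __post_init__(self) -> None:
        if self.vector.shape != (9,):
            raise FormatError(f"descriptor must have 9 dimensions, got {self.vector.shape}")


@dataclass(frozen=True)
class VisualVocabulary:
    """K visual words (cluster centers) in the 9-D descriptor space."""

    words: np.ndarray  # (K, 9)
    seed: int
    inertia: float

    @property
    def k(self) -> int:
        return self.words.shape[0]


@dataclass(frozen=True)
class BoVWHistogram:
    """Normalized visual-word frequencies for one image."""

    frequencies: np.ndarray
    n_descriptors: int


def local_descriptor(
    img: LabImage, seg: SuperpixelSegmentation, region: SalientRegion
) -> LocalDescriptor:
    """Assemble the 9-D descriptor of one salient region.

    Point values are read at the representative; min/max are computed over
    the region's pixels inside the fov mask.
    """
    rep = region.representative
    pix = (seg.labels == region.superpixel_label) & img.fov_mask
    if not pix.any():
        raise DomainError(
            f"region {region.superpixel_label} has no pixels inside the fov mask"
        )
    L, a, b = img.L[pix], img.a[pix], img.b[pix]
    vec = np.array(
        [
            img.L[rep.row, rep.col],
            img.a[rep.row, rep.col],
            img.b[rep.row, rep.col],
            L.min(), L.max(),
            a.min(), a.max(),
            b.min(), b.max(),
        ],
        dtype=float,
    )
    return LocalDescriptor(vector=vec, region_ref=region.superpixel_label,
                           point_ref=(rep.row, rep.col))


def _as_matrix(descriptors) -> np.ndarray:
    if isinstance(descriptors, np.ndarray):
        mat = np.asarray(descriptors, dtype=float)
        if mat.ndim != 2:
            raise FormatError("descriptor array must be 2-D")
    else:
        mat = np.array([d.vector if isinstance(d, LocalDescriptor) else d
                        for d in descriptors], dtype=float)
        if mat.size == 0:
            mat = mat.reshape(0, 9)
    if mat.shape[0] and mat.shape[1] != 9:
        raise FormatError(f"descriptors must be 9-D, got {mat.shape[1]}-D")
    return mat


def build_vocabulary(descriptors, k: int = 600, seed: int = 0) -> VisualVocabulary:
    """k-means visual vocabulary from a pool of local descriptors.

    Uses 10 restarts with a fixed seed so the vocabulary is reproducible.
    """
    mat = _as_matrix(descriptors)
    if mat.shape[0] < k:
        raise ParameterError(f"need at least k={k} descriptors, got {mat.shape[0]}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(mat)
    return VisualVocabulary(words=km.cluster_centers_.copy(), seed=seed,
                            inertia=float(km.inertia_))


def assign_words(descriptors, vocab: VisualVocabulary) -> np.ndarray:
    """Index of the Euclidean-nearest word per descriptor (ties -> lowest)."""
    mat = _as_matrix(descriptors)
    if mat.shape[0] == 0:
        return np.zeros(0, dtype=int)
    if mat.shape[1] != vocab.words.shape[1]:
        raise FormatError(
            f"descriptor dimension {mat.shape[1]} != vocabulary dimension "
            f"{vocab.words.shape[1]}"
        )
    return cdist(mat, vocab.words).argmin(axis=1)


def bovw_histogram(descriptors, vocab: VisualVocabulary) -> BoVWHistogram:
    """Normalized histogram of nearest-word assignments for one image.

    An empty descriptor set yields an all-zero histogram and a warning.
    """
    if vocab.k == 0:
        raise ParameterError("empty vocabulary")
    idx = assign_words(descriptors, vocab)
    if idx.size == 0:
        warnings.warn("no descriptors: BoVW histogram is all-zero", stacklevel=2)
        return BoVWHistogram(frequencies=np.zeros(vocab.k), n_descriptors=0)
    counts = np.bincount(idx, minlength=vocab.k).astype(float)
    return BoVWHistogram(frequencies=counts / idx.size, n_descriptors=int(idx.size))


class BovwEncoder(BaseEstimator, TransformerMixin):
    """sklearn-style Bag-of-Visual-Words encoder.

    ``fit`` learns the k-means vocabulary from a (n, 9) descriptor pool;
    ``transform`` maps a sequence of per-image descriptor arrays to the
    (n_images, k) matrix of normalized word histograms.

    Parameters
    ----------
    k : int
        Vocabulary size (number of visual words).
    random_state : int
        Seed for the k-means restarts.
    """

    def __init__(self, k: int = 600, random_state: int = 0):
        self.k = k
        self.random_state = random_state

    def fit(self, X, y=None):
        self.vocabulary_ = build_vocabulary(X, k=self.k, seed=self.random_state)
        return self

    def transform(self, X):
        check_is_fitted(self, "vocabulary_")
        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty images encode as zeros
            for image_descriptors in X:
                rows.append(bovw_histogram(image_descriptors, self.vocabulary_).frequencies)
        return np.array(rows)
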