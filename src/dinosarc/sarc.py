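"""Selective Aggregation of chRomatic image Components (SARC).

SARC builds a saliency map from the two chromatic channels alone.  The key
assumption is that abnormal tissue occupies the *margins* of the per-image
chromatic range: for each half-axis (positive and negative) of the ``a`` and
``b`` histograms, the algorithm places a threshold at the argmax of the
second derivative of the (normalized, optionally smoothed) probability
sequence walked outward from zero — i.e. at the outer foot of the normal
lump, where the rate of the first derivative changes.  Thresholding yields
four component maps (a+, a-, b+, b-) carrying the chromatic magnitude of
the surviving pixels; each is filtered with an n x n sliding window that
discards local non-maxima, and the four filtered maps are summed into the
final saliency map ``I_SARC``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .errors import DomainError, ParameterError
from .image_core import LabImage

__all__ = [
    "SarcParams",
    "ChromaticHistogram",
    "AxisSequence",
    "AxisThresholds",
    "SaliencyMap",
    "chromatic_histogram",
    "split_axes",
    "axis_threshold",
    "compute_thresholds",
    "threshold_maps",
    "nonmax_filter",
    "sarc_map",
]


@dataclass(frozen=True)
class SarcParams:
    """Tunables of the SARC stage.

    histogram_bin_width
        Width of the chromatic histogram bins (chromatic units); 1 matches
        the near-integer resolution of 8-bit-derived a/b channels.
    smoothing_radius
        Moving-average radius (bins) applied to each half-axis sequence
        before differentiation; 0 disables smoothing.
    nonmax_window_n
        Odd side (pixels) of the local non-maxima suppression window.
    """

    histogram_bin_width: float = 1.0
    smoothing_radius: int = 2
    nonmax_window_n: int = 5

    def __post_init__(self) -> None:
        if self.histogram_bin_width <= 0:
            raise ParameterError("histogram_bin_width must be positive")
        if self.smoothing_radius < 0:
            raise ParameterError("smoothing_radius must be >= 0")
        if self.nonmax_window_n < 3 or self.nonmax_window_n % 2 == 0:
            raise ParameterError("nonmax_window_n must be odd and >= 3")


@dataclass(frozen=True)
class ChromaticHistogram:
    """Normalized histogram H_c of a chromatic channel over the fov mask."""

    component: str  # "a" or "b"
    bin_edges: np.ndarray  # length n_bins + 1, contiguous
    probabilities: np.ndarray  # length n_bins, sums to 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class AxisSequence:
    """One half-axis of a chromatic histogram, walked outward from zero.

    ``inner_edges[k]`` is the edge of bin ``k`` nearer to zero; it is the
    chromatic value a selected threshold maps back to (inclusive comparison
    keeps the selected bin itself).
    """

    probabilities: np.ndarray
    inner_edges: np.ndarray


@dataclass(frozen=True)
class AxisThresholds:
    """The four data-driven thresholds plus derivative diagnostics.

    A threshold is None (ABSENT) when its half-axis has fewer than 3 bins or
    carries no mass; the corresponding component map is then all-zero.
    ``derivatives`` maps axis names ("a+", "a-", "b+", "b-") to the
    (first, second) derivative sequences retained for diagnostics/plots.
    """

    t_a_pos: Optional[float]
    t_a_neg: Optional[float]
    t_b_pos: Optional[float]
    t_b_neg: Optional[float]
    derivatives: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.t_a_pos is not None and self.t_a_pos < 0:
            raise ParameterError("positive-axis threshold must be >= 0")
        if self.t_b_pos is not None and self.t_b_pos < 0:
            raise ParameterError("positive-axis threshold must be >= 0")
        if self.t_a_neg is not None and self.t_a_neg > 0:
            raise ParameterError("negative-axis threshold must be <= 0")
        if self.t_b_neg is not None and self.t_b_neg > 0:
            raise ParameterError("negative-axis threshold must be <= 0")


@dataclass(frozen=True)
class SaliencyMap:
    """The aggregated SARC saliency map I_SARC.

    ``values`` is the M x N nonnegative sum of the four non-max-filtered
    component maps; nonzero pixels are the candidate salient points.
    """

    values: np.ndarray
    params: SarcParams
    thresholds: AxisThresholds


def chromatic_histogram(
    channel: np.ndarray, mask: np.ndarray, bin_width: float = 1.0, component: str = "a"
) -> ChromaticHistogram:
    """Normalized histogram of ``channel`` over ``mask`` pixels.

    Bins are contiguous with width ``bin_width`` covering
    [floor(min), ceil(max)] of the masked values.
    """
    values = np.asarray(channel, dtype=float)[np.asarray(mask, dtype=bool)]
    if values.size == 0:
        raise DomainError("empty mask: no pixels to histogram")
    lo = np.floor(values.min())
    hi = np.ceil(values.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width - 1e-12)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return ChromaticHistogram(
        component=component,
        bin_edges=edges,
        probabilities=counts / counts.sum(),
    )


def split_axes(h: ChromaticHistogram) -> tuple[AxisSequence, AxisSequence]:
    """Split a chromatic histogram into its positive and negative half-axes.

    The positive sequence holds bins whose center is >= 0, ordered by
    increasing chromatic value; the negative sequence holds bins with
    center < 0, ordered by increasing |value| (walking outward from zero).
    """
    centers = h.centers
    pos = centers >= 0
    pos_seq = AxisSequence(
        probabilities=h.probabilities[pos],
        inner_edges=h.bin_edges[:-1][pos],  # lower edge is nearer zero
    )
    neg_idx = np.flatnonzero(~pos)[::-1]  # walk outward: toward -inf
    neg_seq = AxisSequence(
        probabilities=h.probabilities[neg_idx],
        inner_edges=h.bin_edges[1:][neg_idx],  # upper edge is nearer zero
    )
    return pos_seq, neg_seq


def _moving_average(p: np.ndarray, radius: int) -> np.ndarray:
    if radius <= 0:
        return p
    return ndi.uniform_filter1d(p, size=2 * radius + 1, mode="nearest")


def axis_threshold(
    p: np.ndarray, smoothing_radius: int = 0, return_derivatives: bool = False
):
    """Index of the second-derivative argmax of a half-axis sequence.

    The sequence is optionally smoothed by a moving average, then the first
    derivative r(k) = p(k+1) - p(k) and the central second difference
    R(k) = p(k+1) - 2 p(k) + p(k-1) are formed over interior bins; the
    returned index is argmax_k R(k) with ties broken toward the axis margin
    (largest k).  Returns None (ABSENT) for sequences with fewer than 3 bins
    or zero total mass.
    """
    p = np.asarray(p, dtype=float)
    if p.size < 3 or p.sum() <= 0:
        return (None, None, None) if return_derivatives else None
    q = _moving_average(p, smoothing_radius)
    r = np.diff(q)
    second = q[2:] - 2.0 * q[1:-1] + q[:-2]  # R(k) at interior k = 1 .. n-2
    best_interior = int(np.flatnonzero(second == second.max()).max())
    idx = best_interior + 1
    if return_derivatives:
        return idx, r, second
    return idx


def compute_thresholds(img: LabImage, params: SarcParams | None = None) -> AxisThresholds:
    """Derive the four axis thresholds from the image's chromatic histograms."""
    params = params or SarcParams()
    out: dict[str, Optional[float]] = {}
    derivs: dict[str, tuple] = {}
    for name, channel in (("a", img.a), ("b", img.b)):
        hist = chromatic_histogram(
            channel, img.fov_mask, bin_width=params.histogram_bin_width, component=name
        )
        pos_seq, neg_seq = split_axes(hist)
        for axis, seq in ((f"{name}+", pos_seq), (f"{name}-", neg_seq)):
            idx, r, second = axis_threshold(
                seq.probabilities, params.smoothing_radius, return_derivatives=True
            )
            derivs[axis] = (r, second)
            out[axis] = None if idx is None else float(seq.inner_edges[idx])
    return AxisThresholds(
        t_a_pos=out["a+"],
        t_a_neg=out["a-"],
        t_b_pos=out["b+"],
        t_b_neg=out["b-"],
        derivatives=derivs,
    )


def threshold_maps(
    img: LabImage, thr: AxisThresholds
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Apply the four thresholds, producing the component maps.

    Each map carries |chromatic value| at surviving pixels (inclusive
    comparison) and 0 elsewhere; an ABSENT threshold yields an all-zero map.
    All maps are zero outside the fov mask.
    """
    fov = img.fov_mask

    def _pos(channel: np.ndarray, t: Optional[float]) -> np.ndarray:
        if t is None:
            return np.zeros_like(channel)
        return np.where((channel >= t) & fov, np.abs(channel), 0.0)

    def _neg(channel: np.ndarray, t: Optional[float]) -> np.ndarray:
        if t is None:
            return np.zeros_like(channel)
        return np.where((channel <= t) & fov, np.abs(channel), 0.0)

    return (
        _pos(img.a, thr.t_a_pos),
        _neg(img.a, thr.t_a_neg),
        _pos(img.b, thr.t_b_pos),
        _neg(img.b, thr.t_b_neg),
    )


def nonmax_filter(component_map: np.ndarray, n: int = 5) -> np.ndarray:
    """Discard local non-maxima with an n x n sliding window.

    A pixel is retained (value kept) iff it is nonzero and equal to the
    maximum of the n x n window centered on it (ties retained); windows are
    clipped at the image borders.
    """
    if n < 3 or n % 2 == 0:
        raise ParameterError(f"window side n must be odd and >= 3, got {n}")
    m = np.asarray(component_map, dtype=float)
    # Zero padding is equivalent to border clipping for nonnegative maps.
    win_max = ndi.maximum_filter(m, size=n, mode="constant", cval=0.0)
    return np.where((m > 0) & (m == win_max), m, 0.0)


def sarc_map(img: LabImage, params: SarcParams | None = None) -> SaliencyMap:
    """Run the full SARC stage: thresholds, component maps, non-maxima
    filtering, and sum aggregation into I_SARC."""
    params = params or SarcParams()
    thr = compute_thresholds(img, params)
    maps = threshold_maps(img, thr)
    total = np.zeros(img.shape, dtype=float)
    for m in maps:
        total += nonmax_filter(m, params.nonmax_window_n)
    return SaliencyMap(values=total, params=params, thresholds=thr)
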