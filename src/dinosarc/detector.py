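"""DINOSARC salient point detection.

Candidates are the nonzero pixels of the SARC saliency map.  Each candidate
is scored by the chromatic spread of its neighborhood, sampled with two
concentric square windows of nominal sides s and s/2: the score is the
Euclidean distance, in the (a, b) plane, between the aggregate maximum
vector and the aggregate minimum vector of the two windows.  Points scoring
at least the saliency threshold tau are returned; with tau = AUTO the
threshold adapts per image to the mean candidate score, respecting the
observation that chromatic ranges differ image to image.

A nominal even side s is realized as an (s+1) x (s+1) window so it can be
centered on a pixel; windows are clipped at image borders and restricted to
the field-of-view mask.  The detector reads only the chromatic channels —
lightness never enters the score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .errors import DomainError, ParameterError
from .image_core import LabImage
from .sarc import SaliencyMap

__all__ = ["DetectorParams", "SalientPoint", "window_extrema", "point_saliency", "detect"]


@dataclass(frozen=True)
class DetectorParams:
    """Detector tunables.

    window_s
        Nominal outer window side s (even, >= 4); the inner window has side
        s/2.  Default 10, the side found preferable in tuning because it
        yields fewer salient points per image with no missed abnormal frame.
    saliency_tau
        Score threshold; ``None`` means AUTO (per-image mean candidate
        score).
    """

    window_s: int = 10
    saliency_tau: Optional[float] = None

    def __post_init__(self) -> None:
        if self.window_s < 4 or self.window_s % 2 != 0:
            raise ParameterError(f"window_s must be even and >= 4, got {self.window_s}")
        if self.saliency_tau is not None and self.saliency_tau < 0:
            raise ParameterError("saliency_tau must be nonnegative")


@dataclass(frozen=True)
class SalientPoint:
    """A detected salient point: pixel coordinate plus its chromatic
    max-min distance score and the window sides that produced it."""

    row: int
    col: int
    score: float
    window_s: int


def _realized(side: int) -> int:
    """Realize a nominal window side as an odd centered extent."""
    return side if side % 2 == 1 else side + 1


def window_extrema(
    img: LabImage, center: tuple[int, int], side: int
) -> tuple[float, float, float, float]:
    """(max_a, min_a, max_b, min_b) over the side x side window at ``center``.

    The window is clipped to the image and restricted to the fov mask; a
    window with no fov pixel raises :class:`DomainError`.
    """
    if side < 1:
        raise ParameterError("window side must be >= 1")
    r, c = center
    if not (0 <= r < img.height and 0 <= c < img.width):
        raise DomainError(f"center {center} outside the image")
    half = _realized(side) // 2
    rows = slice(max(0, r - half), min(img.height, r + half + 1))
    cols = slice(max(0, c - half), min(img.width, c + half + 1))
    sub_mask = img.fov_mask[rows, cols]
    if not sub_mask.any():
        raise DomainError(f"window at {center} lies entirely outside the fov mask")
    a = img.a[rows, cols][sub_mask]
    b = img.b[rows, cols][sub_mask]
    return float(a.max()), float(a.min()), float(b.max()), float(b.min())


def point_saliency(img: LabImage, center: tuple[int, int], s: int = 10) -> float:
    """Chromatic max-min distance at ``center`` over concentric s and s/2
    windows.

    The aggregate maximum vector (over both windows) and aggregate minimum
    vector are differenced in the (a, b) plane; the score is the Euclidean
    norm of that difference.
    """
    if s < 4 or s % 2 != 0:
        raise ParameterError(f"s must be even and >= 4, got {s}")
    max_ao, min_ao, max_bo, min_bo = window_extrema(img, center, s)
    max_ai, min_ai, max_bi, min_bi = window_extrema(img, center, s // 2)
    da = max(max_ao, max_ai) - min(min_ao, min_ai)
    db = max(max_bo, max_bi) - min(min_bo, min_bi)
    return float(np.hypot(da, db))


def _masked_extrema_maps(img: LabImage, side: int) -> tuple[np.ndarray, ...]:
    """Sliding-window extrema of a and b with fov masking and border
    clipping, for every pixel at once."""
    size = _realized(side)
    neg_inf = np.where(img.fov_mask, img.a, -np.inf)
    pos_inf = np.where(img.fov_mask, img.a, np.inf)
    max_a = ndi.maximum_filter(neg_inf, size=size, mode="constant", cval=-np.inf)
    min_a = ndi.minimum_filter(pos_inf, size=size, mode="constant", cval=np.inf)
    neg_inf = np.where(img.fov_mask, img.b, -np.inf)
    pos_inf = np.where(img.fov_mask, img.b, np.inf)
    max_b = ndi.maximum_filter(neg_inf, size=size, mode="constant", cval=-np.inf)
    min_b = ndi.minimum_filter(pos_inf, size=size, mode="constant", cval=np.inf)
    return max_a, min_a, max_b, min_b


def detect(
    img: LabImage, sal: SaliencyMap, params: DetectorParams | None = None
) -> list[SalientPoint]:
    """Detect salient points at the nonzero pixels of I_SARC.

    Returns points with score >= tau, sorted by descending score (ties in
    row-major order).  An all-zero saliency map yields an empty list.
    """
    params = params or DetectorParams()
    s = params.window_s
    cand = np.argwhere((sal.values > 0) & img.fov_mask)
    if cand.size == 0:
        return []
    mo_a, no_a, mo_b, no_b = _masked_extrema_maps(img, s)
    mi_a, ni_a, mi_b, ni_b = _masked_extrema_maps(img, s // 2)
    rows, cols = cand[:, 0], cand[:, 1]
    da = np.maximum(mo_a, mi_a)[rows, cols] - np.minimum(no_a, ni_a)[rows, cols]
    db = np.maximum(mo_b, mi_b)[rows, cols] - np.minimum(no_b, ni_b)[rows, cols]
    scores = np.hypot(da, db)
    tau = float(scores.mean()) if params.saliency_tau is None else params.saliency_tau
    keep = scores >= tau
    rows, cols, scores = rows[keep], cols[keep], scores[keep]
    order = np.lexsort((cols, rows, -scores))
    return [
        SalientPoint(row=int(rows[i]), col=int(cols[i]), score=float(scores[i]), window_s=s)
        for i in order
    ]
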