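"""Salient region detection via SLIC superpixels.

The frame is oversegmented into color-homogeneous superpixels (SLIC on the
Lab image, restricted to the fov mask).  A superpixel containing at least
one salient point becomes a salient region; a cluster of points inside one
superpixel is reduced to a single representative point (the rounded
arithmetic-mean coordinate, snapped to the nearest member if the centroid
falls outside the superpixel), so that every salient region carries exactly
one point.  Point-level saliency is thereby preserved — an abnormality
smaller than a superpixel is still localized by its representative point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.segmentation import slic

from .detector import SalientPoint
from .errors import ParameterError
from .image_core import LabImage

__all__ = ["SuperpixelSegmentation", "SalientRegion", "slic_segment", "salient_regions"]


@dataclass(frozen=True)
class SuperpixelSegmentation:
    """SLIC label map: label 0 outside the fov mask, labels >= 1 inside."""

    labels: np.ndarray
    n_segments: int
    target_segments: int
    compactness: float


@dataclass(frozen=True)
class SalientRegion:
    """A superpixel containing salient points, reduced to one representative."""

    superpixel_label: int
    member_points: tuple[SalientPoint, ...]
    representative: SalientPoint
    pixel_count: int


def slic_segment(img: LabImage, k_sp: int = 200, m_sp: float = 10.0) -> SuperpixelSegmentation:
    """Segment the frame into ~``k_sp`` superpixels with compactness ``m_sp``.

    SLIC runs on the Lab channels directly, restricted to the fov mask;
    connectivity enforcement merges small fragments into neighbors.
    """
    if k_sp < 2:
        raise ParameterError("k_sp must be >= 2")
    n_fov = int(img.fov_mask.sum())
    if k_sp > n_fov:
        raise ParameterError(f"k_sp={k_sp} exceeds the {n_fov} fov pixels")
    labels = slic(
        img.lab_stack(),
        n_segments=k_sp,
        compactness=m_sp,
        mask=img.fov_mask,
        channel_axis=-1,
        convert2lab=False,
        enforce_connectivity=True,
        start_label=1,
    )
    n = int(len(np.unique(labels[labels > 0])))
    return SuperpixelSegmentation(
        labels=labels, n_segments=n, target_segments=k_sp, compactness=m_sp
    )


def salient_regions(
    seg: SuperpixelSegmentation, points: list[SalientPoint]
) -> list[SalientRegion]:
    """Reduce salient points to one representative per point-bearing superpixel.

    A lone point represents itself.  A cluster is represented by the rounded
    arithmetic-mean coordinate carrying the maximum member score; if that
    centroid pixel falls outside the superpixel, the member point nearest the
    centroid is used instead.  Superpixels without points are not returned.
    """
    labels = seg.labels
    by_label: dict[int, list[SalientPoint]] = {}
    for p in points:
        lab = int(labels[p.row, p.col])
        if lab <= 0:  # outside the fov partition; cannot form a region
            continue
        by_label.setdefault(lab, []).append(p)

    out: list[SalientRegion] = []
    for lab in sorted(by_label):
        members = by_label[lab]
        if len(members) == 1:
            rep = members[0]
        else:
            rr = np.array([p.row for p in members], dtype=float)
            cc = np.array([p.col for p in members], dtype=float)
            cent = (int(np.rint(rr.mean())), int(np.rint(cc.mean())))
            best_score = max(p.score for p in members)
            s = members[0].window_s
            if (
                0 <= cent[0] < labels.shape[0]
                and 0 <= cent[1] < labels.shape[1]
                and int(labels[cent]) == lab
            ):
                rep = SalientPoint(row=cent[0], col=cent[1], score=best_score, window_s=s)
            else:
                d2 = (rr - cent[0]) ** 2 + (cc - cent[1]) ** 2
                near = members[int(np.argmin(d2))]
                rep = SalientPoint(row=near.row, col=near.col, score=best_score, window_s=s)
        out.append(
            SalientRegion(
                superpixel_label=lab,
                member_points=tuple(members),
                representative=rep,
                pixel_count=int((labels == lab).sum()),
            )
        )
    return out
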