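"""Shared fixtures: hand-built Lab images and synthetic frame batches."""

from __future__ import annotations

import numpy as np
import pytest

from dinosarc import (
    DetectorParams,
    LabImage,
    SynthConfig,
    detect,
    generate_dataset,
    salient_regions,
    sarc_map,
    slic_segment,
)


def make_lab(a, b, L=None, fov=None) -> LabImage:
    """Build a LabImage directly from channel arrays (no sRGB round trip)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if L is None:
        L = np.full(a.shape, 50.0)
    if fov is None:
        fov = np.ones(a.shape, dtype=bool)
    return LabImage(L=np.asarray(L, dtype=float), a=a, b=b, fov_mask=np.asarray(fov, bool))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def abnormal_batch():
    """Fifty default-generator abnormal frames (dataset seed 7) with the
    full point/region pipeline applied — shared by the recall, economy and
    reduction checks."""
    frames = generate_dataset(50, 0, dataset_seed=7)
    results = []
    for f in frames:
        img = f.to_lab()
        sal = sarc_map(img)
        pts = detect(img, sal, DetectorParams(window_s=10, saliency_tau=None))
        seg = slic_segment(img)
        regs = salient_regions(seg, pts)
        results.append({"frame": f, "img": img, "sal": sal, "points": pts,
                        "seg": seg, "regions": regs})
    return results


@pytest.fixture()
def small_frame():
    """One small abnormal frame for fast unit tests."""
    from dinosarc import generate_frame

    cfg = SynthConfig(size=(160, 160), lesion_kind="positive_a", lesion_radius=8.0, seed=11)
    return generate_frame(cfg)
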