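"""End-to-end orchestration of the feature-extraction stages.

``run_pipeline`` drives saliency -> points -> regions -> descriptors ->
BoVW for a batch of frames and writes every stage artifact plus a manifest
recording the config hash, so a re-run with identical inputs and config
reproduces identical outputs.  A frame that fails a stage is recorded in
the manifest's ``errors`` section and the run continues.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import detector, features, image_core, regions, sarc
from .config import PipelineConfig
from .synthetic import SynthFrame

__all__ = ["run_pipeline", "extract_image_features", "points_to_frame", "frame_to_points"]

log = logging.getLogger("dinosarc")

_DESC_COLUMNS = ["image_id", "label", "row", "col", *features.DESCRIPTOR_FIELDS]


def points_to_frame(points: Sequence[detector.SalientPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.row, p.col, p.score, p.window_s) for p in points],
        columns=["row", "col", "score", "s"],
    )


def frame_to_points(df: pd.DataFrame) -> list[detector.SalientPoint]:
    return [
        detector.SalientPoint(
            row=int(r.row), col=int(r.col), score=float(r.score), window_s=int(r.s)
        )
        for r in df.itertuples()
    ]


def extract_image_features(img: image_core.LabImage, cfg: PipelineConfig):
    """Run saliency, detection, segmentation and description for one frame.

    Returns (saliency_map, points, segmentation, regions, descriptors).
    """
    params = sarc.SarcParams(
        histogram_bin_width=cfg.bin_width,
        smoothing_radius=cfg.smoothing_radius,
        nonmax_window_n=cfg.nonmax_window_n,
    )
    sal = sarc.sarc_map(img, params)
    pts = detector.detect(
        img, sal, detector.DetectorParams(window_s=cfg.window_s, saliency_tau=cfg.saliency_tau)
    )
    seg = regions.slic_segment(img, k_sp=cfg.k_sp, m_sp=cfg.m_sp)
    regs = regions.salient_regions(seg, pts)
    descs = [features.local_descriptor(img, seg, r) for r in regs]
    return sal, pts, seg, regs, descs


def run_pipeline(
    images: Sequence,
    cfg: PipelineConfig,
    out_dir: str | Path,
    labels: Sequence[str] | None = None,
) -> dict:
    """Process a batch of frames and write all stage artifacts.

    ``images`` may mix file paths and :class:`SynthFrame` objects.  Returns
    the manifest (also written to ``out_dir/manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "provenance": cfg.provenance(),
        "images": [],
        "errors": [],
    }
    desc_rows: list[list] = []
    per_image_desc: dict[str, np.ndarray] = {}
    for i, item in enumerate(images):
        if isinstance(item, SynthFrame):
            image_id = f"synth_{i:04d}"
            label = item.label
        else:
            image_id = Path(str(item)).stem
            label = labels[i] if labels is not None else "unknown"
        t0 = time.perf_counter()  # logged only; kept out of the manifest
        try:
            img = (
                item.to_lab(fov=cfg.fov)
                if isinstance(item, SynthFrame)
                else image_core.load_image(item, fov=cfg.fov, fov_threshold=cfg.fov_threshold)
            )
            sal, pts, seg, regs, descs = extract_image_features(img, cfg)
        except Exception as exc:  # keep the batch going; record the failure
            log.error("stage failure on %s: %s", image_id, exc)
            manifest["errors"].append({"image_id": image_id, "error": str(exc)})
            continue
        points_to_frame(pts).to_csv(out / f"{image_id}_points.csv", index=False)
        image_core.save_saliency_png(sal.values, out / f"{image_id}_sarc.png")
        for r, d in zip(regs, descs):
            desc_rows.append(
                [image_id, label, r.representative.row, r.representative.col, *d.vector]
            )
        per_image_desc[image_id] = (
            np.array([d.vector for d in descs]) if descs else np.zeros((0, 9))
        )
        manifest["images"].append(
            {
                "image_id": image_id,
                "label": label,
                "n_points": len(pts),
                "n_regions": len(regs),
                "n_superpixels": seg.n_segments,
            }
        )
        log.info(
            "%s: %d points, %d regions (%.2fs)",
            image_id, len(pts), len(regs), time.perf_counter() - t0,
        )

    desc_df = pd.DataFrame(desc_rows, columns=_DESC_COLUMNS)
    desc_df.to_csv(out / "descriptors.csv", index=False)

    all_desc = (
        np.concatenate([v for v in per_image_desc.values() if len(v)])
        if any(len(v) for v in per_image_desc.values())
        else np.zeros((0, 9))
    )
    k = min(cfg.k_vocab, len(all_desc))
    if k >= 2:
        vocab = features.build_vocabulary(all_desc, k=k, seed=cfg.vocab_seed)
        pd.DataFrame(vocab.words).to_csv(out / "vocabulary.csv", index=False)
        hist_rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for image_id, descs_arr in per_image_desc.items():
                h = features.bovw_histogram(descs_arr, vocab)
                hist_rows.append([image_id, h.n_descriptors, *h.frequencies])
        pd.DataFrame(
            hist_rows, columns=["image_id", "n_descriptors", *map(str, range(k))]
        ).to_csv(out / "bovw_histograms.csv", index=False)
        manifest["vocabulary_size"] = k
    else:
        manifest["vocabulary_size"] = 0

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
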