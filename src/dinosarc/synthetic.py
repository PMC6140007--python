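"""Synthetic capsule-endoscopy frames with planted lesions and truth masks.

The generator reproduces the statistical structure the saliency method
assumes, without attempting photorealism:

* a circular field of view on a black border, as produced by capsule optics;
* a mucosa-like background whose chromatic channels are smooth low-frequency
  random fields with a uniform marginal over a bounded per-image range
  [center - spread, center + spread]; the per-image center is drawn at
  dataset level, so per-image chromatic ranges differ frame to frame while
  the class-conditional ranges pooled over a dataset overlap;
* a radial lightness falloff emulating the varying distance/angle of the
  endoscope from the tissue;
* for abnormal frames, a soft-edged elliptical lesion whose chromatic values
  sit *beyond* the background extremum of one axis (positive_a, negative_a,
  positive_b or negative_b) by a margin offset, so that within each frame
  the abnormal and normal chromatic histograms are non-overlapping on that
  axis, while across frames the lesion color varies with the background.

Every artifact is a pure function of its seed(s); ``truth_meta`` records the
clean (pre-noise) background extrema and lesion extrema on the lesion axis
for parameter-recovery checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from scipy.special import ndtr
from skimage import color as skcolor

from .errors import DomainError, ParameterError
from .image_core import LabImage, lab_image_from_rgb

__all__ = [
    "LESION_KINDS",
    "SynthConfig",
    "SynthFrame",
    "generate_frame",
    "generate_dataset",
    "class_conditional_histograms",
]

LESION_KINDS = ("positive_a", "negative_a", "positive_b", "negative_b")

#: Lesion chroma ramps from RIM_FACTOR*offset at the rim to 1.0*offset in the
#: core, measured beyond the background extremum: the rim floor keeps the
#: planted per-image gap wide relative to pixel noise.
RIM_FACTOR = 0.75


@dataclass(frozen=True)
class SynthConfig:
    """One frame's generating parameters.

    size
        Frame dimensions in pixels; 360 x 360 matches MiroCam capsule frames.
    base_ab_center
        Per-image chromatic center (a, b).  At dataset level these are drawn
        from U[-3, 3]^2 so each frame's background range straddles zero on
        both axes (see the module docstring) while pooled ranges overlap
        across frames.
    base_ab_spread
        Half-range of the background chroma around the center (units of
        a/b); backgrounds occupy [center - spread, center + spread].
    lesion_kind
        Axis and direction of the planted chromatic shift, or None for a
        normal frame.
    lesion_margin_offset
        Chromatic distance of the lesion core beyond the background extremum.
    lesion_radius
        Semi-major axis of the elliptical lesion, pixels.
    illumination
        Amplitude of the radial lightness falloff (L units, center to rim).
    noise_sigma
        Per-pixel Gaussian noise on the chromatic channels (a/b units).
    """

    size: tuple[int, int] = (360, 360)
    base_ab_center: tuple[float, float] = (0.0, 0.0)
    base_ab_spread: float = 5.0
    lesion_kind: Optional[str] = "positive_a"
    lesion_margin_offset: float = 10.0
    lesion_radius: float = 10.0
    illumination: float = 25.0
    noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_kind is not None and self.lesion_kind not in LESION_KINDS:
            raise ParameterError(f"unknown lesion_kind {self.lesion_kind!r}")
        if self.lesion_kind is not None and self.lesion_margin_offset <= 0:
            raise ParameterError("lesion_margin_offset must be positive")
        if self.base_ab_spread <= 0:
            raise ParameterError("base_ab_spread must be positive")


@dataclass(frozen=True)
class SynthFrame:
    """A generated frame: sRGB raster, truth mask, label, and realized
    generating values."""

    rgb: np.ndarray  # (M, N, 3) uint8
    lesion_mask: np.ndarray  # bool; all-false for normal frames
    label: str  # "normal" | "abnormal"
    truth_meta: dict = field(repr=False)

    def to_lab(self, fov: bool = True) -> LabImage:
        """Re-derive the Lab representation the pipeline will see."""
        return lab_image_from_rgb(self.rgb, fov=fov)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Smooth low-frequency field with a uniform marginal on [-1, 1].

    A Gaussian random field is low-pass filtered and mapped through the
    normal CDF (probability integral transform), yielding a spatially smooth
    texture whose per-image histogram is a flat plateau over a bounded range
    — the structure the saliency method assumes of normal mucosa, with a
    definite chromatic margin and no interior modes.
    """
    g = ndi.gaussian_filter(rng.standard_normal(shape), sigma=min(shape) / 12.0)
    std = g.std()
    if std == 0:
        return np.zeros(shape)
    return 2.0 * ndtr(g / std) - 1.0


def _fov_disk(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, float]:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    dist = np.hypot(rr - cy, cc - cx)
    radius = 0.48 * min(h, w)
    return dist <= radius, dist / radius, radius


def _plant_lesion(
    rng: np.random.Generator,
    cfg: SynthConfig,
    a: np.ndarray,
    b: np.ndarray,
    L: np.ndarray,
    fov: np.ndarray,
    radius_fov: float,
) -> tuple[np.ndarray, dict]:
    h, w = a.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    margin = 1.8 * cfg.lesion_radius
    if margin >= radius_fov:
        raise ParameterError(
            f"lesion_radius {cfg.lesion_radius} cannot fit inside the fov disk"
        )
    # Uniform position within the disk that keeps the lesion fully inside.
    rho = np.sqrt(rng.uniform()) * (radius_fov - margin)
    ang = rng.uniform(0.0, 2.0 * np.pi)
    ly, lx = cy + rho * np.sin(ang), cx + rho * np.cos(ang)
    ecc = rng.uniform(0.6, 1.0)
    theta = rng.uniform(0.0, np.pi)
    rr, cc = np.mgrid[0:h, 0:w]
    u = (cc - lx) * np.cos(theta) + (rr - ly) * np.sin(theta)
    v = -(cc - lx) * np.sin(theta) + (rr - ly) * np.cos(theta)
    d = np.sqrt((u / cfg.lesion_radius) ** 2 + (v / (cfg.lesion_radius * ecc)) ** 2)
    mask = (d <= 1.0) & fov
    if not mask.any():
        raise DomainError("degenerate lesion: no pixels inside the fov disk")
    # Graded interior: smoothstep from the rim (w=0) to the core (w=1).
    t = np.clip((1.0 - d) / 0.35, 0.0, 1.0)
    wgt = t * t * (3.0 - 2.0 * t)

    axis, direction = cfg.lesion_kind.split("_")[1], cfg.lesion_kind.split("_")[0]
    channel = a if axis == "a" else b
    bg = channel[fov & ~mask]
    off = cfg.lesion_margin_offset
    if direction == "positive":
        ref = float(bg.max())
        values = ref + off * (RIM_FACTOR + (1.0 - RIM_FACTOR) * wgt)
    else:
        ref = float(bg.min())
        values = ref - off * (RIM_FACTOR + (1.0 - RIM_FACTOR) * wgt)
    channel[mask] = values[mask]
    L[mask] -= 8.0 * wgt[mask]  # lesions read slightly darker
    meta = {
        "lesion_center": (float(ly), float(lx)),
        "lesion_axes": (float(cfg.lesion_radius), float(cfg.lesion_radius * ecc)),
        "lesion_rotation": float(theta),
        "lesion_axis": axis,
        "lesion_direction": direction,
        "background_ref": ref,
        "background_min": float(bg.min()),
        "background_max": float(bg.max()),
        "lesion_min": float(channel[mask].min()),
        "lesion_max": float(channel[mask].max()),
    }
    return mask, meta


def generate_frame(cfg: SynthConfig) -> SynthFrame:
    """Render one frame from its configuration (bit-deterministic in the
    seed)."""
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.size
    fov, r_norm, radius_fov = _fov_disk((h, w))
    ca, cb = cfg.base_ab_center
    a = ca + cfg.base_ab_spread * _smooth_field(rng, (h, w))
    b = cb + cfg.base_ab_spread * _smooth_field(rng, (h, w))
    L = 58.0 - cfg.illumination * np.clip(r_norm, 0.0, 1.0) ** 2
    L += 4.0 * _smooth_field(rng, (h, w))

    meta: dict = {
        "config": {
            "size": list(cfg.size),
            "base_ab_center": [float(ca), float(cb)],
            "base_ab_spread": float(cfg.base_ab_spread),
            "lesion_kind": cfg.lesion_kind,
            "lesion_margin_offset": float(cfg.lesion_margin_offset),
            "lesion_radius": float(cfg.lesion_radius),
            "illumination": float(cfg.illumination),
            "noise_sigma": float(cfg.noise_sigma),
            "seed": int(cfg.seed),
        }
    }
    if cfg.lesion_kind is not None:
        mask, lesion_meta = _plant_lesion(rng, cfg, a, b, L, fov, radius_fov)
        meta.update(lesion_meta)
        label = "abnormal"
    else:
        mask = np.zeros((h, w), dtype=bool)
        label = "normal"

    # Clean (pre-noise) per-channel extrema over the background, for
    # parameter-recovery diagnostics.
    bg_pix = fov & ~mask
    meta["clean_background"] = {
        "a": (float(a[bg_pix].min()), float(a[bg_pix].max())),
        "b": (float(b[bg_pix].min()), float(b[bg_pix].max())),
    }

    if cfg.noise_sigma > 0:
        a = a + rng.normal(0.0, cfg.noise_sigma, (h, w))
        b = b + rng.normal(0.0, cfg.noise_sigma, (h, w))
        L = L + rng.normal(0.0, 0.5 * cfg.noise_sigma, (h, w))

    L = np.clip(L, 1.0, 99.0)
    lab = np.dstack([L, a, b])
    lab[~fov] = 0.0
    rgb = np.clip(skcolor.lab2rgb(lab), 0.0, 1.0)
    rgb = (rgb * 255.0).round().astype(np.uint8)
    rgb[~fov] = 0
    return SynthFrame(rgb=rgb, lesion_mask=mask, label=label, truth_meta=meta)


def generate_dataset(
    n_abnormal: int,
    n_normal: int,
    dataset_seed: int = 0,
    kind_mix: Optional[dict[str, float]] = None,
    base: SynthConfig | None = None,
) -> list[SynthFrame]:
    """Generate a dataset of frames with per-frame resampled parameters.

    Per-frame chromatic centers are drawn from U[-3, 3]^2 and lesion radii
    from U[6, 14] pixels (covering the small-lesion regime below typical
    superpixel scale), so pooled abnormal/normal chromatic ranges overlap
    across the dataset while each abnormal frame remains separable within
    itself.  Reproducible from ``dataset_seed``; abnormal frames come first.
    """
    if n_abnormal < 0 or n_normal < 0:
        raise ParameterError("frame counts must be >= 0")
    base = base or SynthConfig()
    rng = np.random.default_rng(dataset_seed)
    kinds = list(LESION_KINDS)
    if kind_mix is None:
        probs = np.full(len(kinds), 1.0 / len(kinds))
    else:
        probs = np.array([kind_mix.get(k, 0.0) for k in kinds], dtype=float)
        if probs.sum() <= 0:
            raise ParameterError("kind_mix must give positive total probability")
        probs = probs / probs.sum()
    frames = []
    for i in range(n_abnormal + n_normal):
        abnormal = i < n_abnormal
        cfg = replace(
            base,
            base_ab_center=tuple(rng.uniform(-3.0, 3.0, size=2)),
            lesion_kind=str(rng.choice(kinds, p=probs)) if abnormal else None,
            lesion_radius=float(rng.uniform(6.0, 14.0)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        frames.append(generate_frame(cfg))
    return frames


def class_conditional_histograms(
    frames: list[SynthFrame], bin_width: float = 1.0
) -> dict[str, dict]:
    """Pooled normalized chromatic histograms of abnormal (H^A) and normal
    (H^N) pixels.

    H^A pools lesion-mask pixels, H^N pools non-lesion fov pixels, across
    all frames.  Returns, per component c in {a, b}, a dict with keys
    ``edges``, ``h_abnormal`` (None if no abnormal pixels) and ``h_normal``.
    """
    if not frames:
        raise DomainError("need at least one frame")
    ab_vals = {"a": [], "b": []}
    nm_vals = {"a": [], "b": []}
    for f in frames:
        img = f.to_lab()
        for name, channel in (("a", img.a), ("b", img.b)):
            ab_vals[name].append(channel[f.lesion_mask & img.fov_mask])
            nm_vals[name].append(channel[img.fov_mask & ~f.lesion_mask])
    out: dict[str, dict] = {}
    for name in ("a", "b"):
        ab = np.concatenate(ab_vals[name])
        nm = np.concatenate(nm_vals[name])
        all_vals = np.concatenate([ab, nm])
        lo, hi = np.floor(all_vals.min()), np.ceil(all_vals.max())
        n_bins = max(1, int(np.ceil((hi - lo) / bin_width - 1e-12)))
        edges = lo + bin_width * np.arange(n_bins + 1)
        h_n, _ = np.histogram(nm, bins=edges)
        entry = {"edges": edges, "h_normal": h_n / h_n.sum()}
        if ab.size == 0:
            warnings.warn("no abnormal pixels: H^A is empty", stacklevel=2)
            entry["h_abnormal"] = None
        else:
            h_a, _ = np.histogram(ab, bins=edges)
            entry["h_abnormal"] = h_a / h_a.sum()
        out[name] = entry
    return out


def histogram_overlap(h1: np.ndarray, h2: np.ndarray) -> float:
    """Overlap coefficient sum(min(h1, h2)) of two aligned normalized
    histograms."""
    return float(np.minimum(h1, h2).sum())
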