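"""Image I/O, CIE-Lab conversion, and the circular field-of-view mask.

Capsule-endoscopy frames are stored as sRGB rasters whose optics produce a
bright circular field of view (fov) surrounded by dark corners.  Every
downstream stage works on the CIE-Lab representation (D65 reference white):
lightness ``L`` in [0, 100] and the opponent chromatic axes ``a``
(green <-> red) and ``b`` (blue <-> yellow) on the standard signed scale, so
that ``a > 0`` reads as "quantity of red".  Pixels outside the fov mask are
ignored everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage as ndi
from skimage import color as skcolor

from .errors import FormatError

__all__ = [
    "LabImage",
    "load_image",
    "estimate_fov_mask",
    "lab_image_from_rgb",
    "save_mask_png",
    "save_saliency_png",
]

#: Default intensity level (out of 255) below which a pixel is considered
#: part of the dark border outside the optics.
DEFAULT_FOV_THRESHOLD = 10


@dataclass(frozen=True)
class LabImage:
    """A CIE-Lab image plus the per-pixel validity mask.

    Attributes
    ----------
    L, a, b : (M, N) float arrays
        Lightness and the two chromatic channels.
    fov_mask : (M, N) bool array
        True where tissue is visible (inside the circular field of view).
    """

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray
    fov_mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.L.shape, self.a.shape, self.b.shape, self.fov_mask.shape}
        if len(shapes) != 1:
            raise FormatError(f"channel shapes differ: {shapes}")
        if self.L.ndim != 2:
            raise FormatError("LabImage channels must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.L.shape

    @property
    def height(self) -> int:
        return self.L.shape[0]

    @property
    def width(self) -> int:
        return self.L.shape[1]

    def lab_stack(self) -> np.ndarray:
        """Return the (M, N, 3) Lab array."""
        return np.dstack([self.L, self.a, self.b])

    def to_rgb(self) -> np.ndarray:
        """Convert back to an 8-bit sRGB array (pixels outside the fov are
        converted as-is; the caller may blank them)."""
        rgb = skcolor.lab2rgb(self.lab_stack())
        return (np.clip(rgb, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def estimate_fov_mask(rgb: np.ndarray, threshold: int = DEFAULT_FOV_THRESHOLD) -> np.ndarray:
    """Estimate the circular field-of-view mask of a capsule frame.

    A pixel is "lit" when any sRGB channel exceeds ``threshold``.  The mask is
    the largest connected component of lit pixels with holes filled, which for
    capsule frames recovers the centered optics disk.

    Parameters
    ----------
    rgb : (M, N, 3) uint8 array
    threshold : int
        Intensity level (0-255) separating the dark border from tissue.

    Returns
    -------
    (M, N) bool array.  An entirely dark frame yields an all-false mask and a
    warning.
    """
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise FormatError(f"expected an M x N x 3 image, got shape {rgb.shape}")
    lit = rgb.max(axis=2) > threshold
    if not lit.any():
        warnings.warn("entirely dark image: field-of-view mask is empty", stacklevel=2)
        return np.zeros(rgb.shape[:2], dtype=bool)
    labels, n = ndi.label(lit)
    if n > 1:
        sizes = ndi.sum_labels(lit, labels, index=np.arange(1, n + 1))
        lit = labels == (int(np.argmax(sizes)) + 1)
    return ndi.binary_fill_holes(lit)


def lab_image_from_rgb(
    rgb: np.ndarray,
    fov: bool = True,
    fov_threshold: int = DEFAULT_FOV_THRESHOLD,
) -> LabImage:
    """Convert an 8-bit sRGB array to a :class:`LabImage`.

    ``fov=False`` disables border masking (all pixels valid).
    """
    if rgb.ndim == 2:
        raise FormatError("grayscale input (1 channel); 3 color channels required")
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        nchan = rgb.shape[2] if rgb.ndim == 3 else rgb.ndim
        raise FormatError(f"expected 3 color channels, got {nchan}")
    lab = skcolor.rgb2lab(rgb)  # D65 reference white, L in [0, 100]
    if fov:
        mask = estimate_fov_mask(rgb, threshold=fov_threshold)
    else:
        mask = np.ones(rgb.shape[:2], dtype=bool)
    return LabImage(L=lab[..., 0], a=lab[..., 1], b=lab[..., 2], fov_mask=mask)


def load_image(
    path: str | Path,
    fov: bool = True,
    fov_threshold: int = DEFAULT_FOV_THRESHOLD,
) -> LabImage:
    """Read a PNG/PPM/JPEG frame and convert it to CIE-Lab.

    Raises ``OSError`` for unreadable files and :class:`FormatError` for
    images without exactly 3 color channels.
    """
    with Image.open(path) as im:
        im.load()
        if im.mode in ("L", "I", "I;16", "F", "1"):
            raise FormatError(
                f"{path}: grayscale input (1 channel); 3 color channels required"
            )
        if im.mode in ("LA", "RGBA", "P", "PA", "CMYK"):
            nchan = len(im.getbands())
            raise FormatError(
                f"{path}: expected 3 color channels, got {nchan} (mode {im.mode})"
            )
        rgb = np.asarray(im.convert("RGB") if im.mode != "RGB" else im)
    return lab_image_from_rgb(rgb, fov=fov, fov_threshold=fov_threshold)


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as a single-channel 0/255 PNG."""
    Image.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(path)


def save_saliency_png(values: np.ndarray, path: str | Path) -> None:
    """Write a nonnegative map as 16-bit PNG, scaled to the full range."""
    v = np.asarray(values, dtype=float)
    top = v.max()
    scaled = np.zeros_like(v) if top <= 0 else v / top
    Image.fromarray((scaled * 65535.0).round().astype(np.uint16)).save(path)


def load_mask_png(path: str | Path) -> np.ndarray:
    """Read a 0/255 single-channel PNG back into a boolean mask."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 127
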