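"""Image preprocessing: grayscale inversion, intensity correction, ROI, morphology.

The goal of this stage is a clean binary image of the projected gridlines.
Endoscopic illumination is strongly non-uniform, so a global threshold on the
raw (inverted) grayscale image loses lines wherever the local background
approaches the line intensity.  The intensity-correction step re-centres
every pixel on its local neighbourhood mean,

    I_new = 255 - ((I_ave - I_c) / 2 + 127),

which maps background to a flat 128 and lines to 128 plus half their local
contrast, making a single global threshold work across the whole image.
The neighbourhood must be large relative to the line width so that the local
mean tracks the background rather than the line itself.

Region-of-interest (ROI) detection thresholds the corrected image, closes it
morphologically so the line lattice merges into one solid blob, keeps the
largest connected component and fills its holes.  Restricting all later
stages to this mask removes real-but-irrelevant image structure (glints,
markings, instruments) that would otherwise produce false junctions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import closing, disk


def _binary_close_disk(binary: np.ndarray, radius: float) -> np.ndarray:
    """Binary closing with a Euclidean disk via two distance transforms.

    Equivalent to dilation-then-erosion with a disk of the given radius but
    O(N) regardless of the radius, which matters for the large ROI-bridging
    elements.
    """
    dilated = ndimage.distance_transform_edt(~binary) <= radius
    return ndimage.distance_transform_edt(dilated) > radius

from .errors import ConfigError, NoPatternFoundError

__all__ = [
    "to_gray_inverted",
    "intensity_correct",
    "binarize",
    "detect_roi",
    "clean_binary",
    "RoiMask",
    "contrast_variance",
]

# ITU-R 601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


def to_gray_inverted(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit gray or RGB image to inverted grayscale (uint8).

    Dark gridlines become bright so that thinning/junction detection can
    treat them as foreground.
    """
    img = np.asarray(image)
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.floating) and img.size and img.max() <= 255:
            img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        else:
            raise ConfigError(f"unsupported image dtype {img.dtype}; expected 8-bit")
    if img.ndim == 3:
        if img.shape[2] == 4:
            img = img[:, :, :3]
        if img.shape[2] != 3:
            raise ConfigError(f"expected 1 or 3 channels, got {img.shape[2]}")
        gray = np.rint(img.astype(float) @ _LUMA).astype(np.uint8)
    elif img.ndim == 2:
        gray = img
    else:
        raise ConfigError(f"expected a 2D or 3D raster, got ndim={img.ndim}")
    return (255 - gray.astype(np.int16)).astype(np.uint8)


def intensity_correct(
    image: np.ndarray, window: int = 31, *, mode: str = "half"
) -> np.ndarray:
    """Equalize line/background contrast against the local mean.

    ``I_ave`` is the mean over a ``window x window`` box centred on each
    pixel with reflected borders.  ``mode='half'`` applies
    ``255 - ((I_ave - I_c)/2 + 127)`` (default; keeps the full difference
    range in byte range).  ``mode='squared'`` applies the literal squared
    variant ``255 - ((I_ave - I_c)**2 + 127)``, kept for comparison — it
    saturates for local contrasts above ~11 gray levels.
    """
    if window < 3 or window % 2 == 0:
        raise ConfigError(f"window must be odd and >= 3, got {window}")
    if mode not in ("half", "squared"):
        raise ConfigError(f"unknown intensity-correction mode {mode!r}")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ConfigError("intensity_correct expects a single-channel image")
    ave = ndimage.uniform_filter(img, size=window, mode="reflect")
    diff = ave - img
    term = diff / 2.0 if mode == "half" else diff**2
    out = 255.0 - (term + 127.0)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def binarize(
    image: np.ndarray,
    method: str = "otsu",
    level: float | None = None,
    *,
    mask: np.ndarray | None = None,
    background_k: float = 3.0,
) -> np.ndarray:
    """Threshold a grayscale image; foreground = pixels strictly above threshold.

    Methods:

    * ``'otsu'`` — threshold from the histogram (restricted to ``mask`` if
      given).  A constant image has no separable classes and raises
      :class:`NoPatternFoundError`.
    * ``'fixed'`` — explicit ``level``.
    * ``'background'`` — for *intensity-corrected* images, whose background
      sits at 127.5 by construction: threshold = 127.5 + ``background_k``
      times a robust noise estimate (1.4826 x median absolute deviation of
      the samples).  Unlike Otsu this never migrates into the line class
      when the background is nearly constant.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ConfigError("binarize expects a single-channel image")
    samples = img[mask] if mask is not None else img
    if method == "otsu":
        if samples.size == 0 or np.all(samples == samples.reshape(-1)[0]):
            raise NoPatternFoundError("constant image: Otsu has no separable classes")
        thr = threshold_otsu(samples)
    elif method == "fixed":
        if level is None or not (0 <= level <= 255):
            raise ConfigError("fixed thresholding needs level in [0, 255]")
        thr = level
    elif method == "background":
        if samples.size == 0:
            raise NoPatternFoundError("empty sample set for background thresholding")
        # noise scale from horizontal first differences (robust, insensitive
        # to slowly varying structure); the 3-level floor guards against
        # residual shading curvature the local-mean correction cannot flatten
        diffs = np.diff(img.astype(float), axis=1)
        if mask is not None:
            m = mask.astype(bool)
            diffs = diffs[m[:, 1:] & m[:, :-1]]
        sigma = 1.4826 * np.median(np.abs(diffs)) / np.sqrt(2.0) if diffs.size else 0.0
        thr = 127.5 + max(background_k * sigma, 3.0)
    else:
        raise ConfigError(f"unknown threshold method {method!r}")
    fg = img > thr
    if mask is not None:
        fg &= mask.astype(bool)
    return fg


@dataclass(frozen=True)
class RoiMask:
    """Binary mask of the pattern region plus its bounding box (row/col slices)."""

    mask: np.ndarray
    bbox: tuple[int, int, int, int]  # rmin, rmax, cmin, cmax (inclusive)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def detect_roi(
    image: np.ndarray,
    close_radius: int = 18,
    min_area_fraction: float = 0.02,
    *,
    threshold_method: str = "otsu",
    min_component: int = 25,
) -> RoiMask:
    """Locate the region covered by the projected pattern.

    Threshold -> drop foreground specks below ``min_component`` pixels (a
    large closing element would otherwise chain isolated noise pixels into
    one image-wide blob) -> morphological closing with a disk of
    ``close_radius`` (the dilation bridges inter-line gaps, the erosion
    restores the outline) -> keep the largest connected component -> fill
    holes.  ``close_radius`` must be at least half the inter-line spacing in
    image pixels for the lattice to merge into one blob.
    """
    if close_radius < 1:
        raise ConfigError("close_radius must be >= 1")
    try:
        binary = binarize(image, threshold_method)
    except NoPatternFoundError as exc:
        raise NoPatternFoundError(f"no pattern found: {exc}") from exc
    if min_component > 0:
        labs, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
        if n:
            counts = np.bincount(labs.reshape(-1))
            counts[0] = 0
            binary = counts[labs] >= min_component
    closed = _binary_close_disk(binary, close_radius)
    labels = label(closed, connectivity=2)
    if labels.max() == 0:
        raise NoPatternFoundError("no foreground region after closing")
    counts = np.bincount(labels.reshape(-1))
    counts[0] = 0
    biggest = int(np.argmax(counts))
    mask = labels == biggest
    if counts[biggest] < min_area_fraction * mask.size:
        raise NoPatternFoundError(
            f"largest region covers {counts[biggest] / mask.size:.2%} of the image, "
            f"below the {min_area_fraction:.2%} minimum"
        )
    mask = ndimage.binary_fill_holes(mask)
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    rmin, rmax = np.nonzero(rows)[0][[0, -1]]
    cmin, cmax = np.nonzero(cols)[0][[0, -1]]
    return RoiMask(mask=mask, bbox=(int(rmin), int(rmax), int(cmin), int(cmax)))


def clean_binary(
    image: np.ndarray, radius: int = 1, min_size: int = 0, max_hole: int = 0
) -> np.ndarray:
    """Morphological cleanup of the gridline binary image.

    Closing with a disk of ``radius`` bridges small gaps in lines and
    smooths protrusions below the structuring-element scale.  With
    ``min_size > 0`` connected components smaller than that many pixels are
    removed first — stray foreground pixels away from the gridlines would
    otherwise survive thinning and show up as spurious skeleton branches.
    With ``max_hole > 0`` background holes smaller than that many pixels are
    filled afterwards (the open cells of the line lattice are far larger
    than ``max_hole`` and stay open).  Idempotent when applied twice.
    """
    if radius < 1:
        raise ConfigError("radius must be >= 1")
    img = np.asarray(image).astype(bool)
    eight = np.ones((3, 3), dtype=int)
    if min_size > 0:
        labels, n = ndimage.label(img, structure=eight)
        if n:
            counts = np.bincount(labels.reshape(-1))
            counts[0] = 0
            img = counts[labels] >= min_size
    img = closing(img, disk(radius))
    if max_hole > 0:
        # 4-connected background components not touching the border and
        # smaller than max_hole are holes to fill
        holes, n = ndimage.label(~img)
        if n:
            counts = np.bincount(holes.reshape(-1))
            border = np.unique(
                np.concatenate([holes[0], holes[-1], holes[:, 0], holes[:, -1]])
            )
            small = counts <= max_hole
            small[border] = False
            small[0] = False
            img = img | small[holes]
    return img


def contrast_variance(
    image: np.ndarray,
    line_mask: np.ndarray,
    tiles: tuple[int, int] = (6, 6),
    min_pixels: int = 20,
) -> float:
    """Variance of per-tile line/background contrast.

    The image is split into a ``tiles`` grid; in every tile containing
    enough line and background pixels the contrast is the difference of
    their mean intensities.  A spatially uniform image has low variance —
    the quantity the intensity-correction step is meant to reduce.
    """
    img = np.asarray(image, dtype=float)
    lm = np.asarray(line_mask, dtype=bool)
    H, W = img.shape
    contrasts = []
    for i in range(tiles[0]):
        for j in range(tiles[1]):
            rs = slice(i * H // tiles[0], (i + 1) * H // tiles[0])
            cs = slice(j * W // tiles[1], (j + 1) * W // tiles[1])
            tile_lm = lm[rs, cs]
            if tile_lm.sum() < min_pixels or (~tile_lm).sum() < min_pixels:
                continue
            tile = img[rs, cs]
            contrasts.append(tile[tile_lm].mean() - tile[~tile_lm].mean())
    if len(contrasts) < 2:
        raise ConfigError("too few usable tiles to estimate contrast variance")
    return float(np.var(contrasts))
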