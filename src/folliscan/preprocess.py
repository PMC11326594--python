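"""Grayscale conversion, CLAHE contrast enhancement and Gaussian denoising.

Abdominal ultrasound is dominated by multiplicative speckle, which both
obscures follicle boundaries and compresses local contrast.  The standard
remedy chain used here is: collapse any colour channels to luminance,
stretch local contrast with contrast-limited adaptive histogram
equalization (CLAHE), then suppress high-frequency speckle with a small
Gaussian blur before clustering.

All operations are deterministic and keep intensities inside [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "GrayImage",
    "ClaheParams",
    "PreprocessConfig",
    "to_grayscale",
    "clahe",
    "gaussian_smooth",
    "preprocess_image",
]

# ITU-R BT.601 luma weights for RGB -> gray.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class GrayImage:
    """A 2-D grayscale image with intensities in [0, 255].

    Parameters
    ----------
    pixels
        2-D float array of intensities in [0, 255].
    pixel_spacing
        Physical size of one pixel in mm/px, or ``None`` when unknown.
        Needed only by size-aware stages (mm-based follicle filtering).
    """

    pixels: np.ndarray
    pixel_spacing: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("GrayImage requires a non-empty 2-D array")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        if self.pixel_spacing is not None and self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def to_uint8(self) -> np.ndarray:
        return np.clip(np.rint(self.pixels), 0, 255).astype(np.uint8)


def _as_gray(image: GrayImage | np.ndarray) -> GrayImage:
    if isinstance(image, GrayImage):
        return image
    return GrayImage(np.asarray(image, dtype=float))


@dataclass
class ClaheParams:
    """CLAHE tiling and clipping parameters.

    ``clip_limit`` is expressed as a multiple of the mean histogram bin
    count of a tile; ``math.inf`` disables clipping entirely (plain
    adaptive histogram equalization).
    """

    tile_grid: tuple[int, int] = (8, 8)
    clip_limit: float = 2.0
    n_bins: int = 256

    def __post_init__(self) -> None:
        r, c = self.tile_grid
        if r < 1 or c < 1:
            raise ValueError("tile_grid must be >= 1 in both directions")
        if not self.clip_limit > 0:
            raise ValueError("clip_limit must be positive")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def to_grayscale(image: np.ndarray | GrayImage) -> GrayImage:
    """Collapse a colour image to single-channel luminance.

    2-D input passes through unchanged; H x W x 3 input is reduced with
    the ITU-R BT.601 weights (0.299, 0.587, 0.114) and rounded to the
    nearest integer gray level.
    """
    if isinstance(image, GrayImage):
        return image
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        return GrayImage(arr)
    if arr.ndim == 3 and arr.shape[2] == 3:
        return GrayImage(np.rint(arr @ _LUMA))
    raise ValueError(f"unsupported input shape {arr.shape}: expected 2-D or H x W x 3")


def _tile_mapping(tile: np.ndarray, params: ClaheParams) -> np.ndarray:
    """Clipped-histogram equalization mapping for one tile.

    Returns a 256-entry lookup table gray level -> equalized gray level,
    built as ``round(255 * cdf)`` of the clipped histogram.  Excess mass
    above the clip ceiling is redistributed uniformly over all bins.
    """
    hist, _ = np.histogram(tile, bins=params.n_bins, range=(0, 256))
    hist = hist.astype(float)
    if np.isfinite(params.clip_limit):
        ceiling = params.clip_limit * tile.size / params.n_bins
        excess = np.clip(hist - ceiling, 0, None).sum()
        hist = np.minimum(hist, ceiling) + excess / params.n_bins
    cdf = np.cumsum(hist) / hist.sum()
    lut_bins = np.rint(255.0 * cdf)
    # expand to a per-gray-level table (bins may be coarser than 256)
    levels = np.minimum((np.arange(256) * params.n_bins) // 256, params.n_bins - 1)
    return lut_bins[levels]


def clahe(image: GrayImage | np.ndarray, params: ClaheParams | None = None) -> GrayImage:
    """Contrast-limited adaptive histogram equalization.

    The image is divided into ``tile_grid`` tiles (reflect-padded to a
    tile multiple when the grid does not divide the image).  Each tile
    gets a clipped-histogram equalization mapping, and every pixel is
    remapped by bilinear interpolation between the mappings of the four
    nearest tile centres, which removes blocking artefacts at tile seams.

    With a single tile and an infinite clip limit this reduces to plain
    global histogram equalization.
    """
    img = _as_gray(image)
    params = params or ClaheParams()
    rows, cols = img.shape
    tr, tc = params.tile_grid
    if rows < tr or cols < tc:
        raise ValueError(
            f"tile grid {params.tile_grid} exceeds image of shape {img.shape}"
        )

    th = -(-rows // tr)  # ceil division: tile height
    tw = -(-cols // tc)
    pad_r, pad_c = th * tr - rows, tw * tc - cols
    padded = np.pad(img.pixels, ((0, pad_r), (0, pad_c)), mode="reflect")

    idx = np.clip(padded.astype(int), 0, 255)
    luts = np.empty((tr, tc, 256))
    for i in range(tr):
        for j in range(tc):
            tile = padded[i * th : (i + 1) * th, j * tw : (j + 1) * tw]
            luts[i, j] = _tile_mapping(tile, params)

    # bilinear blend between tile-centre mappings
    r = np.arange(padded.shape[0])[:, None]
    c = np.arange(padded.shape[1])[None, :]
    # fractional tile coordinate of each pixel relative to tile centres
    fr = np.clip((r - th / 2 + 0.5) / th, 0, tr - 1)
    fc = np.clip((c - tw / 2 + 0.5) / tw, 0, tc - 1)
    r0 = np.floor(fr).astype(int)
    c0 = np.floor(fc).astype(int)
    r1 = np.minimum(r0 + 1, tr - 1)
    c1 = np.minimum(c0 + 1, tc - 1)
    wr = fr - r0
    wc = fc - c0

    r0b, r1b = np.broadcast_to(r0, padded.shape), np.broadcast_to(r1, padded.shape)
    c0b, c1b = np.broadcast_to(c0, padded.shape), np.broadcast_to(c1, padded.shape)
    out = (
        (1 - wr) * (1 - wc) * luts[r0b, c0b, idx]
        + (1 - wr) * wc * luts[r0b, c1b, idx]
        + wr * (1 - wc) * luts[r1b, c0b, idx]
        + wr * wc * luts[r1b, c1b, idx]
    )
    out = np.clip(out[:rows, :cols], 0, 255)
    return GrayImage(out, img.pixel_spacing)


def gaussian_smooth(image: GrayImage | np.ndarray, sigma: float = 1.0) -> GrayImage:
    """Gaussian blur with reflective boundaries; ``sigma=0`` is the identity."""
    img = _as_gray(image)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return GrayImage(img.pixels.copy(), img.pixel_spacing)
    out = ndimage.gaussian_filter(img.pixels, sigma=sigma, mode="reflect")
    return GrayImage(np.clip(out, 0, 255), img.pixel_spacing)


@dataclass
class PreprocessConfig:
    """Which preprocessing steps run, and with what parameters."""

    clahe_enabled: bool = True
    clahe: ClaheParams = field(default_factory=ClaheParams)
    gaussian_sigma: float = 1.0


def preprocess_image(
    image: np.ndarray | GrayImage, config: PreprocessConfig | None = None
) -> GrayImage:
    """Grayscale -> CLAHE -> Gaussian smoothing, per the configured steps."""
    config = config or PreprocessConfig()
    img = to_grayscale(image)
    if config.clahe_enabled:
        img = clahe(img, config.clahe)
    if config.gaussian_sigma > 0:
        img = gaussian_smooth(img, config.gaussian_sigma)
    return img
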