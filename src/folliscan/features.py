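"""Texture and first-order statistics of a segmented region.

Ten features describe each segmented follicle region: four Haralick
statistics of the gray-level co-occurrence matrix (GLCM) — contrast,
correlation, energy and homogeneity — plus GLCM entropy, and five
first-order intensity statistics — mean, variance, standard deviation,
skewness and kurtosis (non-excess).

The GLCM p(i, j) is the joint distribution of quantized gray-level pairs
at a fixed pixel offset.  With marginal means/SDs mu_x, mu_y, sigma_x,
sigma_y:

    contrast     = sum_{i,j} (i - j)^2 p(i, j)
    correlation  = (sum_{i,j} i*j*p(i, j) - mu_x mu_y) / (sigma_x sigma_y)
    energy       = sum_{i,j} p(i, j)^2
    homogeneity  = sum_{i,j} p(i, j) / (1 + (i - j)^2)
    entropy      = -sum_{i,j} p(i, j) ln p(i, j)     (over nonzero entries)

First-order moments use population (1/N) normalization:
skewness = (1/N) sum ((x - mean)/sigma)^3 and
kurtosis = (1/N) sum ((x - mean)/sigma)^4, so a normal distribution has
kurtosis 3.  Degenerate regions (sigma = 0) report skewness and kurtosis
of 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import GrayImage

__all__ = [
    "GLCM",
    "GLCMConfig",
    "FeatureVector",
    "FEATURE_NAMES",
    "quantize",
    "compute_glcm",
    "glcm_features",
    "first_order_features",
    "extract_feature_vector",
]

FEATURE_NAMES = (
    "mean",
    "variance",
    "std_dev",
    "contrast",
    "energy",
    "homogeneity",
    "correlation",
    "entropy",
    "skewness",
    "kurtosis",
)

# (d_row, d_col) unit offsets for the four standard GLCM directions
ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


class EmptyGLCMError(ValueError):
    """Raised when a mask contains no co-occurring in-mask pixel pairs."""


@dataclass
class GLCM:
    """A gray-level co-occurrence matrix and how it was built."""

    matrix: np.ndarray  # (Ng, Ng)
    n_levels: int
    distance: int
    angles: tuple[int, ...]
    symmetric: bool
    normalized: bool


@dataclass
class GLCMConfig:
    n_levels: int = 8
    distance: int = 1
    angles: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True


def quantize(pixels: np.ndarray, n_levels: int = 8) -> np.ndarray:
    """Uniformly bin [0, 255] intensities into integer levels 0..n_levels-1."""
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    arr = np.asarray(pixels, dtype=float)
    levels = np.floor(arr * n_levels / 256.0).astype(int)
    return np.clip(levels, 0, n_levels - 1)


def compute_glcm(
    levels: np.ndarray,
    mask: np.ndarray | None = None,
    distance: int = 1,
    angles: tuple[int, ...] = (0, 45, 90, 135),
    symmetric: bool = True,
    normalize: bool = True,
    n_levels: int | None = None,
) -> GLCM:
    """Co-occurrence counts of level pairs at the given offset(s).

    A pixel pair contributes only when *both* pixels lie inside ``mask``.
    Symmetric mode counts both orderings; multiple angles are accumulated
    into one matrix before normalization.
    """
    lv = np.asarray(levels, dtype=int)
    ng = n_levels if n_levels is not None else int(lv.max()) + 1
    msk = np.ones(lv.shape, bool) if mask is None else np.asarray(mask, bool)
    if msk.shape != lv.shape:
        raise ValueError("mask must match the levels grid")

    counts = np.zeros((ng, ng))
    h, w = lv.shape
    for ang in angles:
        dr, dc = ANGLE_OFFSETS[ang]
        dr, dc = dr * distance, dc * distance
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        src = np.s_[r0:r1, c0:c1]
        dst = np.s_[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = msk[src] & msk[dst]
        i = lv[src][valid]
        j = lv[dst][valid]
        np.add.at(counts, (i, j), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise EmptyGLCMError("mask contains no co-occurring in-mask pixel pairs")
    if normalize:
        counts = counts / total
    return GLCM(
        matrix=counts,
        n_levels=ng,
        distance=distance,
        angles=tuple(angles),
        symmetric=symmetric,
        normalized=normalize,
    )


def glcm_features(glcm: GLCM) -> dict[str, float]:
    """Contrast, correlation, energy, homogeneity and entropy of a GLCM.

    Requires a normalized matrix.  Correlation is defined as 0 when either
    marginal is degenerate (sigma_x * sigma_y = 0).
    """
    if not glcm.normalized:
        raise ValueError("glcm_features requires a normalized GLCM")
    p = glcm.matrix
    ng = p.shape[0]
    i = np.arange(ng)[:, None]
    j = np.arange(ng)[None, :]

    contrast = float(((i - j) ** 2 * p).sum())
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + (i - j) ** 2)).sum())

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((np.arange(ng) * px).sum())
    mu_y = float((np.arange(ng) * py).sum())
    sig_x = float(np.sqrt(((np.arange(ng) - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((np.arange(ng) - mu_y) ** 2 * py).sum()))
    if sig_x * sig_y > 0:
        correlation = float(((i * j * p).sum() - mu_x * mu_y) / (sig_x * sig_y))
    else:
        correlation = 0.0

    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())

    return {
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "homogeneity": homogeneity,
        "entropy": entropy,
    }


def first_order_features(region_pixels: np.ndarray) -> dict[str, float]:
    """Mean, population variance/SD, skewness and non-excess kurtosis."""
    x = np.asarray(region_pixels, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("region is empty")
    mean = float(x.mean())
    var = float(x.var())  # population (1/N)
    std = float(np.sqrt(var))
    if std == 0:
        skew = kurt = 0.0
    else:
        z = (x - mean) / std
        skew = float((z**3).mean())
        kurt = float((z**4).mean())
    return {
        "mean": mean,
        "variance": var,
        "std_dev": std,
        "skewness": skew,
        "kurtosis": kurt,
    }


@dataclass
class FeatureVector:
    """The ten named region features, in table order."""

    mean: float
    variance: float
    std_dev: float
    contrast: float
    energy: float
    homogeneity: float
    correlation: float
    entropy: float
    skewness: float
    kurtosis: float

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


@dataclass
class FeatureConfig:
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    whole_image_fallback: bool = True  # use the full frame when the mask is empty


def extract_feature_vector(
    image: GrayImage | np.ndarray,
    mask: np.ndarray | None = None,
    config: FeatureConfig | None = None,
) -> FeatureVector:
    """All ten features of the masked region of ``image``.

    GLCM statistics are computed on quantized intensities; first-order
    statistics on the raw (unquantized) masked intensities.  An empty mask
    falls back to the whole frame when the config allows it — on a normal
    image with no detected follicles the texture of the full field is
    still informative for classification.
    """
    cfg = config or FeatureConfig()
    px = image.pixels if isinstance(image, GrayImage) else np.asarray(image, dtype=float)
    msk = np.ones(px.shape, bool) if mask is None else np.asarray(mask, bool)
    if not msk.any():
        if not cfg.whole_image_fallback:
            raise ValueError("mask is empty and whole-image fallback is disabled")
        msk = np.ones(px.shape, bool)

    levels = quantize(px, cfg.glcm.n_levels)
    glcm = compute_glcm(
        levels,
        msk,
        distance=cfg.glcm.distance,
        angles=cfg.glcm.angles,
        symmetric=cfg.glcm.symmetric,
        normalize=True,
        n_levels=cfg.glcm.n_levels,
    )
    tex = glcm_features(glcm)
    first = first_order_features(px[msk])
    return FeatureVector(**first, **tex)
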