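"""Hybrid follicle segmentation: fuzzy c-means + active-contour refinement.

The segmentation strategy is a two-stage hybrid.  First, fuzzy c-means
(FCM) partitions the preprocessed image intensities into ``c`` clusters
(default 4); because follicles are fluid-filled and hypoechoic, the
cluster with the darkest centroid is taken as the follicle class (the
choice is configurable).  Second, the boundary of every connected
component of that cluster is refined with a parametric active contour
("snake") driven by the image gradient, which snaps the fuzzy cluster
boundary onto the actual intensity edge.  Components are finally filtered
by equivalent diameter: follicles below 2 mm are clinically disregarded.

FCM minimizes the objective

    J(U, V) = sum_i sum_j  u_ij^m  |x_i - v_j|^2,      sum_j u_ij = 1,

by alternating the closed-form membership and centroid updates; ``m > 1``
is the fuzzifier.  The snake minimizes a discrete Kass-style energy
E = sum alpha |x'|^2 + beta |x''|^2 - G(x) with G the normalized squared
gradient magnitude of the Gaussian-smoothed image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw, measure

from .preprocess import GrayImage

__all__ = [
    "FCMResult",
    "Component",
    "SegmentationMask",
    "SegmentConfig",
    "FCMConfig",
    "SnakeConfig",
    "fcm_cluster",
    "select_follicle_cluster",
    "extract_components",
    "filter_by_size",
    "snake_refine",
    "segment_follicles",
    "count_follicles",
]


# --------------------------------------------------------------------------
# fuzzy c-means
# --------------------------------------------------------------------------


@dataclass
class FCMResult:
    """Outcome of a fuzzy c-means run on image intensities.

    ``centroids`` are sorted ascending by gray level and ``membership``
    columns are permuted consistently.  ``membership`` has one row per
    pixel (row-major flattening of the image).
    """

    centroids: np.ndarray  # (c,)
    membership: np.ndarray  # (n_pixels, c), rows sum to 1
    fuzzifier: float
    objective_trace: np.ndarray  # J per iteration
    iterations: int
    image_shape: tuple[int, int]

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def hard_labels(self) -> np.ndarray:
        """Per-pixel argmax-membership cluster index, as an image grid."""
        return self.membership.argmax(axis=1).reshape(self.image_shape)


def _fcm_objective(x: np.ndarray, u: np.ndarray, v: np.ndarray, m: float) -> float:
    d2 = (x[:, None] - v[None, :]) ** 2
    return float(((u**m) * d2).sum())


def _fcm_membership(x: np.ndarray, v: np.ndarray, m: float) -> np.ndarray:
    """Closed-form membership update; exact 0/1 rows at zero distances."""
    d2 = (x[:, None] - v[None, :]) ** 2
    zero = d2 <= 1e-300
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
    if any_zero.any():
        rows = np.where(any_zero)[0]
        u[rows] = 0.0
        # mass split evenly among coincident zero-distance centroids
        z = zero[rows]
        u[rows] = z / z.sum(axis=1, keepdims=True)
    return u


def fcm_cluster(
    image: GrayImage | np.ndarray,
    c: int = 4,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 100,
    seed: int = 0,
) -> FCMResult:
    """Fuzzy c-means clustering of pixel intensities.

    Memberships are initialized uniformly at random from ``seed`` and the
    standard alternating updates run until the largest centroid shift
    drops below ``tol`` or ``max_iter`` is reached.
    """
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image, dtype=float)
    if pixels.size == 0:
        raise ValueError("cannot cluster an empty image")
    if c < 1:
        raise ValueError("c must be >= 1")
    if not m > 1:
        raise ValueError("fuzzifier m must be > 1")
    if not tol > 0:
        raise ValueError("tol must be positive")
    shape = pixels.shape
    x = pixels.ravel().astype(float)

    if len(np.unique(x)) < c:
        warnings.warn(
            f"c={c} exceeds the number of distinct intensities; "
            "clusters may be degenerate",
            RuntimeWarning,
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    u = rng.random((x.size, c))
    u /= u.sum(axis=1, keepdims=True)

    v = np.empty(c)
    trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        um = u**m
        denom = um.sum(axis=0)
        v_new = np.where(denom > 0, um.T @ x / np.where(denom > 0, denom, 1.0), v if it > 1 else x.mean())
        u = _fcm_membership(x, v_new, m)
        trace.append(_fcm_objective(x, u, v_new, m))
        shift = np.abs(v_new - v).max() if it > 1 else np.inf
        v = v_new
        if shift < tol:
            break

    order = np.argsort(v)
    return FCMResult(
        centroids=v[order],
        membership=u[:, order],
        fuzzifier=m,
        objective_trace=np.asarray(trace),
        iterations=it,
        image_shape=shape,
    )


# --------------------------------------------------------------------------
# masks and components
# --------------------------------------------------------------------------


@dataclass
class Component:
    """One 8-connected foreground region of a segmentation mask."""

    label: int
    area_px: int
    centroid: tuple[float, float]  # (row, col)
    bbox: tuple[int, int, int, int]  # (x, y, w, h): col, row, width, height
    coords: np.ndarray  # (area, 2) pixel coordinates, (row, col)
    contour: np.ndarray  # (k, 2) closed boundary polyline, (row, col)
    equivalent_diameter_px: float
    equivalent_diameter_mm: float | None

    @classmethod
    def _from_regionprops(cls, rp, labeled: np.ndarray, spacing: float | None) -> "Component":
        d_px = 2.0 * np.sqrt(rp.area / np.pi)
        minr, minc, maxr, maxc = rp.bbox
        comp_mask = np.pad(labeled == rp.label, 1)
        contours = measure.find_contours(comp_mask.astype(float), 0.5)
        contour = max(contours, key=len) - 1.0  # undo padding
        return cls(
            label=int(rp.label),
            area_px=int(rp.area),
            centroid=tuple(map(float, rp.centroid)),
            bbox=(int(minc), int(minr), int(maxc - minc), int(maxr - minr)),
            coords=rp.coords.copy(),
            contour=contour,
            equivalent_diameter_px=float(d_px),
            equivalent_diameter_mm=float(d_px * spacing) if spacing else None,
        )


@dataclass
class SegmentationMask:
    """Binary follicle mask plus its 8-connected components."""

    mask: np.ndarray  # bool grid
    pixel_spacing: float | None = None
    components: list[Component] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def foreground_px(self) -> int:
        return int(self.mask.sum())


def select_follicle_cluster(
    fcm: FCMResult,
    strategy: str | int = "darkest",
    gt_mask: np.ndarray | None = None,
) -> SegmentationMask:
    """Hard-assign pixels and pick the follicle cluster.

    Strategies: ``"darkest"`` (default; follicles are hypoechoic),
    an explicit integer index into the ascending-sorted clusters, or
    ``"gt_overlap"`` which picks the cluster maximizing overlap with a
    supplied ground-truth mask (calibration only).
    """
    if fcm.n_clusters < 1:
        raise ValueError("FCM result has no clusters")
    labels = fcm.hard_labels()
    if strategy == "darkest":
        k = 0  # centroids are sorted ascending
    elif strategy == "gt_overlap":
        if gt_mask is None:
            raise ValueError("gt_overlap strategy requires gt_mask")
        overlaps = [(labels == j)[gt_mask].sum() for j in range(fcm.n_clusters)]
        k = int(np.argmax(overlaps))
    elif isinstance(strategy, int):
        if not 0 <= strategy < fcm.n_clusters:
            raise ValueError(f"cluster index {strategy} out of range 0..{fcm.n_clusters - 1}")
        k = strategy
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return SegmentationMask(mask=labels == k)


def extract_components(
    mask: SegmentationMask | np.ndarray, pixel_spacing: float | None = None
) -> SegmentationMask:
    """Label 8-connected regions and populate per-component geometry."""
    if isinstance(mask, SegmentationMask):
        grid = mask.mask
        pixel_spacing = pixel_spacing or mask.pixel_spacing
    else:
        grid = np.asarray(mask, dtype=bool)
    labeled = measure.label(grid, connectivity=2)
    comps = [
        Component._from_regionprops(rp, labeled, pixel_spacing)
        for rp in measure.regionprops(labeled)
    ]
    return SegmentationMask(mask=grid, pixel_spacing=pixel_spacing, components=comps)


def filter_by_size(
    mask: SegmentationMask,
    min_diameter_mm: float = 2.0,
    max_diameter_mm: float = 12.0,
) -> SegmentationMask:
    """Drop components whose equivalent diameter falls outside [min, max] mm.

    The 2 mm floor reflects clinical practice: smaller follicles cannot be
    distinguished from speckle.  The ceiling is the 9 mm anatomical upper
    bound plus tolerance for boundary overshoot.
    """
    if mask.pixel_spacing is None:
        raise ValueError("filter_by_size requires a known pixel spacing (mm/px)")
    if not 0 <= min_diameter_mm < max_diameter_mm:
        raise ValueError("require 0 <= min_diameter_mm < max_diameter_mm")
    keep = [
        c
        for c in mask.components
        if min_diameter_mm <= c.equivalent_diameter_mm <= max_diameter_mm
    ]
    out = np.zeros_like(mask.mask)
    for c in keep:
        out[c.coords[:, 0], c.coords[:, 1]] = True
    return extract_components(out, mask.pixel_spacing)


# --------------------------------------------------------------------------
# active contour (snake)
# --------------------------------------------------------------------------


@dataclass
class SnakeConfig:
    """Active-contour parameters.

    alpha: elasticity (penalizes stretching); beta: rigidity (penalizes
    bending); gamma: step size of the semi-implicit update; sigma:
    Gaussian scale of the external edge field.
    """

    alpha: float = 0.1
    beta: float = 1.0
    # with the edge field normalized to [0, 1], a vertex advances about
    # gamma * |grad field| px per accepted step; gamma of order 1 lets a
    # contour cross the ~2*sigma capture range within the iteration budget
    gamma: float = 1.0
    iterations: int = 250
    sigma: float = 2.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma, self.sigma) < 0 or self.iterations < 0:
            raise ValueError("snake parameters must be non-negative")


def _resample_closed(contour: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Resample a closed polyline to roughly uniform vertex spacing."""
    pts = np.asarray(contour, dtype=float)
    if not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[0]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    n = max(int(round(total / spacing)), 8)
    s = np.linspace(0, total, n, endpoint=False)
    r = np.interp(s, arclen, pts[:, 0])
    c = np.interp(s, arclen, pts[:, 1])
    return np.column_stack([r, c])


def _internal_matrix(n: int, alpha: float, beta: float) -> np.ndarray:
    """Circulant pentadiagonal stiffness matrix of the discrete snake."""
    a = np.zeros(n)
    a[0] = 2 * alpha + 6 * beta
    a[1] = a[-1] = -alpha - 4 * beta
    a[2] = a[-2] = beta
    idx = (np.arange(n)[:, None] - np.arange(n)[None, :]) % n
    return a[idx]


def external_energy_field(image: GrayImage | np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Normalized squared gradient magnitude of the smoothed image.

    Snakes descend the negative of this field, i.e. they are attracted to
    intensity edges.  Normalization to [0, 1] keeps the default
    alpha/beta/gamma meaningful across images.
    """
    px = image.pixels if isinstance(image, GrayImage) else np.asarray(image, dtype=float)
    gr = ndimage.gaussian_filter(px, sigma, order=(1, 0), mode="reflect")
    gc = ndimage.gaussian_filter(px, sigma, order=(0, 1), mode="reflect")
    g2 = gr**2 + gc**2
    peak = g2.max()
    return g2 / peak if peak > 0 else g2


def _snake_energy(pts: np.ndarray, field: np.ndarray, alpha: float, beta: float) -> float:
    d1 = np.roll(pts, -1, axis=0) - pts
    d2 = np.roll(pts, -1, axis=0) - 2 * pts + np.roll(pts, 1, axis=0)
    ext = ndimage.map_coordinates(field, pts.T, order=1, mode="nearest")
    return float(alpha * (d1**2).sum() + beta * (d2**2).sum() - ext.sum())


def snake_refine(
    image: GrayImage | np.ndarray,
    init: list[np.ndarray],
    config: SnakeConfig | None = None,
) -> list[np.ndarray]:
    """Evolve each closed contour to minimize its snake energy.

    Uses the semi-implicit update x <- (I + gamma A)^-1 (x + gamma F(x))
    with A the internal stiffness matrix and F the gradient of the edge
    field.  A step that would raise the total energy is retried with a
    halved step and the contour stops once no decreasing step is found,
    so the per-contour energy is non-increasing over accepted steps.
    Contours that collapse below 3 vertices are dropped with a warning.
    """
    cfg = config or SnakeConfig()
    px = image.pixels if isinstance(image, GrayImage) else np.asarray(image, dtype=float)
    if cfg.iterations == 0:
        return [np.asarray(c, dtype=float).copy() for c in init]

    field = external_energy_field(px, cfg.sigma)
    frow = ndimage.sobel(field, axis=0, mode="nearest") / 8.0
    fcol = ndimage.sobel(field, axis=1, mode="nearest") / 8.0

    out: list[np.ndarray] = []
    for contour in init:
        raw = np.asarray(contour, dtype=float)
        if len(raw) < 3:
            warnings.warn("dropping contour with < 3 vertices", RuntimeWarning, stacklevel=2)
            continue
        pts = _resample_closed(raw)
        n = len(pts)
        inv = {}  # cache (gamma) -> inverse system matrix

        def solve(gamma: float, rhs: np.ndarray) -> np.ndarray:
            if gamma not in inv:
                A = _internal_matrix(n, cfg.alpha, cfg.beta)
                inv[gamma] = np.linalg.inv(np.eye(n) + gamma * A)
            return inv[gamma] @ rhs

        energy = _snake_energy(pts, field, cfg.alpha, cfg.beta)
        gamma = cfg.gamma
        for _ in range(cfg.iterations):
            fr = ndimage.map_coordinates(frow, pts.T, order=1, mode="nearest")
            fc = ndimage.map_coordinates(fcol, pts.T, order=1, mode="nearest")
            force = np.column_stack([fr, fc])
            accepted = False
            g = gamma
            for _try in range(8):
                cand = solve(g, pts + g * force)
                cand[:, 0] = np.clip(cand[:, 0], 0, px.shape[0] - 1)
                cand[:, 1] = np.clip(cand[:, 1], 0, px.shape[1] - 1)
                e_new = _snake_energy(cand, field, cfg.alpha, cfg.beta)
                if e_new <= energy + 1e-12:
                    pts, energy, accepted = cand, e_new, True
                    break
                g *= 0.5
            if not accepted:
                break
        out.append(pts)
    return out


# --------------------------------------------------------------------------
# full hybrid pipeline
# --------------------------------------------------------------------------


@dataclass
class FCMConfig:
    c: int = 4
    m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 100
    seed: int = 0


@dataclass
class SegmentConfig:
    """Configuration of the hybrid FCM + active-contour pipeline."""

    fcm: FCMConfig = field(default_factory=FCMConfig)
    snake: SnakeConfig = field(default_factory=SnakeConfig)
    selection: str | int = "darkest"
    min_diameter_mm: float = 2.0
    max_diameter_mm: float = 12.0
    refine: bool = True
    init_dilation_px: int = 2
    # hypoechogenicity gate: a genuine follicle is fluid-filled and hence
    # markedly darker than the surrounding tissue; components whose mean
    # interior intensity exceeds this fraction of the mean intensity in a
    # surrounding annulus are dark speckle clumps, not follicles
    max_interior_ratio: float = 0.6


def _hypoechoic_filter(
    mask: SegmentationMask, image: GrayImage, max_ratio: float
) -> SegmentationMask:
    """Keep only components markedly darker than their surroundings."""
    px = image.pixels
    keep = np.zeros_like(mask.mask)
    for comp in mask.components:
        blob = np.zeros(px.shape, dtype=bool)
        blob[comp.coords[:, 0], comp.coords[:, 1]] = True
        annulus = ndimage.binary_dilation(blob, iterations=4) & ~blob
        surround = px[annulus].mean() if annulus.any() else np.inf
        if surround > 0 and px[blob].mean() / surround <= max_ratio:
            keep |= blob
    return extract_components(keep, mask.pixel_spacing)


def _rasterize(contours: list[np.ndarray], shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    for pts in contours:
        rr, cc = draw.polygon(pts[:, 0], pts[:, 1], shape=shape)
        out[rr, cc] = True
    return out


def segment_follicles(
    image: GrayImage, config: SegmentConfig | None = None
) -> SegmentationMask:
    """FCM partition -> follicle-cluster mask -> snake refinement -> size filter.

    ``image`` should already be preprocessed (grayscale, CLAHE, Gaussian).
    Returns the final mask with populated, size-filtered components.
    """
    cfg = config or SegmentConfig()
    fcm = fcm_cluster(
        image, c=cfg.fcm.c, m=cfg.fcm.m, tol=cfg.fcm.tol,
        max_iter=cfg.fcm.max_iter, seed=cfg.fcm.seed,
    )
    raw = select_follicle_cluster(fcm, cfg.selection)
    raw = extract_components(raw.mask, image.pixel_spacing)

    # prune implausible candidates before the (costly) contour refinement:
    # size with a 20% slack so borderline follicles survive until their
    # boundary is refined, then the hypoechogenicity gate
    if image.pixel_spacing is not None:
        raw = filter_by_size(raw, 0.8 * cfg.min_diameter_mm, 1.2 * cfg.max_diameter_mm)
    if cfg.max_interior_ratio < 1.0:
        raw = _hypoechoic_filter(raw, image, cfg.max_interior_ratio)

    if cfg.refine and raw.components:
        # snakes start from a slightly dilated component boundary so the
        # contour closes in on the edge from outside
        contours = []
        for comp in raw.components:
            if comp.area_px < 4:
                continue
            blob = np.zeros(image.shape, dtype=bool)
            blob[comp.coords[:, 0], comp.coords[:, 1]] = True
            blob = ndimage.binary_dilation(blob, iterations=cfg.init_dilation_px)
            cs = measure.find_contours(blob.astype(float), 0.5)
            if cs:
                contours.append(max(cs, key=len))
        refined = snake_refine(image, contours, cfg.snake)
        final = _rasterize(refined, image.shape)
    else:
        final = raw.mask

    result = extract_components(final, image.pixel_spacing)
    if image.pixel_spacing is not None:
        result = filter_by_size(result, cfg.min_diameter_mm, cfg.max_diameter_mm)
    if cfg.max_interior_ratio < 1.0:
        result = _hypoechoic_filter(result, image, cfg.max_interior_ratio)
    return result


def count_follicles(mask: SegmentationMask) -> tuple[int, list[tuple[int, int, int, int]]]:
    """Component count and per-component (x, y, w, h) bounding boxes."""
    return mask.n_components, [c.bbox for c in mask.components]
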