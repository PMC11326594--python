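"""Seeded synthetic ultrasound-like phantoms with ground-truth follicle masks.

Ovarian follicles appear on B-mode ultrasound as dark (hypoechoic)
roughly-elliptical sacs of 2-9 mm diameter embedded in brighter speckled
tissue.  The phantom generator emulates exactly that and nothing more: a
smooth tissue background, fully developed multiplicative speckle (Gamma
noise of unit mean), and non-overlapping dark ellipses with softly
feathered rims.  Each phantom carries its exact ground-truth mask and
per-follicle geometry, so segmentation and counting can be scored without
manual annotation.

A PCOS-labeled phantom carries many follicles (polycystic morphology), a
normal-labeled phantom few or none.  Everything is a pure function of
(spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .preprocess import GrayImage

__all__ = [
    "PhantomSpec",
    "Follicle",
    "LabeledImage",
    "PlacementError",
    "generate_phantom",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "default_pcos_spec",
    "default_normal_spec",
]

PCOS = "PCOS"
NORMAL = "normal"


class PlacementError(RuntimeError):
    """Raised when non-overlapping follicle placement fails repeatedly."""


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom.

    ``n_follicles`` is either an exact count or an inclusive ``(lo, hi)``
    range sampled per image.  Diameters are in mm and refer to the major
    axis of the rendered ellipse.
    """

    width: int = 224
    height: int = 224
    pixel_spacing: float = 0.2
    n_follicles: int | tuple[int, int] = 0
    follicle_diameter_range: tuple[float, float] = (2.0, 9.0)
    follicle_intensity: float = 40.0
    background_intensity: float = 150.0
    speckle_shape: float = 4.0
    class_label: str = NORMAL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 8 or self.height < 8:
            raise ValueError("phantom must be at least 8x8 pixels")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        lo, hi = self.follicle_diameter_range
        fov = min(self.width, self.height) * self.pixel_spacing
        if not (0 < lo <= hi < fov):
            raise ValueError(
                f"follicle_diameter_range {self.follicle_diameter_range} must lie in (0, {fov})"
            )
        n = self.n_follicles
        if isinstance(n, tuple):
            if n[0] < 0 or n[1] < n[0]:
                raise ValueError("n_follicles range must satisfy 0 <= lo <= hi")
        elif n < 0:
            raise ValueError("n_follicles must be non-negative")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")
        if not (0 <= self.follicle_intensity < self.background_intensity <= 255):
            raise ValueError("require 0 <= follicle_intensity < background_intensity <= 255")
        if self.class_label not in (PCOS, NORMAL):
            raise ValueError(f"class_label must be {PCOS!r} or {NORMAL!r}")


@dataclass(frozen=True)
class Follicle:
    """Ground-truth geometry of one rendered follicle."""

    cx: float  # column of the centre, px
    cy: float  # row of the centre, px
    d_mm: float  # major-axis diameter, mm
    axis_ratio: float
    angle: float  # major-axis orientation, radians


@dataclass
class LabeledImage:
    """A phantom, its ground-truth mask, its class label and its recipe."""

    image: GrayImage
    mask: np.ndarray  # bool, True inside follicles
    label: str
    spec: PhantomSpec
    follicles: list[Follicle] = field(default_factory=list)

    @property
    def n_follicles(self) -> int:
        return len(self.follicles)


def _sample_count(n: int | tuple[int, int], rng: np.random.Generator) -> int:
    if isinstance(n, tuple):
        return int(rng.integers(n[0], n[1] + 1))
    return n


def _place_follicles(
    spec: PhantomSpec, n: int, rng: np.random.Generator, max_attempts: int = 2000
) -> list[Follicle]:
    """Rejection-sample non-overlapping, fully interior follicles."""
    placed: list[Follicle] = []
    lo, hi = spec.follicle_diameter_range
    # 1 mm clearance (at the default 0.2 mm/px spacing) between follicles
    # and from the border, so rendered follicles are individually resolvable
    margin = 1.0 / spec.pixel_spacing
    for _ in range(max_attempts):
        if len(placed) == n:
            break
        d_mm = rng.uniform(lo, hi)
        r_px = d_mm / spec.pixel_spacing / 2.0
        cx = rng.uniform(r_px + margin, spec.width - r_px - margin)
        cy = rng.uniform(r_px + margin, spec.height - r_px - margin)
        ok = True
        for f in placed:
            r_other = f.d_mm / spec.pixel_spacing / 2.0
            if np.hypot(cx - f.cx, cy - f.cy) < r_px + r_other + margin:
                ok = False
                break
        if ok:
            placed.append(
                Follicle(
                    cx=cx,
                    cy=cy,
                    d_mm=d_mm,
                    axis_ratio=float(rng.uniform(0.7, 1.0)),
                    angle=float(rng.uniform(0, np.pi)),
                )
            )
    if len(placed) < n:
        raise PlacementError(
            f"could only place {len(placed)}/{n} non-overlapping follicles "
            f"in a {spec.width}x{spec.height} phantom after {max_attempts} attempts"
        )
    return placed


def _ellipse_mask(shape: tuple[int, int], f: Follicle, spacing: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    a = f.d_mm / spacing / 2.0  # semi-major, px
    b = a * f.axis_ratio
    dx = cc - f.cx
    dy = rr - f.cy
    u = dx * np.cos(f.angle) + dy * np.sin(f.angle)
    v = -dx * np.sin(f.angle) + dy * np.cos(f.angle)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> LabeledImage:
    """Render one phantom from its spec; bit-identical for identical inputs."""
    rng = np.random.default_rng(spec.seed)
    n = _sample_count(spec.n_follicles, rng)
    follicles = _place_follicles(spec, n, rng)

    shape = (spec.height, spec.width)
    # smooth tissue background: low-frequency multiplicative shading
    shading = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=24)
    if shading.std() > 0:
        shading = shading / shading.std() * 0.08
    echo = np.full(shape, spec.background_intensity) * (1.0 + shading)

    mask = np.zeros(shape, dtype=bool)
    for f in follicles:
        mask |= _ellipse_mask(shape, f, spec.pixel_spacing)
    # soft 1-px feathered rim so boundaries are not knife edges
    alpha = ndimage.gaussian_filter(mask.astype(float), sigma=1.0)
    echo = echo * (1 - alpha) + spec.follicle_intensity * alpha

    # fully developed speckle: multiplicative Gamma noise with unit mean
    speckle = rng.gamma(shape=spec.speckle_shape, scale=1.0 / spec.speckle_shape, size=shape)
    pixels = np.clip(np.rint(echo * speckle), 0, 255)

    return LabeledImage(
        image=GrayImage(pixels, spec.pixel_spacing),
        mask=mask,
        label=spec.class_label,
        spec=spec,
        follicles=follicles,
    )


def default_pcos_spec(**overrides) -> PhantomSpec:
    """Polycystic morphology: 8-15 follicles of 2.5-9 mm."""
    base = dict(n_follicles=(8, 15), follicle_diameter_range=(2.5, 9.0), class_label=PCOS)
    base.update(overrides)
    return PhantomSpec(**base)


def default_normal_spec(**overrides) -> PhantomSpec:
    """Normal morphology: at most a couple of follicles."""
    base = dict(n_follicles=(0, 2), follicle_diameter_range=(2.5, 9.0), class_label=NORMAL)
    base.update(overrides)
    return PhantomSpec(**base)


def generate_dataset(
    n_per_class: int,
    pcos_spec: PhantomSpec | None = None,
    normal_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> list[LabeledImage]:
    """Balanced labeled phantom set; per-image seeds derive from ``seed``."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    pcos_spec = pcos_spec or default_pcos_spec()
    normal_spec = normal_spec or default_normal_spec()
    children = np.random.SeedSequence(seed).spawn(2 * n_per_class)
    out: list[LabeledImage] = []
    for i in range(n_per_class):
        for j, spec in enumerate((pcos_spec, normal_spec)):
            child_seed = int(children[2 * i + j].generate_state(1)[0] % (2**31))
            out.append(generate_phantom(replace(spec, seed=child_seed)))
    return out


def write_dataset(dataset: list[LabeledImage], directory: str | Path) -> Path:
    """Write PNG images + masks and a JSON-lines manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.jsonl"
    try:
        with manifest.open("w") as fh:
            for i, item in enumerate(dataset):
                img_path = directory / f"phantom_{i:04d}.png"
                mask_path = directory / f"phantom_{i:04d}_mask.png"
                iio.imwrite(img_path, item.image.to_uint8())
                iio.imwrite(mask_path, (item.mask.astype(np.uint8)) * 255)
                record = {
                    "path": img_path.name,
                    "mask_path": mask_path.name,
                    "label": item.label,
                    "seed": item.spec.seed,
                    "pixel_spacing": item.spec.pixel_spacing,
                    "follicles": [
                        {"cx": f.cx, "cy": f.cy, "d_mm": f.d_mm} for f in item.follicles
                    ],
                }
                fh.write(json.dumps(record) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing dataset under {directory}: {exc}") from exc
    return manifest


def read_dataset(manifest: str | Path) -> list[LabeledImage]:
    """Load a written dataset back; inverse of :func:`write_dataset`.

    Recipe fields that are not stored (noise shape, intensity means) come
    back as spec defaults; pixels, masks, labels and follicle geometry
    round-trip exactly.
    """
    manifest = Path(manifest)
    directory = manifest.parent
    out: list[LabeledImage] = []
    for line in manifest.read_text().splitlines():
        rec = json.loads(line)
        pixels = np.asarray(iio.imread(directory / rec["path"]), dtype=float)
        mask = np.asarray(iio.imread(directory / rec["mask_path"])) > 127
        spec = PhantomSpec(
            width=pixels.shape[1],
            height=pixels.shape[0],
            pixel_spacing=rec["pixel_spacing"],
            n_follicles=len(rec["follicles"]),
            class_label=rec["label"],
            seed=rec["seed"],
        )
        out.append(
            LabeledImage(
                image=GrayImage(pixels, rec["pixel_spacing"]),
                mask=mask,
                label=rec["label"],
                spec=spec,
                follicles=[
                    Follicle(cx=f["cx"], cy=f["cy"], d_mm=f["d_mm"], axis_ratio=1.0, angle=0.0)
                    for f in rec["follicles"]
                ],
            )
        )
    return out
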