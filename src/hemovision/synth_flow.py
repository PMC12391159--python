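"""Synthetic brightfield microfluidic imagery with exact ground truth.

Generates annotated frames emulating unstained blood cells suspended in a
200 um-wide microfluidic channel under brightfield illumination: a bright,
mildly vignetted background, cells rendered as darker (or ringed) discs with
class-specific physical sizes, Gaussian pixel noise and a global blur.
Every rendered cell yields exactly one tight-bounding-box annotation, so the
generator is the ground-truth oracle for the whole downstream pipeline.

Physical scale: the default calibration is 57.37 um across a 416-px tile
(0.13791 um/px at 40x).  Cell sizes follow the morphological ranges of the
major blood cell types: platelets mostly <= 5 um, red cells 6-8 um,
lymphocytes 10-15 um, neutrophils 12-17 um, monocytes 12-22 um.  Echinocytes
are red cells with a spiculated membrane, rendered with a wavy contour
r(theta) = r0 * (1 + a * sin(k * theta)).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .yolo_io import Annotation, LabeledImage, NormBox

__all__ = [
    "Morphology",
    "CellSpec",
    "SimConfig",
    "MixtureSpec",
    "DEFAULT_CELL_SPECS",
    "DEFAULT_MIXTURE_6",
    "DEFAULT_MIXTURE_3",
    "UM_PER_PX",
    "generate_frame",
    "generate_dataset",
    "compose_mixture",
    "largest_remainder_counts",
]

#: Default physical calibration: 57.37 um across a 416-px tile at 40x.
UM_PER_PX = 57.37 / 416


class Morphology(enum.Enum):
    BICONCAVE_DISC = "biconcave_disc"
    SPICULATED_DISC = "spiculated_disc"
    GRANULAR_SPHERE = "granular_sphere"
    SMALL_DOT = "small_dot"


@dataclass(frozen=True)
class CellSpec:
    """Physical rendering parameters for one cell class.

    ``contrast`` is the peak signed intensity offset of the cell body versus
    the background, as a fraction of full scale in [-1, 1] (negative: darker
    than background, the brightfield norm for unstained cells).
    """

    class_name: str
    diameter_um: tuple[float, float]
    morphology: Morphology
    contrast: float = -0.35
    spicule_count: tuple[int, int] = (8, 16)
    spicule_amplitude: tuple[float, float] = (0.08, 0.20)

    def __post_init__(self) -> None:
        lo, hi = self.diameter_um
        if not 0 < lo <= hi:
            raise ValueError(f"bad diameter range {self.diameter_um}")
        alo, ahi = self.spicule_amplitude
        if not 0 < alo <= ahi < 0.5:
            raise ValueError(f"spicule amplitude must lie in (0, 0.5): {self.spicule_amplitude}")


#: Morphological defaults per class.  Platelet default range covers the
#: typical bulk (<= 5 um); individual platelets can reach 7 um and a user
#: spec may widen the range accordingly.
DEFAULT_CELL_SPECS: dict[str, CellSpec] = {
    "echinocyte": CellSpec("echinocyte", (6.0, 8.0), Morphology.SPICULATED_DISC),
    "erythrocyte": CellSpec("erythrocyte", (6.0, 8.0), Morphology.BICONCAVE_DISC),
    "lymphocyte": CellSpec("lymphocyte", (10.0, 15.0), Morphology.GRANULAR_SPHERE),
    "monocyte": CellSpec("monocyte", (12.0, 22.0), Morphology.GRANULAR_SPHERE),
    "neutrophil": CellSpec("neutrophil", (12.0, 17.0), Morphology.GRANULAR_SPHERE),
    "platelet": CellSpec("platelet", (2.0, 5.0), Morphology.SMALL_DOT, contrast=-0.45),
    # Consolidated classes used by merged schemes
    "red cell": CellSpec("red cell", (6.0, 8.0), Morphology.BICONCAVE_DISC),
    "leukocyte": CellSpec("leukocyte", (10.0, 22.0), Morphology.GRANULAR_SPHERE),
}

#: Six-class mixture matching the composition of the full training corpus
#: (53,100 / 33,200 / 7,100 / 3,300 / 4,100 / 9,600 cells, normalised).
_COUNTS_6 = {
    "echinocyte": 53100, "erythrocyte": 33200, "lymphocyte": 7100,
    "monocyte": 3300, "neutrophil": 4100, "platelet": 9600,
}
_TOTAL_6 = sum(_COUNTS_6.values())
DEFAULT_MIXTURE_6: dict[str, float] = {k: v / _TOTAL_6 for k, v in _COUNTS_6.items()}

#: The same corpus consolidated to red cell / leukocyte / platelet.
DEFAULT_MIXTURE_3: dict[str, float] = {
    "red cell": (_COUNTS_6["echinocyte"] + _COUNTS_6["erythrocyte"]) / _TOTAL_6,
    "leukocyte": (_COUNTS_6["lymphocyte"] + _COUNTS_6["monocyte"] + _COUNTS_6["neutrophil"])
    / _TOTAL_6,
    "platelet": _COUNTS_6["platelet"] / _TOTAL_6,
}


@dataclass(frozen=True)
class SimConfig:
    """Scene parameters for one simulated acquisition.

    Defaults emulate the reference acquisition: 416x416-px tiles at
    0.13791 um/px, on average 4 +/- 3 cells per tile, bright background with
    additive Gaussian noise and a light global blur.
    """

    um_per_px: float = UM_PER_PX
    frame_px: tuple[int, int] = (416, 416)  # (width, height)
    mean_cells_per_tile: float = 4.0
    sd_cells_per_tile: float = 3.0
    mixture: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE_6))
    cell_specs: Mapping[str, CellSpec] = field(
        default_factory=lambda: dict(DEFAULT_CELL_SPECS)
    )
    channel_width_um: float = 200.0
    background_level: float = 200.0
    noise_sd: float = 3.0
    blur_sigma_px: float = 0.7
    defocus_probability: float = 0.1
    defocus_extra_sigma_px: float = 2.0
    allow_overlap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture proportions sum to {total}, expected 1")
        for name in self.mixture:
            if name not in self.cell_specs:
                raise KeyError(f"mixture class {name!r} has no CellSpec")

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(self.mixture.keys())


@dataclass(frozen=True)
class MixtureSpec:
    """Image-level dilution series: component pools combined at given ratios."""

    component_ratios: tuple[tuple[str, float], ...]
    n_images: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images <= 0:
            raise ValueError("n_images must be positive")
        for name, ratio in self.component_ratios:
            if ratio <= 0:
                raise ValueError(f"ratio for {name!r} must be positive, got {ratio}")


# ---------------------------------------------------------------------------
# Cell rendering
# ---------------------------------------------------------------------------

def _radial_profile(morph: Morphology, rel_r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Signed intensity weight (fraction of CellSpec contrast) vs relative radius.

    Brightfield appearance: a biconcave disc shows a darker annulus with a
    brighter center and a bright rim halo; spheres and dots are uniformly
    dark with soft edges.
    """
    if morph is Morphology.BICONCAVE_DISC or morph is Morphology.SPICULATED_DISC:
        # dark ring toward the edge, brighter central dimple; the refractive
        # cell edge keeps the whole footprint darker than background
        ring = np.exp(-(((rel_r - 0.78) / 0.18) ** 2))
        center = np.exp(-((rel_r / 0.28) ** 2))
        return 0.55 + 0.45 * ring - 0.35 * center
    if morph is Morphology.GRANULAR_SPHERE:
        return np.full_like(rel_r, 0.85)
    if morph is Morphology.SMALL_DOT:
        return np.full_like(rel_r, 0.9)
    raise ValueError(morph)


def _render_cell(
    canvas: np.ndarray,
    mask_out: np.ndarray,
    cx_px: float,
    cy_px: float,
    spec: CellSpec,
    diameter_px: float,
    rng: np.random.Generator,
    full_scale: float = 255.0,
) -> tuple[int, int, int, int]:
    """Draw one cell onto *canvas* (float64 H x W), set its pixels in
    *mask_out*, and return the tight pixel bbox (x0, y0, x1, y1), inclusive.

    The cell boundary is r(theta) = r0 for smooth morphologies, or
    r0 * (1 + a * sin(k * theta)) for a spiculated disc; r0 is chosen so the
    mean boundary radius equals diameter/2 (sin integrates to zero over the
    circle, so r0 = diameter/2 exactly).
    """
    h, w = canvas.shape
    r0 = diameter_px / 2.0
    if spec.morphology is Morphology.SPICULATED_DISC:
        k = int(rng.integers(spec.spicule_count[0], spec.spicule_count[1] + 1))
        a = float(rng.uniform(*spec.spicule_amplitude))
        phase = float(rng.uniform(0, 2 * math.pi))
        r_max = r0 * (1 + a)
    else:
        k, a, phase = 0, 0.0, 0.0
        r_max = r0

    pad = int(math.ceil(r_max)) + 2
    x0 = max(0, int(math.floor(cx_px)) - pad)
    x1 = min(w - 1, int(math.ceil(cx_px)) + pad)
    y0 = max(0, int(math.floor(cy_px)) - pad)
    y1 = min(h - 1, int(math.ceil(cy_px)) + pad)

    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    dx = xx - cx_px
    dy = yy - cy_px
    r = np.hypot(dx, dy)
    if a > 0:
        theta = np.arctan2(dy, dx)
        boundary = r0 * (1 + a * np.sin(k * theta + phase))
    else:
        boundary = r0
    inside = r <= boundary
    if not inside.any():
        return (int(round(cx_px)), int(round(cy_px)), int(round(cx_px)), int(round(cy_px)))

    rel_r = np.where(inside, r / np.maximum(boundary, 1e-9), 1.0)
    profile = _radial_profile(spec.morphology, rel_r, rng)
    delta = np.zeros_like(r)
    delta[inside] = spec.contrast * full_scale * profile[inside]
    if spec.morphology is Morphology.GRANULAR_SPHERE:
        # internal granularity: low-amplitude multiplicative speckle
        speckle = rng.normal(1.0, 0.15, size=delta.shape)
        delta[inside] *= speckle[inside]

    canvas[y0 : y1 + 1, x0 : x1 + 1] += delta
    mask_out[y0 : y1 + 1, x0 : x1 + 1] |= inside

    ys, xs = np.nonzero(inside)
    return (x0 + int(xs.min()), y0 + int(ys.min()), x0 + int(xs.max()), y0 + int(ys.max()))


def _background(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Bright field with mild vignetting; channel-wall bands when the frame
    spans more than the 200 um channel width vertically."""
    w, h = config.frame_px
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cx, cy = (w - 1) / 2, (h - 1) / 2
    r2 = ((xx - cx) / max(w, 1)) ** 2 + ((yy - cy) / max(h, 1)) ** 2
    bg = config.background_level * (1.0 - 0.08 * r2 / 0.5)
    channel_px = config.channel_width_um / config.um_per_px
    if h > channel_px:
        wall = 0.5 * (h - channel_px)
        band = (yy < wall) | (yy > h - wall)
        bg = np.where(band, bg * 0.55, bg)
    return bg


def _cell_count(config: SimConfig, rng: np.random.Generator) -> int:
    """Integer draw from Normal(mean, sd), rounded, truncated at zero."""
    return max(0, int(round(rng.normal(config.mean_cells_per_tile, config.sd_cells_per_tile))))


def generate_frame(config: SimConfig, rng: np.random.Generator | int | None = None) -> LabeledImage:
    """Render one annotated frame.

    The cell count is drawn from a rounded, zero-truncated normal with the
    configured mean and sd; classes from the mixture; diameters uniformly
    within each class range.  The ground-truth box of each cell is the tight
    bounding box of its rendered (pre-noise, pre-blur) mask.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(
        config.seed if rng is None else rng
    )
    w, h = config.frame_px
    channel_px = config.channel_width_um / config.um_per_px
    # vertical band where cells may appear (inside the channel walls)
    if h > channel_px:
        y_lo, y_hi = 0.5 * (h - channel_px), h - 0.5 * (h - channel_px)
    else:
        y_lo, y_hi = 0.0, float(h)

    names = list(config.mixture.keys())
    probs = np.array([config.mixture[n] for n in names], dtype=np.float64)
    probs = probs / probs.sum()

    canvas = _background(config, rng)
    n_cells = _cell_count(config, rng)
    annotations: list[Annotation] = []
    defocus_centers: list[tuple[float, float, float]] = []
    placed: list[tuple[float, float, float]] = []  # (cx, cy, radius)

    for _ in range(n_cells):
        name = names[int(rng.choice(len(names), p=probs))]
        spec = config.cell_specs[name]
        d_um = float(rng.uniform(*spec.diameter_um))
        d_px = d_um / config.um_per_px
        r_margin = d_px / 2 * (
            1 + (spec.spicule_amplitude[1] if spec.morphology is Morphology.SPICULATED_DISC else 0)
        )
        if 2 * r_margin >= min(w, y_hi - y_lo):
            raise ValueError(
                f"cell {name!r} ({d_um:.1f} um = {d_px:.0f} px) does not fit the "
                f"{w}x{h}-px frame / channel band"
            )
        for _attempt in range(60):
            cx = float(rng.uniform(r_margin + 1, w - r_margin - 1))
            cy = float(rng.uniform(y_lo + r_margin + 1, y_hi - r_margin - 1))
            if config.allow_overlap:
                # cells are rigid bodies in a shallow channel: partial
                # projection overlap happens, coincident centers do not
                if all(
                    np.hypot(cx - px, cy - py) > 0.5 * (r_margin + pr) + 1
                    for px, py, pr in placed
                ):
                    break
            elif all(
                np.hypot(cx - px, cy - py) > r_margin + pr + 2 for px, py, pr in placed
            ):
                break
        else:
            continue  # crowded frame: skip this cell rather than force a pile-up
        mask = np.zeros(canvas.shape, dtype=bool)
        bx0, by0, bx1, by1 = _render_cell(canvas, mask, cx, cy, spec, d_px, rng)
        placed.append((cx, cy, r_margin))
        class_id = names.index(name)
        # +1 on the max edge: inclusive pixel bbox -> continuous extent
        annotations.append(
            Annotation(class_id, NormBox.from_pixels(bx0, by0, bx1 + 1, by1 + 1, w, h))
        )
        if config.defocus_probability > 0 and rng.random() < config.defocus_probability:
            if spec.morphology is Morphology.SMALL_DOT:
                defocus_centers.append((cx, cy, d_px))

    if config.blur_sigma_px > 0:
        from scipy.ndimage import gaussian_filter

        canvas = gaussian_filter(canvas, sigma=config.blur_sigma_px)
    for cx, cy, d_px in defocus_centers:
        # local extra blur emulating a platelet drifting out of the focal plane
        from scipy.ndimage import gaussian_filter

        rad = int(d_px * 2) + 4
        x0, x1 = max(0, int(cx) - rad), min(w, int(cx) + rad)
        y0, y1 = max(0, int(cy) - rad), min(h, int(cy) + rad)
        canvas[y0:y1, x0:x1] = gaussian_filter(
            canvas[y0:y1, x0:x1], sigma=config.defocus_extra_sigma_px
        )
    if config.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, config.noise_sd, size=canvas.shape)

    pixels = np.clip(canvas, 0, 255).round().astype(np.uint8)
    return LabeledImage(pixels=pixels, annotations=annotations, source_id="synth")


def generate_dataset(
    config: SimConfig, n_frames: int, seed: int | None = None
) -> list[LabeledImage]:
    """Render *n_frames* reproducibly; frame *i* uses child seed ``seed_seq[i]``."""
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    frames = []
    for i, child in enumerate(root.spawn(n_frames)):
        frame = generate_frame(config, np.random.default_rng(child))
        frame.source_id = f"synth_{i:05d}"
        frames.append(frame)
    return frames


# ---------------------------------------------------------------------------
# Dilution / mixture composition
# ---------------------------------------------------------------------------

def largest_remainder_counts(ratios: Sequence[float], n: int) -> list[int]:
    """Apportion *n* items to components proportionally to *ratios* using the
    largest-remainder method (Hamilton apportionment)."""
    total = float(sum(ratios))
    if total <= 0:
        raise ValueError("ratios must sum to a positive value")
    quotas = [r / total * n for r in ratios]
    counts = [int(math.floor(q)) for q in quotas]
    shortfall = n - sum(counts)
    remainders = sorted(
        range(len(ratios)), key=lambda i: (quotas[i] - counts[i], -i), reverse=True
    )
    for i in remainders[:shortfall]:
        counts[i] += 1
    return counts


def compose_mixture(
    pools: Mapping[str, Sequence[LabeledImage]], spec: MixtureSpec
) -> list[LabeledImage]:
    """Combine image pools at the requested ratios (largest-remainder
    apportionment of ``n_images``), sampling without replacement.

    Raises if any pool is too small, naming the component.
    """
    names = [name for name, _ in spec.component_ratios]
    ratios = [ratio for _, ratio in spec.component_ratios]
    counts = largest_remainder_counts(ratios, spec.n_images)
    rng = np.random.default_rng(spec.seed)
    out: list[LabeledImage] = []
    for name, count in zip(names, counts):
        pool = pools.get(name)
        if pool is None:
            raise KeyError(f"no pool named {name!r}")
        if count > len(pool):
            raise ValueError(
                f"pool {name!r} exhausted: need {count} images, have {len(pool)}"
            )
        idx = rng.choice(len(pool), size=count, replace=False)
        for j in sorted(int(i) for i in idx):
            img = pool[j].copy()
            img.source_id = f"{name}/{img.source_id}"
            out.append(img)
    return out
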