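"""Tiling of full camera frames into 416x416 training tiles, and the
augmentation suite (right-angle rotations, flips, +/-5% photometrics).

Tiling places tiles on a stride grid and shifts the last row/column inward
so coverage always reaches the frame edge.  Annotations are re-expressed in
tile-relative normalized coordinates; an annotation is kept in a tile only
when its whole box lies strictly more than ``edge_margin_px`` (default 5 px)
from every tile border, so the kept objects are fully visible cells.  The
same physical cell may legitimately appear in several overlapping tiles.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .yolo_io import Annotation, LabeledImage, NormBox

__all__ = [
    "TileSpec",
    "AugmentKind",
    "AugmentOp",
    "GEOMETRIC_KINDS",
    "PHOTOMETRIC_KINDS",
    "DEFAULT_GEOMETRIC_OPS",
    "tile_origins",
    "tile_image",
    "tile_dataset",
    "apply_augment",
    "build_augmented_set",
]


@dataclass(frozen=True)
class TileSpec:
    """Tiling geometry.

    ``stride_px == tile_px`` gives non-overlapping tiles; ``stride_px =
    tile_px // 2`` gives 50% overlap, which roughly doubles the tile count
    per frame.
    """

    tile_px: int = 416
    stride_px: int = 416
    edge_margin_px: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.stride_px <= self.tile_px:
            raise ValueError(
                f"stride_px must be in (0, tile_px]; got stride {self.stride_px}, "
                f"tile {self.tile_px}"
            )
        if self.edge_margin_px < 0:
            raise ValueError(f"edge_margin_px must be >= 0, got {self.edge_margin_px}")


class AugmentKind(enum.Enum):
    ROT90 = "rot90"
    ROT180 = "rot180"
    ROT270 = "rot270"
    FLIP_H = "fliph"
    FLIP_V = "flipv"
    CONTRAST = "contrast"
    BRIGHTNESS = "brightness"
    SATURATION = "saturation"
    HUE = "hue"
    SHARPNESS = "sharpness"
    BLUR = "blur"


GEOMETRIC_KINDS = frozenset(
    {AugmentKind.ROT90, AugmentKind.ROT180, AugmentKind.ROT270,
     AugmentKind.FLIP_H, AugmentKind.FLIP_V}
)
PHOTOMETRIC_KINDS = frozenset(set(AugmentKind) - GEOMETRIC_KINDS)

@dataclass(frozen=True)
class AugmentOp:
    """One augmentation.

    ``magnitude`` is a signed fraction for photometric kinds (default
    amplitude 0.05, i.e. +/-5%); ``None`` means draw the sign from the rng
    at application time.  Geometric kinds ignore it.
    """

    kind: AugmentKind
    magnitude: float | None = None

    def __post_init__(self) -> None:
        if self.kind in PHOTOMETRIC_KINDS and self.magnitude is not None:
            if abs(self.magnitude) > 0.05 + 1e-12:
                raise ValueError(
                    f"photometric magnitude {self.magnitude} exceeds the +/-5% limit"
                )


#: The five exact geometric ops; pixels and boxes transform analytically.
DEFAULT_GEOMETRIC_OPS = tuple(
    AugmentOp(k) for k in (
        AugmentKind.ROT90, AugmentKind.ROT180, AugmentKind.ROT270,
        AugmentKind.FLIP_H, AugmentKind.FLIP_V,
    )
)

DEFAULT_PHOTOMETRIC_OPS = tuple(
    AugmentOp(k) for k in sorted(PHOTOMETRIC_KINDS, key=lambda k: k.value)
)


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------

def tile_origins(frame_px: int, tile_px: int, stride_px: int) -> list[int]:
    """1-D tile origins on a stride grid, last tile shifted inward to the edge."""
    if frame_px < tile_px:
        raise ValueError(f"frame ({frame_px} px) smaller than tile ({tile_px} px)")
    origins = list(range(0, frame_px - tile_px + 1, stride_px))
    if origins[-1] != frame_px - tile_px:
        origins.append(frame_px - tile_px)
    return origins


def tile_image(
    frame: LabeledImage, spec: TileSpec = TileSpec()
) -> list[tuple[LabeledImage, tuple[int, int]]]:
    """Cut *frame* into tiles, remapping annotations into tile coordinates.

    Returns ``(tile, (x_origin, y_origin))`` pairs in row-major grid order.
    An annotation survives into a tile only if every box edge is strictly
    more than ``edge_margin_px`` from every tile border.
    """
    t = spec.tile_px
    xs = tile_origins(frame.width_px, t, spec.stride_px)
    ys = tile_origins(frame.height_px, t, spec.stride_px)
    margin = spec.edge_margin_px

    # Precompute annotation pixel corners once.
    px_boxes = [ann.box.to_pixels(frame.width_px, frame.height_px) for ann in frame.annotations]

    out = []
    for oy in ys:
        for ox in xs:
            pixels = np.ascontiguousarray(frame.pixels[oy : oy + t, ox : ox + t])
            kept: list[Annotation] = []
            for ann, (x0, y0, x1, y1) in zip(frame.annotations, px_boxes):
                rx0, ry0, rx1, ry1 = x0 - ox, y0 - oy, x1 - ox, y1 - oy
                if (
                    rx0 > margin and ry0 > margin
                    and rx1 < t - margin and ry1 < t - margin
                ):
                    kept.append(
                        Annotation(ann.class_id, NormBox.from_pixels(rx0, ry0, rx1, ry1, t, t))
                    )
            out.append(
                (
                    LabeledImage(
                        pixels=pixels,
                        annotations=kept,
                        source_id=f"{frame.source_id}+{ox}+{oy}",
                    ),
                    (ox, oy),
                )
            )
    return out


def tile_dataset(
    frames: Iterable[LabeledImage], spec: TileSpec = TileSpec()
) -> list[LabeledImage]:
    """Tile every frame, discarding origin bookkeeping."""
    return [tile for frame in frames for tile, _ in tile_image(frame, spec)]


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def _transform_box(box: NormBox, kind: AugmentKind) -> NormBox:
    cx, cy, w, h = box.cx, box.cy, box.w, box.h
    if kind is AugmentKind.ROT90:  # clockwise
        return NormBox(1 - cy, cx, h, w)
    if kind is AugmentKind.ROT180:
        return NormBox(1 - cx, 1 - cy, w, h)
    if kind is AugmentKind.ROT270:
        return NormBox(cy, 1 - cx, h, w)
    if kind is AugmentKind.FLIP_H:  # mirror across the vertical mid axis
        return NormBox(1 - cx, cy, w, h)
    if kind is AugmentKind.FLIP_V:
        return NormBox(cx, 1 - cy, w, h)
    return box


def _transform_pixels(pixels: np.ndarray, kind: AugmentKind) -> np.ndarray:
    if kind is AugmentKind.ROT90:
        return np.ascontiguousarray(np.rot90(pixels, k=-1, axes=(0, 1)))
    if kind is AugmentKind.ROT180:
        return np.ascontiguousarray(np.rot90(pixels, k=2, axes=(0, 1)))
    if kind is AugmentKind.ROT270:
        return np.ascontiguousarray(np.rot90(pixels, k=1, axes=(0, 1)))
    if kind is AugmentKind.FLIP_H:
        return np.ascontiguousarray(pixels[:, ::-1])
    if kind is AugmentKind.FLIP_V:
        return np.ascontiguousarray(pixels[::-1, :])
    return pixels


def _apply_photometric(pixels: np.ndarray, kind: AugmentKind, magnitude: float) -> np.ndarray:
    """Photometric op at signed *magnitude* (fraction, |m| <= 0.05).

    Contrast/brightness/saturation/sharpness scale by ``1 + m``; hue rotates
    by ``m`` of the full hue circle; blur applies a Gaussian with sigma
    proportional to ``|m|``.  Output stays uint8 in [0, 255].
    """
    from PIL import Image, ImageEnhance
    from scipy.ndimage import gaussian_filter

    factor = 1.0 + magnitude
    if kind is AugmentKind.BRIGHTNESS:
        out = np.clip(pixels.astype(np.float64) * factor, 0, 255)
        return out.round().astype(np.uint8)
    if kind is AugmentKind.CONTRAST:
        mean = float(pixels.mean())
        out = np.clip((pixels.astype(np.float64) - mean) * factor + mean, 0, 255)
        return out.round().astype(np.uint8)
    if kind is AugmentKind.BLUR:
        # sigma = 20 px * |m|, i.e. 1 px at the +/-5% default
        sigma = 20.0 * abs(magnitude)
        if pixels.ndim == 3:
            out = gaussian_filter(pixels.astype(np.float64), sigma=(sigma, sigma, 0))
        else:
            out = gaussian_filter(pixels.astype(np.float64), sigma=sigma)
        return np.clip(out, 0, 255).round().astype(np.uint8)
    if kind in (AugmentKind.SATURATION, AugmentKind.HUE):
        rgb = pixels if pixels.ndim == 3 else np.stack([pixels] * 3, axis=-1)
        im = Image.fromarray(rgb, mode="RGB").convert("HSV")
        hsv = np.asarray(im).astype(np.float64)
        if kind is AugmentKind.SATURATION:
            hsv[..., 1] = np.clip(hsv[..., 1] * factor, 0, 255)
        else:
            hsv[..., 0] = np.mod(hsv[..., 0] + magnitude * 256.0, 256.0)
        out = Image.fromarray(hsv.round().astype(np.uint8), mode="HSV").convert("RGB")
        out = np.asarray(out)
        return out if pixels.ndim == 3 else out[..., 0].copy()
    if kind is AugmentKind.SHARPNESS:
        if pixels.ndim == 3:
            im = Image.fromarray(pixels, mode="RGB")
        else:
            im = Image.fromarray(pixels, mode="L")
        # ImageEnhance.Sharpness: 1.0 is the identity
        return np.asarray(ImageEnhance.Sharpness(im).enhance(factor)).copy()
    raise ValueError(f"not a photometric kind: {kind}")


def apply_augment(
    image: LabeledImage, op: AugmentOp, rng: np.random.Generator | int | None = None
) -> LabeledImage:
    """Apply one augmentation; geometric ops transform annotations exactly,
    photometric ops leave them untouched.

    ``rng`` (Generator or seed) supplies the magnitude sign for photometric
    ops whose magnitude is unset.
    """
    kind = op.kind
    if kind in GEOMETRIC_KINDS:
        if kind in (AugmentKind.ROT90, AugmentKind.ROT270) and (
            image.width_px != image.height_px
        ):
            raise ValueError(
                f"90/270-degree rotation requires a square image, got "
                f"{image.width_px}x{image.height_px}"
            )
        return LabeledImage(
            pixels=_transform_pixels(image.pixels, kind),
            annotations=[
                Annotation(a.class_id, _transform_box(a.box, kind)) for a in image.annotations
            ],
            source_id=f"{image.source_id}#{kind.value}",
        )
    magnitude = op.magnitude
    if magnitude is None:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        magnitude = 0.05 * (1.0 if gen.random() < 0.5 else -1.0)
    return LabeledImage(
        pixels=_apply_photometric(image.pixels, kind, magnitude),
        annotations=list(image.annotations),
        source_id=f"{image.source_id}#{kind.value}{magnitude:+.3f}",
    )


def build_augmented_set(
    tiles: Sequence[LabeledImage],
    ops: Sequence[AugmentOp] = DEFAULT_GEOMETRIC_OPS,
    seed: int | None = 0,
) -> list[LabeledImage]:
    """Originals plus one augmented copy per (tile, op); deterministic given seed."""
    if not ops:
        raise ValueError("ops must be non-empty")
    rng = np.random.default_rng(seed)
    out = [img.copy() for img in tiles]
    for img in tiles:
        for op in ops:
            out.append(apply_augment(img, op, rng))
    return out
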