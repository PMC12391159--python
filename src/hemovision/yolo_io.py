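"""YOLO-format annotation I/O and the core geometric types.

The annotation atom throughout the package is the normalized center-format
bounding box used by YOLO label files: each object is one line
``class cx cy w h`` where ``cx, cy`` are the box center as fractions of the
image width/height and ``w, h`` the box extent as fractions.  Pixel-space
conversion is continuous, ``x_px = cx * width_px``, with no half-pixel
offset, matching the convention of the LabelImg export the format comes
from.

Boxes that leave the unit square by at most ``CLIP_TOL`` (float noise from
coordinate arithmetic) are clipped silently; larger violations raise
:class:`BoxValidationError` since they indicate real corruption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DROP",
    "CLIP_TOL",
    "NormBox",
    "Annotation",
    "Detection",
    "ClassScheme",
    "LabeledImage",
    "BoxValidationError",
    "LabelParseError",
    "read_yolo_labels",
    "write_yolo_labels",
    "read_class_names",
    "write_class_names",
    "remap_classes",
    "remap_annotations",
    "SCHEME_6",
    "SCHEME_4",
    "SCHEME_3",
    "REMAP_6_TO_4",
    "REMAP_6_TO_3",
    "REMAP_4_TO_3",
]

#: Sentinel marking a class as removed by a remap table.
DROP = "DROP"

#: Boxes exceeding [0, 1] by at most this much are clipped silently.
CLIP_TOL = 1e-6


class BoxValidationError(ValueError):
    """A bounding box violates the normalized-coordinate contract."""


class LabelParseError(ValueError):
    """A YOLO label file or detection record could not be parsed."""


@dataclass(frozen=True)
class NormBox:
    """Axis-aligned box in normalized center format.

    Parameters
    ----------
    cx, cy:
        Box center as a fraction of image width / height, in ``[0, 1]``.
    w, h:
        Box extent as a fraction of image width / height, in ``(0, 1]``.
    """

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        cx, cy, w, h = _clip_box(self.cx, self.cy, self.w, self.h)
        object.__setattr__(self, "cx", cx)
        object.__setattr__(self, "cy", cy)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "h", h)

    @property
    def x0(self) -> float:
        return self.cx - self.w / 2

    @property
    def x1(self) -> float:
        return self.cx + self.w / 2

    @property
    def y0(self) -> float:
        return self.cy - self.h / 2

    @property
    def y1(self) -> float:
        return self.cy + self.h / 2

    @property
    def area(self) -> float:
        return self.w * self.h

    def to_pixels(self, width_px: int, height_px: int) -> tuple[float, float, float, float]:
        """Return ``(x0, y0, x1, y1)`` in continuous pixel coordinates."""
        return (
            self.x0 * width_px,
            self.y0 * height_px,
            self.x1 * width_px,
            self.y1 * height_px,
        )

    @classmethod
    def from_pixels(
        cls,
        x0: float,
        y0: float,
        x1: float,
        y1: float,
        width_px: int,
        height_px: int,
    ) -> "NormBox":
        """Build a box from continuous pixel corner coordinates."""
        return cls(
            cx=(x0 + x1) / 2 / width_px,
            cy=(y0 + y1) / 2 / height_px,
            w=(x1 - x0) / width_px,
            h=(y1 - y0) / height_px,
        )


def _clip_box(cx: float, cy: float, w: float, h: float) -> tuple[float, float, float, float]:
    for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
        if not math.isfinite(v):
            raise BoxValidationError(f"non-finite {name}={v!r}")
    if w <= 0 or h <= 0:
        raise BoxValidationError(f"non-positive box extent w={w} h={h}")
    # Extent check before clipping: tolerate float noise only.
    for lo, hi, axis in ((cx - w / 2, cx + w / 2, "x"), ((cy - h / 2), (cy + h / 2), "y")):
        if lo < -CLIP_TOL or hi > 1 + CLIP_TOL:
            raise BoxValidationError(
                f"box extent [{lo:.9f}, {hi:.9f}] leaves [0, 1] on {axis} axis "
                f"by more than {CLIP_TOL}"
            )
    # Clip only when an edge actually leaves the unit square, so clean
    # coordinates pass through bit-exact.
    if cx - w / 2 < 0 or cx + w / 2 > 1:
        x0, x1 = max(0.0, cx - w / 2), min(1.0, cx + w / 2)
        cx, w = (x0 + x1) / 2, x1 - x0
    if cy - h / 2 < 0 or cy + h / 2 > 1:
        y0, y1 = max(0.0, cy - h / 2), min(1.0, cy + h / 2)
        cy, h = (y0 + y1) / 2, y1 - y0
    return cx, cy, w, h


@dataclass(frozen=True)
class Annotation:
    """A ground-truth object: class index into a :class:`ClassScheme` plus box."""

    class_id: int
    box: NormBox

    def __post_init__(self) -> None:
        if self.class_id < 0:
            raise BoxValidationError(f"negative class_id {self.class_id}")


@dataclass(frozen=True)
class Detection:
    """A predicted object with a confidence score in ``[0, 1]``."""

    class_id: int
    box: NormBox
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise BoxValidationError(f"confidence {self.confidence} outside [0, 1]")


@dataclass(frozen=True)
class ClassScheme:
    """Ordered class vocabulary.

    The id order is explicit and carried with every dataset; label files are
    meaningless without it.  Remap tables between schemes are plain dicts
    ``old_id -> new_id`` with the string sentinel :data:`DROP` marking
    removed classes.
    """

    names: tuple[str, ...]

    def __init__(self, names: Sequence[str]):
        names = tuple(names)
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate class names in {names}")
        object.__setattr__(self, "names", names)

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def id_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"class {name!r} not in scheme {self.names}") from None

    def validate_id(self, class_id: int) -> None:
        if not 0 <= class_id < len(self.names):
            raise BoxValidationError(
                f"class_id {class_id} outside scheme of {len(self.names)} classes"
            )


# The six-class vocabulary, alphabetical within the red-cell / leukocyte /
# platelet groupings; the consolidated four- and three-class schemes.
SCHEME_6 = ClassScheme(
    ["echinocyte", "erythrocyte", "lymphocyte", "monocyte", "neutrophil", "platelet"]
)
SCHEME_4 = ClassScheme(["echinocyte", "erythrocyte", "leukocyte", "platelet"])
SCHEME_3 = ClassScheme(["red cell", "leukocyte", "platelet"])

#: lymphocyte/monocyte/neutrophil -> leukocyte
REMAP_6_TO_4: dict[int, int | str] = {0: 0, 1: 1, 2: 2, 3: 2, 4: 2, 5: 3}
#: echinocyte+erythrocyte -> red cell; leukocyte subtypes -> leukocyte
REMAP_6_TO_3: dict[int, int | str] = {0: 0, 1: 0, 2: 1, 3: 1, 4: 1, 5: 2}
#: echinocyte+erythrocyte -> red cell
REMAP_4_TO_3: dict[int, int | str] = {0: 0, 1: 0, 2: 1, 3: 2}


@dataclass
class LabeledImage:
    """An 8-bit pixel grid with its annotations.

    ``pixels`` is ``(H, W)`` grayscale or ``(H, W, 3)`` RGB, dtype uint8.
    This is the unit flowing through tiling, augmentation, simulation and
    detection.
    """

    pixels: np.ndarray
    annotations: list[Annotation] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise ValueError(f"pixels must be (H, W) or (H, W, 3), got {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {px.dtype}")
        self.pixels = px

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])

    def copy(self) -> "LabeledImage":
        return LabeledImage(
            pixels=self.pixels.copy(),
            annotations=list(self.annotations),
            source_id=self.source_id,
        )


# ---------------------------------------------------------------------------
# Label file I/O
# ---------------------------------------------------------------------------

def read_yolo_labels(path: str | Path, scheme: ClassScheme | None = None) -> list[Annotation]:
    """Read a YOLO label file (``class cx cy w h`` per line).

    Empty lines are skipped; order is preserved.  If *scheme* is given,
    class ids are validated against it.

    Raises
    ------
    LabelParseError
        On a malformed line (names the 1-based line number).
    BoxValidationError
        On a class id outside *scheme* or an invalid box.
    """
    path = Path(path)
    annotations: list[Annotation] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) != 5:
            raise LabelParseError(
                f"{path}:{lineno}: expected 5 tokens, got {len(tokens)}: {line!r}"
            )
        try:
            class_id = int(tokens[0])
            cx, cy, w, h = (float(t) for t in tokens[1:])
        except ValueError as exc:
            raise LabelParseError(f"{path}:{lineno}: non-numeric token: {line!r}") from exc
        if scheme is not None:
            scheme.validate_id(class_id)
        annotations.append(Annotation(class_id, NormBox(cx, cy, w, h)))
    return annotations


def write_yolo_labels(annotations: Iterable[Annotation], path: str | Path) -> None:
    """Write annotations to a YOLO label file, fixed 6-decimal formatting.

    Lines are written in input order; an invalid annotation aborts the write
    reporting its index.
    """
    annotations = list(annotations)
    lines = []
    for i, ann in enumerate(annotations):
        if not isinstance(ann, Annotation):
            raise BoxValidationError(f"annotation {i} is not an Annotation: {ann!r}")
        b = ann.box
        lines.append(f"{ann.class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}")
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_class_names(path: str | Path) -> ClassScheme:
    """Read a ``classes.txt`` (one class name per line) into a scheme."""
    names = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    return ClassScheme(names)


def write_class_names(scheme: ClassScheme, path: str | Path) -> None:
    Path(path).write_text("".join(name + "\n" for name in scheme.names))


# ---------------------------------------------------------------------------
# Class remapping (merge / drop)
# ---------------------------------------------------------------------------

def remap_annotations(
    annotations: Iterable[Annotation],
    remap: Mapping[int, int | str],
    scheme_to: ClassScheme | None = None,
) -> list[Annotation]:
    """Relabel annotations through ``old_id -> new_id | DROP``.

    Every class id present must be covered by *remap*; dropped annotations
    are removed, order otherwise preserved.
    """
    out: list[Annotation] = []
    missing: set[int] = set()
    for ann in annotations:
        if ann.class_id not in remap:
            missing.add(ann.class_id)
            continue
        target = remap[ann.class_id]
        if target == DROP:
            continue
        target = int(target)
        if scheme_to is not None:
            scheme_to.validate_id(target)
        out.append(replace(ann, class_id=target))
    if missing:
        raise BoxValidationError(
            f"remap does not cover class ids {sorted(missing)}; map them or mark DROP"
        )
    return out


def remap_classes(
    dataset: Iterable[LabeledImage],
    remap: Mapping[int, int | str],
    scheme_to: ClassScheme | None = None,
) -> list[LabeledImage]:
    """Apply :func:`remap_annotations` to every image of a dataset.

    Images left with zero annotations are retained: background tiles are
    legitimate training material.
    """
    out = []
    for img in dataset:
        out.append(
            LabeledImage(
                pixels=img.pixels,
                annotations=remap_annotations(img.annotations, remap, scheme_to),
                source_id=img.source_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Sibling-file dataset layout helpers
# ---------------------------------------------------------------------------

def load_image_dir(directory: str | Path, scheme: ClassScheme | None = None) -> list[LabeledImage]:
    """Load every ``<stem>.png|.jpg`` with its sibling ``<stem>.txt`` labels."""
    from PIL import Image

    directory = Path(directory)
    images: list[LabeledImage] = []
    for img_path in sorted(directory.iterdir()):
        if img_path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
            continue
        pixels = np.asarray(Image.open(img_path))
        label_path = img_path.with_suffix(".txt")
        anns = read_yolo_labels(label_path, scheme) if label_path.exists() else []
        images.append(LabeledImage(pixels=pixels, annotations=anns, source_id=img_path.stem))
    return images


def save_image_dir(images: Iterable[LabeledImage], directory: str | Path) -> None:
    """Write images as PNG with sibling YOLO label files."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, img in enumerate(images):
        stem = img.source_id or f"image_{i:05d}"
        stem = stem.replace("/", "_")
        Image.fromarray(img.pixels).save(directory / f"{stem}.png")
        write_yolo_labels(img.annotations, directory / f"{stem}.txt")
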