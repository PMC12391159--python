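"""Pluggable detector layer.

Two routes fill the detector slot of the pipeline:

* :func:`detect_reference` — a classical segmentation detector (background
  flattening, Otsu thresholding, connected components, size-bin
  classification with a contour-roughness test for the spiculated red-cell
  phenotype).  It runs on one CPU in milliseconds per tile and lets the full
  simulate -> detect -> evaluate loop execute end to end without any trained
  network.
* :func:`read_darknet_detections` — an adapter for external YOLO/Darknet
  result files (the documented JSON dialect, or a whitespace text fallback),
  so detections from a trained model drop into the same evaluation.

Size bins follow the physical size separation of the classes: platelets at
the lower end, red cells mid-range (6-8 um), leukocytes at the upper end.
Within the red-cell bin, a contour roughness score (std of the
centroid-to-contour radius over its mean) separates spiculated echinocytes
from smooth erythrocytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .yolo_io import (
    ClassScheme,
    Detection,
    LabelParseError,
    LabeledImage,
    NormBox,
)
from .synth_flow import UM_PER_PX

__all__ = [
    "DetectorConfig",
    "DetectionSet",
    "detect_reference",
    "roughness_score",
    "read_darknet_detections",
    "write_darknet_detections",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Classical detector parameters.

    ``size_bins_um`` are the two class boundaries on equivalent diameter:
    below the first -> platelet, between -> red cell, above the second ->
    leukocyte.  ``segmentation_threshold`` is a relative intensity in
    [0, 1], or ``None`` for Otsu (AUTO).
    """

    um_per_px: float = UM_PER_PX
    background_flatten_sigma_px: float = 25.0
    #: grey-closing window applied before the blur; must exceed the widest
    #: cell (a 22 um monocyte spans ~160 px at the default calibration) so
    #: dark objects are erased from the background estimate
    background_closing_px: int = 171
    segmentation_threshold: float | None = None  # None = AUTO (Otsu)
    size_bins_um: tuple[float, float] = (5.0, 9.5)
    roughness_threshold: float = 0.06
    min_area_px: int = 20
    #: interior texture cut: a component above the red-cell size bin with an
    #: interior coefficient of variation below this is a single granular
    #: leukocyte; above it, an unresolved clump of ringed red cells
    granularity_threshold: float = 0.20
    #: largest equivalent diameter a fused pair of red cells can reach
    #: (sqrt(2) x the 8 um red-cell maximum); larger clumps must contain a
    #: leukocyte
    red_clump_max_um: float = 11.5
    distinguish_echinocytes: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.size_bins_um
        if not 0 < lo < hi:
            raise ValueError(f"size bins must be strictly increasing: {self.size_bins_um}")
        if self.roughness_threshold <= 0:
            raise ValueError("roughness_threshold must be positive")

    def classify(
        self,
        equivalent_diameter_um: float,
        roughness: float | None,
        interior_cv: float | None = None,
    ) -> str:
        lo, hi = self.size_bins_um
        if equivalent_diameter_um < lo:
            return "platelet"
        if equivalent_diameter_um > hi:
            # just above the red-cell bin: either a small granular
            # (texture-uniform) leukocyte or an unsplit pair of ringed red
            # cells, told apart by interior variance; beyond the largest
            # possible red-cell pair it must contain a leukocyte
            if (
                equivalent_diameter_um <= self.red_clump_max_um
                and interior_cv is not None
                and interior_cv > self.granularity_threshold
            ):
                return "red cell"
            return "leukocyte"
        if self.distinguish_echinocytes and roughness is not None:
            return "echinocyte" if roughness > self.roughness_threshold else "erythrocyte"
        return "red cell"


@dataclass
class DetectionSet:
    """All detections for one image."""

    image_id: str
    detections: list[Detection] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.detections)


def roughness_score(mask: np.ndarray) -> float:
    """Contour roughness: std of centroid-to-contour radius / mean radius.

    Near zero for a circle; for a spiculated boundary
    r(theta) = r0 * (1 + a * sin(k * theta)) the score approaches
    a / sqrt(2).  Requires a single connected component whose boundary
    yields at least 16 contour points.
    """
    from skimage import measure

    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    lab = measure.label(mask, connectivity=2)
    if lab.max() != 1:
        raise ValueError(f"mask must have exactly one connected component, got {lab.max()}")
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("no contour found")
    contour = max(contours, key=len)
    if len(contour) < 16:
        raise ValueError(f"degenerate mask: contour has {len(contour)} (<16) points")
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    radii = np.hypot(contour[:, 0] - cy, contour[:, 1] - cx)
    return float(radii.std() / radii.mean())


def _split_touching(
    component_mask: np.ndarray,
) -> list[tuple[np.ndarray, tuple[int, int] | None]]:
    """Watershed split of a component on its distance transform.

    Single cells (one deep distance maximum) come back whole with peak
    ``None``; touching or partially overlapping cells separate at the waist
    between their centers, each part carrying its seeding peak so the caller
    can reconstruct the occluded extent.
    """
    from scipy import ndimage
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    dist = ndimage.distance_transform_edt(component_mask)
    min_sep = max(3, int(dist.max() * 0.3))
    # only deep maxima count as cell centers: shallow maxima at spicule tips
    # or boundary bumps (depth ~ a fraction of the spicule width) must not
    # seed the watershed
    peaks = peak_local_max(
        dist, min_distance=min_sep, threshold_abs=0.3 * float(dist.max()),
        labels=component_mask,
    )
    if len(peaks) < 2:
        return [(component_mask, None)]
    markers = np.zeros(component_mask.shape, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-dist, markers, mask=component_mask)
    out = []
    for i, (r, c) in enumerate(peaks, start=1):
        part = labels == i
        if part.any():
            out.append((part, (int(r), int(c), float(dist[r, c]))))
    return out


def detect_reference(image: LabeledImage, config: DetectorConfig = DetectorConfig()) -> DetectionSet:
    """Run the classical detector on one 8-bit image.

    Pipeline: flatten the background by dividing by a heavy Gaussian blur,
    threshold the darker-than-background residual (Otsu when AUTO), keep
    connected components of at least ``min_area_px``, split low-solidity
    components by one watershed pass, then classify each component by
    equivalent diameter (and contour roughness within the red-cell bin).
    Confidence is the component's normalized contrast, clipped to
    [0.05, 0.99].  A blank image yields an empty set.
    """
    from scipy.ndimage import binary_erosion
    from scipy.ndimage import binary_fill_holes as ndimage_fill
    from scipy.ndimage import gaussian_filter, grey_closing
    from skimage import measure
    from skimage.filters import threshold_otsu

    px = image.pixels
    gray = px.astype(np.float64) if px.ndim == 2 else px.astype(np.float64).mean(axis=2)
    h, w = gray.shape

    closed = grey_closing(gray, size=config.background_closing_px)
    background = gaussian_filter(closed, sigma=config.background_flatten_sigma_px)
    flat = gray / np.maximum(background, 1.0)  # ~1.0 on background
    # cells are darker than background: deficit in [0, 1]
    deficit = np.clip(1.0 - flat, 0.0, None)

    if config.segmentation_threshold is not None:
        thr = config.segmentation_threshold
    else:
        # cells are at least ~10% darker than background; below this floor
        # Otsu would carve structure out of vignette residue on blank frames
        floor = 0.08
        if deficit.max() < floor:
            return DetectionSet(image.source_id, [])
        thr = max(threshold_otsu(deficit), floor)
    binary = deficit > thr
    # biconcave discs threshold as rings (bright center); fill them
    binary = ndimage_fill(binary)

    labels = measure.label(binary, connectivity=2)
    detections: list[Detection] = []
    for region in measure.regionprops(labels):
        if region.area < config.min_area_px:
            continue
        full_mask = labels == region.label
        for part, peak in _split_touching(full_mask):
            area = int(part.sum())
            if area < config.min_area_px:
                continue
            ys, xs = np.nonzero(part)
            if peak is None:
                x0, x1 = float(xs.min()), float(xs.max()) + 1
                y0, y1 = float(ys.min()), float(ys.max()) + 1
            else:
                # occluded split part: the seeding peak sits at the cell
                # center and its distance value is the inradius, i.e. the
                # radius of a circular cell; reconstruct the extent hidden
                # behind the neighbour from it
                pr, pc, radius = peak
                half = radius + 0.5
                x0, x1 = max(0.0, pc + 0.5 - half), min(float(w), pc + 0.5 + half)
                y0, y1 = max(0.0, pr + 0.5 - half), min(float(h), pr + 0.5 + half)
            eq_diam_um = (
                2.0 * np.sqrt(area / np.pi) * config.um_per_px
                if peak is None
                else 0.5 * ((x1 - x0) + (y1 - y0)) * config.um_per_px
            )
            lo, hi = config.size_bins_um
            rough = None
            if peak is None and lo <= eq_diam_um <= hi:
                try:
                    rough = roughness_score(part)
                except ValueError:
                    rough = None
            cv = None
            if eq_diam_um > hi:
                interior = binary_erosion(part, iterations=2)
                if interior.sum() >= 10 and deficit[interior].mean() > 0:
                    cv = float(deficit[interior].std() / deficit[interior].mean())
            name = config.classify(eq_diam_um, rough, cv)
            contrast = float(deficit[part].mean())
            confidence = float(np.clip(contrast * 4.0, 0.05, 0.99))
            box = NormBox.from_pixels(x0, y0, x1, y1, w, h)
            detections.append(Detection(_CLASS_IDS[name], box, confidence))
    return DetectionSet(image.source_id, detections)


# Stable ids for the detector's output vocabulary; remap to the evaluation
# scheme with `resolve_classes`.
_DETECTOR_CLASSES = ("echinocyte", "erythrocyte", "red cell", "leukocyte", "platelet")
_CLASS_IDS = {name: i for i, name in enumerate(_DETECTOR_CLASSES)}
DETECTOR_SCHEME = ClassScheme(_DETECTOR_CLASSES)


def resolve_classes(dset: DetectionSet, scheme: ClassScheme) -> DetectionSet:
    """Re-index detector-vocabulary class ids into *scheme*.

    ``echinocyte``/``erythrocyte`` fall back to ``red cell`` (and vice
    versa) when the target scheme lacks the finer (or coarser) labels.
    """
    fallback = {"echinocyte": "red cell", "erythrocyte": "red cell"}
    out = []
    for det in dset.detections:
        name = _DETECTOR_CLASSES[det.class_id]
        if name not in scheme.names and name in fallback:
            name = fallback[name]
        if name == "red cell" and name not in scheme.names:
            raise KeyError(f"scheme {scheme.names} cannot express detector class 'red cell'")
        out.append(Detection(scheme.id_of(name), det.box, det.confidence))
    return DetectionSet(dset.image_id, out)


# ---------------------------------------------------------------------------
# Darknet result adapter
# ---------------------------------------------------------------------------

def read_darknet_detections(
    path: str | Path, scheme: ClassScheme
) -> dict[str, DetectionSet]:
    """Read external detector output into DetectionSets keyed by image id.

    Accepted dialects:

    * Darknet result JSON: a list of objects with ``filename`` and
      ``objects``: each object carries ``class_id``, ``name``,
      ``relative_coordinates`` (``center_x``, ``center_y``, ``width``,
      ``height``) and ``confidence``.
    * Whitespace text fallback: lines ``image_id class_id cx cy w h conf``.

    Coordinates are already normalized center format and pass through
    unchanged.  Unknown class names/ids and malformed records raise, naming
    the record index.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped.startswith("[") or stripped.startswith("{"):
        return _read_darknet_json(text, scheme, path)
    return _read_darknet_text(text, scheme, path)


def _read_darknet_json(
    text: str, scheme: ClassScheme, path: Path
) -> dict[str, DetectionSet]:
    try:
        records = json.loads(text)
    except json.JSONDecodeError as exc:
        raise LabelParseError(f"{path}: invalid JSON: {exc}") from exc
    if isinstance(records, dict):
        records = [records]
    out: dict[str, DetectionSet] = {}
    for i, rec in enumerate(records):
        try:
            image_id = Path(rec["filename"]).stem
            objects = rec["objects"]
        except (KeyError, TypeError) as exc:
            raise LabelParseError(f"{path}: record {i}: missing filename/objects") from exc
        dets = []
        for j, obj in enumerate(objects):
            try:
                class_id = int(obj["class_id"])
                name = obj.get("name")
                rc = obj["relative_coordinates"]
                box = NormBox(
                    float(rc["center_x"]), float(rc["center_y"]),
                    float(rc["width"]), float(rc["height"]),
                )
                conf = float(obj["confidence"])
            except (KeyError, TypeError, ValueError) as exc:
                raise LabelParseError(
                    f"{path}: record {i}, object {j}: malformed: {exc}"
                ) from exc
            scheme.validate_id(class_id)
            if name is not None and name != scheme.names[class_id]:
                raise LabelParseError(
                    f"{path}: record {i}, object {j}: class name {name!r} does not "
                    f"match scheme id {class_id} ({scheme.names[class_id]!r})"
                )
            dets.append(Detection(class_id, box, conf))
        out[image_id] = DetectionSet(image_id, dets)
    return out


def _read_darknet_text(
    text: str, scheme: ClassScheme, path: Path
) -> dict[str, DetectionSet]:
    out: dict[str, DetectionSet] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) != 7:
            raise LabelParseError(
                f"{path}:{lineno}: expected 'image_id class cx cy w h conf' (7 tokens), "
                f"got {len(tokens)}"
            )
        image_id = tokens[0]
        try:
            class_id = int(tokens[1])
            cx, cy, w, h, conf = (float(t) for t in tokens[2:])
        except ValueError as exc:
            raise LabelParseError(f"{path}:{lineno}: non-numeric token") from exc
        scheme.validate_id(class_id)
        out.setdefault(image_id, DetectionSet(image_id, []))
        out[image_id].detections.append(Detection(class_id, NormBox(cx, cy, w, h), conf))
    return out


def write_darknet_detections(
    detection_sets: Mapping[str, DetectionSet] | Sequence[DetectionSet],
    path: str | Path,
    scheme: ClassScheme,
) -> None:
    """Write DetectionSets in the Darknet result JSON dialect."""
    if isinstance(detection_sets, Mapping):
        sets = list(detection_sets.values())
    else:
        sets = list(detection_sets)
    records = []
    for dset in sets:
        records.append(
            {
                "filename": f"{dset.image_id}.png",
                "objects": [
                    {
                        "class_id": det.class_id,
                        "name": scheme.names[det.class_id],
                        "relative_coordinates": {
                            "center_x": det.box.cx,
                            "center_y": det.box.cy,
                            "width": det.box.w,
                            "height": det.box.h,
                        },
                        "confidence": det.confidence,
                    }
                    for det in dset.detections
                ],
            }
        )
    Path(path).write_text(json.dumps(records, indent=1))
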