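"""Physical sizing of detections, population ratio tables, and
device-agreement statistics for dilution / mixture experiments.

All sizing flows through one calibration: ``size_um = normalized_extent x
image_px x um_per_px`` with the default scale 57.37 um across a 416-px tile
(0.13791 um/px).  Bounding boxes overestimate non-spherical cells slightly;
a ~2 um margin of error is the practical accuracy of box-derived sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synth_flow import UM_PER_PX
from .yolo_io import Annotation, ClassScheme, Detection, NormBox

__all__ = [
    "SizeRecord",
    "CountTable",
    "AgreementStats",
    "box_to_microns",
    "size_distribution",
    "size_summary",
    "ratio_table",
    "compare_ratios",
]


@dataclass(frozen=True)
class SizeRecord:
    class_name: str
    width_um: float
    height_um: float


@dataclass(frozen=True)
class CountTable:
    """Per-class counts plus fractions of the total (None when empty)."""

    counts: Mapping[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float | None]:
        total = self.total
        if total == 0:
            return {name: None for name in self.counts}
        return {name: c / total for name, c in self.counts.items()}


@dataclass(frozen=True)
class AgreementStats:
    """Least-squares agreement of one ratio series against another."""

    slope: float
    intercept: float
    r_squared: float
    stderr_slope: float
    n: int


def box_to_microns(
    box: NormBox, image_px: tuple[int, int], um_per_px: float = UM_PER_PX
) -> tuple[float, float]:
    """Physical (width_um, height_um) of a normalized box."""
    if um_per_px <= 0:
        raise ValueError("um_per_px must be positive")
    w_px, h_px = image_px
    return box.w * w_px * um_per_px, box.h * h_px * um_per_px


def size_distribution(
    objects_by_image: Mapping[str, Sequence[Detection | Annotation]],
    image_px: Mapping[str, tuple[int, int]] | tuple[int, int],
    scheme: ClassScheme,
    um_per_px: float = UM_PER_PX,
) -> list[SizeRecord]:
    """One SizeRecord per detection/annotation.

    ``image_px`` is either one (w, h) applying to every image, or a map
    image_id -> (w, h).
    """
    records: list[SizeRecord] = []
    for image_id, objects in objects_by_image.items():
        px = image_px[image_id] if isinstance(image_px, Mapping) else image_px
        for obj in objects:
            w_um, h_um = box_to_microns(obj.box, px, um_per_px)
            records.append(SizeRecord(scheme.names[obj.class_id], w_um, h_um))
    return records


def size_summary(records: Iterable[SizeRecord]) -> pd.DataFrame:
    """Per-class quantiles (10/25/50/75/90%) of width and height in um."""
    df = pd.DataFrame([(r.class_name, r.width_um, r.height_um) for r in records],
                      columns=["class_name", "width_um", "height_um"])
    if df.empty:
        return df
    return (
        df.groupby("class_name")[["width_um", "height_um"]]
        .quantile([0.10, 0.25, 0.50, 0.75, 0.90])
        .unstack()
    )


def ratio_table(
    objects: Iterable[Detection | Annotation], scheme: ClassScheme
) -> CountTable:
    """Per-class counts and fractions of the total cell count.

    Consolidation-aware: pass objects already remapped to a 6-, 4- or
    3-class scheme and the table follows that scheme.
    """
    counts = {name: 0 for name in scheme.names}
    for obj in objects:
        scheme.validate_id(obj.class_id)
        counts[scheme.names[obj.class_id]] += 1
    return CountTable(counts)


def compare_ratios(
    x: Sequence[CountTable], y: Sequence[CountTable]
) -> dict[str, AgreementStats | None]:
    """Per-class ordinary least squares of y-fractions on x-fractions over
    paired samples (e.g. device vs flow-cytometry ratio series).

    R^2 is the squared Pearson correlation.  A class with zero variance on
    either axis gets None (undefined), mirroring how a constant series
    carries no correlation information.  Requires >= 3 pairs.
    """
    from scipy import stats

    if len(x) != len(y):
        raise ValueError(f"paired series differ in length: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError(f"need >= 3 paired samples, got {len(x)}")
    classes = list(x[0].counts.keys())
    for t in list(x) + list(y):
        if list(t.counts.keys()) != classes:
            raise ValueError("all count tables must share one class scheme")

    out: dict[str, AgreementStats | None] = {}
    for name in classes:
        xs = np.array([t.fractions[name] for t in x], dtype=np.float64)
        ys = np.array([t.fractions[name] for t in y], dtype=np.float64)
        if np.isnan(xs).any() or np.isnan(ys).any():
            raise ValueError(f"empty count table in series for class {name!r}")
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            out[name] = None
            continue
        res = stats.linregress(xs, ys)
        out[name] = AgreementStats(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(res.rvalue) ** 2,
            stderr_slope=float(res.stderr),
            n=len(xs),
        )
    return out
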