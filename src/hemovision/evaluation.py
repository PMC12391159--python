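"""Detection-evaluation methodology: IoU matching at threshold 0.75,
confusion matrices with a non-detected column, per-class and macro
precision/recall/F1, and stratified 5-fold cross-validation bookkeeping.

Matching rules
--------------
Detections are processed in descending confidence (ties: descending best
IoU, then input order).  Each claims its highest-IoU *unmatched* annotation
provided that IoU is at least the threshold (default 0.75, inclusive).  A
claimed pair is a true positive when the classes agree and a wrong-class
false positive otherwise — either way the pair fills the confusion cell
``[ground-truth class, predicted class]``.  A detection whose best IoU over
all annotations is below the threshold is a spurious false positive; one
whose only qualifying annotations are already claimed is a duplicate false
positive.  Annotations left unclaimed are non-detected (false negatives).

Metric conventions
------------------
``recall_c = diag_c / row_total_c`` — misclassified and non-detected both
count against recall.  ``precision_c = diag_c / (column_total_c +
spurious_c)``.  F1 is the harmonic mean.  Macro metrics are unweighted means
over classes.  Reported percentages round half-up to one decimal.
"""

from __future__ import annotations

import csv
import enum
import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .yolo_io import Annotation, ClassScheme, Detection, LabeledImage, NormBox

__all__ = [
    "Outcome",
    "MatchResult",
    "ConfusionMatrix",
    "ClassMetrics",
    "FoldSplit",
    "CVReport",
    "iou",
    "match_detections",
    "confusion_from_matches",
    "evaluate_image_set",
    "metrics_from_confusion",
    "macro_metrics",
    "stratified_split",
    "aggregate_folds",
    "round_half_up",
    "load_confusion_csv",
    "save_confusion_csv",
]


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero at *decimals* places (reporting convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# IoU and matching
# ---------------------------------------------------------------------------

def iou(a: NormBox, b: NormBox) -> float:
    """Intersection-over-union of two axis-aligned normalized boxes."""
    # corner-derived areas keep iou(b, b) exactly 1.0
    area_a = (a.x1 - a.x0) * (a.y1 - a.y0)
    area_b = (b.x1 - b.x0) * (b.y1 - b.y0)
    if area_a == 0 or area_b == 0:
        raise ValueError("zero-area box")
    ix = max(0.0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0.0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    if inter == 0.0:
        return 0.0
    return inter / (area_a + area_b - inter)


class Outcome(enum.Enum):
    TP = "TP"
    FP_WRONG_CLASS = "FP_WRONG_CLASS"
    FP_SPURIOUS = "FP_SPURIOUS"
    FP_DUPLICATE = "FP_DUPLICATE"


@dataclass
class MatchResult:
    """One image's matching outcome.

    ``matched_detection[i]`` is the index of the detection claiming
    annotation *i* (or None); ``outcomes[j]`` labels detection *j*.
    """

    annotations: list[Annotation]
    detections: list[Detection]
    matched_detection: list[int | None]
    outcomes: list[Outcome]
    iou_threshold: float

    @property
    def n_non_detected(self) -> int:
        return sum(1 for m in self.matched_detection if m is None)


def match_detections(
    annotations: Sequence[Annotation],
    detections: Sequence[Detection],
    iou_threshold: float = 0.75,
) -> MatchResult:
    """Greedy one-to-one matching of detections to annotations (see module
    docstring for the claiming rule)."""
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError(f"iou_threshold must be in (0, 1], got {iou_threshold}")
    annotations = list(annotations)
    detections = list(detections)
    n_ann, n_det = len(annotations), len(detections)

    ious = np.zeros((n_det, n_ann))
    for j, det in enumerate(detections):
        for i, ann in enumerate(annotations):
            ious[j, i] = iou(det.box, ann.box)
    best = ious.max(axis=1) if n_ann else np.zeros(n_det)

    order = sorted(range(n_det), key=lambda j: (-detections[j].confidence, -best[j], j))
    matched_detection: list[int | None] = [None] * n_ann
    outcomes: list[Outcome | None] = [None] * n_det
    claimed = [False] * n_ann

    for j in order:
        if n_ann == 0 or best[j] < iou_threshold:
            outcomes[j] = Outcome.FP_SPURIOUS
            continue
        candidates = [
            i for i in range(n_ann) if not claimed[i] and ious[j, i] >= iou_threshold
        ]
        if not candidates:
            outcomes[j] = Outcome.FP_DUPLICATE
            continue
        i = max(candidates, key=lambda i: (ious[j, i], -i))
        claimed[i] = True
        matched_detection[i] = j
        outcomes[j] = (
            Outcome.TP
            if detections[j].class_id == annotations[i].class_id
            else Outcome.FP_WRONG_CLASS
        )

    return MatchResult(
        annotations=annotations,
        detections=detections,
        matched_detection=matched_detection,
        outcomes=[o for o in outcomes],  # all filled
        iou_threshold=iou_threshold,
    )


# ---------------------------------------------------------------------------
# Confusion matrix
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """K x (K+1) ground-truth-by-(predicted + non-detected) counts plus a
    per-predicted-class spurious vector.

    ``counts[g, p]`` for p < K is the number of ground-truth class-*g*
    objects claimed by a class-*p* detection; ``counts[g, K]`` is the
    non-detected column.  ``spurious[p]`` counts class-*p* detections that
    matched no ground truth (below-threshold or duplicate).
    """

    class_names: tuple[str, ...]
    counts: np.ndarray
    spurious: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.class_names)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.spurious = np.asarray(self.spurious, dtype=np.int64)
        if self.counts.shape != (k, k + 1):
            raise ValueError(f"counts must be {k}x{k + 1}, got {self.counts.shape}")
        if self.spurious.shape != (k,):
            raise ValueError(f"spurious must have length {k}")
        if (self.counts < 0).any() or (self.spurious < 0).any():
            raise ValueError("negative counts")

    @property
    def k(self) -> int:
        return len(self.class_names)

    def row_totals(self) -> np.ndarray:
        """Per-class ground-truth totals."""
        return self.counts.sum(axis=1)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.class_names != other.class_names:
            raise ValueError("class schemes differ")
        return ConfusionMatrix(
            self.class_names, self.counts + other.counts, self.spurious + other.spurious
        )

    def merged(self, remap: Mapping[int, int], class_names: Sequence[str]) -> "ConfusionMatrix":
        """Consolidate classes (e.g. echinocyte+erythrocyte -> red cell)."""
        k_new = len(class_names)
        counts = np.zeros((k_new, k_new + 1), dtype=np.int64)
        spurious = np.zeros(k_new, dtype=np.int64)
        for g in range(self.k):
            for p in range(self.k):
                counts[remap[g], remap[p]] += self.counts[g, p]
            counts[remap[g], k_new] += self.counts[g, self.k]
            spurious[remap[g]] += self.spurious[g]
        return ConfusionMatrix(tuple(class_names), counts, spurious)


def confusion_from_matches(
    match_results: Iterable[MatchResult], scheme: ClassScheme
) -> ConfusionMatrix:
    """Accumulate matching outcomes over an image set into one matrix."""
    k = len(scheme)
    counts = np.zeros((k, k + 1), dtype=np.int64)
    spurious = np.zeros(k, dtype=np.int64)
    for mr in match_results:
        for i, ann in enumerate(mr.annotations):
            scheme.validate_id(ann.class_id)
            j = mr.matched_detection[i]
            if j is None:
                counts[ann.class_id, k] += 1
            else:
                pred = mr.detections[j].class_id
                scheme.validate_id(pred)
                counts[ann.class_id, pred] += 1
        for j, outcome in enumerate(mr.outcomes):
            if outcome in (Outcome.FP_SPURIOUS, Outcome.FP_DUPLICATE):
                pred = mr.detections[j].class_id
                scheme.validate_id(pred)
                spurious[pred] += 1
    return ConfusionMatrix(scheme.names, counts, spurious)


def evaluate_image_set(
    labeled: Sequence[LabeledImage],
    detections_by_id: Mapping[str, Sequence[Detection]],
    scheme: ClassScheme,
    iou_threshold: float = 0.75,
) -> tuple[ConfusionMatrix, list[MatchResult]]:
    """Match and accumulate an image set against its detections."""
    results = [
        match_detections(img.annotations, list(detections_by_id.get(img.source_id, ())),
                         iou_threshold)
        for img in labeled
    ]
    return confusion_from_matches(results, scheme), results


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassMetrics:
    """Precision / recall / F1 as fractions in [0, 1] (None = undefined)."""

    precision: float | None
    recall: float | None
    f1: float | None

    def as_percent(self) -> dict[str, float | None]:
        return {
            name: None if v is None else round_half_up(100.0 * v, 1)
            for name, v in (
                ("precision", self.precision),
                ("recall", self.recall),
                ("f1", self.f1),
            )
        }


def _f1(p: float | None, r: float | None) -> float | None:
    if p is None or r is None:
        return None
    return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def metrics_from_confusion(cm: ConfusionMatrix) -> dict[str, ClassMetrics]:
    """Per-class metrics plus the unweighted ``"macro"`` average.

    An empty ground-truth row leaves that class's recall (and F1) undefined
    (None, with a warning), not zero; undefined values are excluded from the
    macro mean.
    """
    k = cm.k
    out: dict[str, ClassMetrics] = {}
    for c, name in enumerate(cm.class_names):
        row_total = int(cm.counts[c].sum())
        col_total = int(cm.counts[:, c].sum()) + int(cm.spurious[c])
        diag = int(cm.counts[c, c])
        if row_total == 0:
            warnings.warn(f"class {name!r} has no ground-truth instances; recall undefined")
            recall = None
        else:
            recall = diag / row_total
        precision = diag / col_total if col_total > 0 else None
        out[name] = ClassMetrics(precision, recall, _f1(precision, recall))
    out["macro"] = macro_metrics(out)
    return out


def macro_metrics(per_class: Mapping[str, ClassMetrics]) -> ClassMetrics:
    """Unweighted mean over classes (``"macro"`` key excluded if present)."""
    items = [m for name, m in per_class.items() if name != "macro"]

    def mean_of(attr: str) -> float | None:
        vals = [getattr(m, attr) for m in items if getattr(m, attr) is not None]
        return sum(vals) / len(vals) if vals else None

    return ClassMetrics(mean_of("precision"), mean_of("recall"), mean_of("f1"))


# ---------------------------------------------------------------------------
# Stratified k-fold 70/20/10 splitting
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    """k folds, each assigning every image id to train/val/test."""

    folds: list[dict[str, str]]  # image_id -> "train" | "val" | "test"
    fractions: tuple[float, float, float]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def subset(self, fold: int, which: str) -> list[str]:
        return [img for img, s in self.folds[fold].items() if s == which]


def _dominant_class(img: LabeledImage) -> int | None:
    if not img.annotations:
        return None
    ids = [a.class_id for a in img.annotations]
    # most frequent class; ties break to the smaller id
    vals, counts = np.unique(ids, return_counts=True)
    return int(vals[np.argmax(counts)])


def _largest_remainder_alloc(n: int, fractions: Sequence[float]) -> list[int]:
    quotas = [f * n for f in fractions]
    counts = [int(math.floor(q)) for q in quotas]
    rem = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def stratified_split(
    dataset: Sequence[LabeledImage],
    k: int = 5,
    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10),
    seed: int = 0,
) -> FoldSplit:
    """Stratified k-fold 70/20/10 splitting by dominant image class.

    Images are bucketed by their dominant annotation class (background
    images form their own bucket); within each bucket a seeded shuffle is
    followed by largest-remainder allocation to train/val/test, so each
    subset's per-class image counts match the pooled proportions to within
    one image.  Each fold reshuffles independently.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    ids = [img.source_id for img in dataset]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate image ids in dataset")
    buckets: dict[int | None, list[str]] = {}
    for img in dataset:
        buckets.setdefault(_dominant_class(img), []).append(img.source_id)
    for cls, members in buckets.items():
        if cls is not None and len(members) < k:
            raise ValueError(
                f"class id {cls} is dominant in only {len(members)} images (< k={k})"
            )

    rng = np.random.default_rng(seed)
    names = ("train", "val", "test")
    folds: list[dict[str, str]] = []
    for _fold in range(k):
        assignment: dict[str, str] = {}
        for cls in sorted(buckets, key=lambda c: (-1 if c is None else c)):
            members = list(buckets[cls])
            rng.shuffle(members)
            counts = _largest_remainder_alloc(len(members), fractions)
            pos = 0
            for subset, count in zip(names, counts):
                for img_id in members[pos : pos + count]:
                    assignment[img_id] = subset
                pos += count
        folds.append(assignment)
    return FoldSplit(folds=folds, fractions=fractions, seed=seed)


# ---------------------------------------------------------------------------
# Fold aggregation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Cross-validation summary: per-fold metrics plus mean and sample sd
    (denominator k-1) for every class and metric, as percentages."""

    per_fold: list[dict[str, ClassMetrics]]
    mean: dict[str, dict[str, float | None]]
    sd: dict[str, dict[str, float | None]]

    def formatted(self) -> dict[str, dict[str, str]]:
        """``mean% +/- sd%`` strings to one decimal."""
        out: dict[str, dict[str, str]] = {}
        for cls in self.mean:
            out[cls] = {}
            for metric in ("precision", "recall", "f1"):
                m, s = self.mean[cls][metric], self.sd[cls][metric]
                if m is None:
                    out[cls][metric] = "n/a"
                else:
                    out[cls][metric] = (
                        f"{round_half_up(m, 1):.1f}% ± {round_half_up(s, 1):.1f}%"
                    )
        return out


def aggregate_folds(per_fold: Sequence[Mapping[str, ClassMetrics]]) -> CVReport:
    """Mean and sample standard deviation (k-1) per class and metric, on the
    percentage scale.  All folds must report the same class set."""
    if len(per_fold) < 2:
        raise ValueError("need at least 2 folds to aggregate")
    class_sets = [tuple(sorted(f.keys())) for f in per_fold]
    if len(set(class_sets)) != 1:
        raise ValueError(f"ragged class sets across folds: {sorted(set(class_sets))}")
    classes = list(per_fold[0].keys())
    mean: dict[str, dict[str, float | None]] = {}
    sd: dict[str, dict[str, float | None]] = {}
    for cls in classes:
        mean[cls], sd[cls] = {}, {}
        for metric in ("precision", "recall", "f1"):
            vals = [getattr(f[cls], metric) for f in per_fold]
            if any(v is None for v in vals):
                mean[cls][metric] = None
                sd[cls][metric] = None
            else:
                arr = 100.0 * np.asarray(vals, dtype=np.float64)
                mean[cls][metric] = float(arr.mean())
                sd[cls][metric] = float(arr.std(ddof=1))
    return CVReport(per_fold=list(per_fold), mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# Confusion-matrix CSV fixtures
# ---------------------------------------------------------------------------

def load_confusion_csv(path: str | Path) -> ConfusionMatrix:
    """Load a confusion-matrix CSV.

    Layout: header ``ground_truth, <class...>, non_detected[, ...]``; one
    row per ground-truth class; an optional final ``spurious`` row.  Printed
    reference matrices carry no spurious row, in which case spurious = 0 —
    which is exactly consistent with their printed precisions.
    """
    rows = list(csv.reader(Path(path).read_text().splitlines()))
    rows = [r for r in rows if r and any(cell.strip() for cell in r)]
    header = [c.strip() for c in rows[0]]
    if header[-1].lower().replace(" ", "_") != "non_detected":
        raise ValueError(f"{path}: last header column must be non_detected, got {header[-1]!r}")
    class_names = tuple(header[1:-1])
    k = len(class_names)
    counts = np.zeros((k, k + 1), dtype=np.int64)
    spurious = np.zeros(k, dtype=np.int64)
    body = rows[1:]
    seen = []
    for r in body:
        label = r[0].strip()
        values = [int(c.strip().replace(",", "")) for c in r[1:]]
        if label.lower() == "spurious":
            if len(values) < k:
                raise ValueError(f"{path}: spurious row needs {k} values")
            spurious[:] = values[:k]
            continue
        if label not in class_names:
            raise ValueError(f"{path}: unknown ground-truth class {label!r}")
        if len(values) != k + 1:
            raise ValueError(f"{path}: row {label!r} needs {k + 1} values, got {len(values)}")
        counts[class_names.index(label)] = values
        seen.append(label)
    if set(seen) != set(class_names):
        raise ValueError(f"{path}: missing rows for {set(class_names) - set(seen)}")
    return ConfusionMatrix(class_names, counts, spurious)


def save_confusion_csv(cm: ConfusionMatrix, path: str | Path) -> None:
    lines = ["ground_truth," + ",".join(cm.class_names) + ",non_detected"]
    for g, name in enumerate(cm.class_names):
        lines.append(name + "," + ",".join(str(int(v)) for v in cm.counts[g]))
    lines.append("spurious," + ",".join(str(int(v)) for v in cm.spurious) + ",0")
    Path(path).write_text("\n".join(lines) + "\n")
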