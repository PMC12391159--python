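"""Packaged reference confusion matrices.

Six published single-fold confusion matrices of the YOLOv4 blood-cell
detectors ship as CSV fixtures, each a ground-truth-by-(predicted +
non-detected) table with class-name headers:

===========================  ====================================================
name                         detector
===========================  ====================================================
``two_class_initial``        echinocyte vs erythrocyte, pre-optimisation
``two_class_optimised``      echinocyte vs erythrocyte, tuned hyperparameters
``four_class``               echinocyte / erythrocyte / leukocyte / platelet
``four_class_redcell_merged``  the four-class run with red-cell classes merged
``six_class``                full six-class vocabulary
``three_class``              red cell / leukocyte / platelet consolidation
===========================  ====================================================

Printed matrices carry no spurious-detection row; loading them with
spurious = 0 reproduces their published precisions exactly.
"""

from __future__ import annotations

from importlib import resources

from .evaluation import ConfusionMatrix, load_confusion_csv

__all__ = ["TABLE_NAMES", "load_reference_table"]

TABLE_NAMES = (
    "two_class_initial",
    "two_class_optimised",
    "four_class",
    "four_class_redcell_merged",
    "six_class",
    "three_class",
)


def load_reference_table(name: str) -> ConfusionMatrix:
    """Load one packaged reference confusion matrix by name."""
    if name not in TABLE_NAMES:
        raise KeyError(f"unknown table {name!r}; choose from {TABLE_NAMES}")
    ref = resources.files("hemovision.data.tables") / f"{name}.csv"
    with resources.as_file(ref) as path:
        return load_confusion_csv(path)
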