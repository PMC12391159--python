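"""Shared brute-force oracles used by the unit and acceptance tests."""

import numpy as np


def rasterized_iou_unionbox(a, b, res=4000):
    """Brute-force IoU by pixel counting on a grid scaled to the union's
    bounding box (keeps sliver intersections well resolved)."""
    x_lo, x_hi = min(a.x0, b.x0), max(a.x1, b.x1)
    y_lo, y_hi = min(a.y0, b.y0), max(a.y1, b.y1)
    sx, sy = x_hi - x_lo, y_hi - y_lo
    grid_a = np.zeros((res, res), dtype=bool)
    grid_b = np.zeros((res, res), dtype=bool)
    for g, bx in ((grid_a, a), (grid_b, b)):
        g[round((bx.y0 - y_lo) / sy * res): round((bx.y1 - y_lo) / sy * res),
          round((bx.x0 - x_lo) / sx * res): round((bx.x1 - x_lo) / sx * res)] = True
    inter = np.logical_and(grid_a, grid_b).sum()
    union = np.logical_or(grid_a, grid_b).sum()
    return inter / union
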