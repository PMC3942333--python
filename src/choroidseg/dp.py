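"""Dynamic-programming boundary tracking.

The RPE is the brightest near-horizontal band of an EDI-OCT B-scan, so
it is located by tracing the globally cheapest left-to-right path
through the *inverted* image, where each pixel's cost is its (inverted)
brightness and the path may move at most ``step_bound`` rows between
adjacent columns.  Bruch's membrane is then placed at the strongest
axial gradient just below the traced RPE, and everything above it is
zeroed out so the later texture stages see only choroid and sclera.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .core import BoundaryCurve, BScanImage

__all__ = [
    "DPResult",
    "trace_optimal_path",
    "detect_rpe",
    "detect_bm",
    "zero_above",
]

log = logging.getLogger(__name__)


@dataclass
class DPResult:
    """Outcome of a dynamic-programming path search.

    ``predecessors[k, m]`` holds the row offset (relative to row ``k``)
    of the optimal predecessor in column ``m - 1``; column 0 stores 0.
    """

    path: BoundaryCurve
    total_cost: float
    cost_table: np.ndarray
    predecessors: np.ndarray


def trace_optimal_path(cost_image: np.ndarray, step_bound: int = 1) -> DPResult:
    """Minimum-cost left-to-right path through a node-cost image.

    Columns are the graph layers, rows the nodes within a layer.  The
    cumulative cost of a node in column ``m`` is its own cost plus the
    cheapest cumulative cost among the rows within ``step_bound`` of it
    in column ``m - 1``; the first column is initialized with the node
    costs themselves.  The optimal path is recovered by backtracking
    from the cheapest node of the last column.

    Ties are broken deterministically: among equal-cost predecessors
    the offsets are preferred in the order 0, -1, +1, -2, +2, ...; among
    equal-cost terminal nodes the smallest row index wins.
    """
    cost = np.asarray(cost_image, dtype=float)
    if cost.ndim != 2:
        raise ValueError("cost image must be 2-D")
    n_rows, n_cols = cost.shape
    if n_cols < 1 or n_rows < 1:
        raise ValueError("cost image must have at least one column and row")
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost image contains non-finite values")
    if step_bound < 0:
        raise ValueError("step_bound must be non-negative")

    offsets = [0]
    for s in range(1, step_bound + 1):
        offsets.extend([-s, s])
    offsets_arr = np.asarray(offsets)

    cum = np.empty_like(cost)
    pred = np.zeros(cost.shape, dtype=np.int64)
    cum[:, 0] = cost[:, 0]

    cand = np.empty((len(offsets), n_rows))
    for m in range(1, n_cols):
        cand.fill(np.inf)
        prev = cum[:, m - 1]
        for j, off in enumerate(offsets):
            # predecessor of row k sits at row k + off in column m - 1
            if off == 0:
                cand[j, :] = prev
            elif off > 0:
                cand[j, : n_rows - off] = prev[off:]
            else:
                cand[j, -off:] = prev[: n_rows + off]
        best = np.argmin(cand, axis=0)  # first minimum -> preferred offset
        cum[:, m] = cost[:, m] + cand[best, np.arange(n_rows)]
        pred[:, m] = offsets_arr[best]

    end_row = int(np.argmin(cum[:, -1]))
    rows = np.empty(n_cols, dtype=np.int64)
    rows[-1] = end_row
    for m in range(n_cols - 1, 0, -1):
        rows[m - 1] = rows[m] + pred[rows[m], m]
    return DPResult(
        path=BoundaryCurve(rows),
        total_cost=float(cum[end_row, -1]),
        cost_table=cum,
        predecessors=pred,
    )


def detect_rpe(image: BScanImage, step_bound: int = 1) -> BoundaryCurve:
    """Trace the RPE as the brightest path across the B-scan.

    The DP search minimizes cost, so the image brightness is inverted
    (``max - I``) before tracing.
    """
    inverted = image.pixels.max() - image.pixels
    return trace_optimal_path(inverted, step_bound=step_bound).path


def detect_bm(
    image: BScanImage,
    rpe: BoundaryCurve,
    search_depth: int = 8,
    smooth_window: int = 5,
) -> BoundaryCurve:
    """Locate Bruch's membrane below a traced RPE curve.

    Per column the row in ``(rpe, rpe + search_depth]`` with the largest
    axial intensity-gradient magnitude (central differences) is taken,
    and the resulting curve is median-smoothed across columns.  Columns
    whose search window falls entirely outside the image take the
    nearest valid row.
    """
    rpe.validate_for(image)
    if search_depth < 1:
        raise ValueError("search_depth must be at least 1")
    n_rows = image.n_rows
    grad = np.abs(np.gradient(image.pixels, axis=0))
    rows = np.empty(image.n_cols, dtype=np.int64)
    n_clipped = 0
    for c in range(image.n_cols):
        lo = int(rpe.rows[c]) + 1
        hi = min(int(rpe.rows[c]) + search_depth, n_rows - 1)
        if lo > n_rows - 1:
            rows[c] = n_rows - 1
            n_clipped += 1
            continue
        rows[c] = lo + int(np.argmax(grad[lo : hi + 1, c]))
    if n_clipped:
        log.warning(
            "BM search window fell outside the image in %d column(s); "
            "nearest valid row used",
            n_clipped,
        )
    smoothed = median_filter(rows.astype(float), size=smooth_window, mode="nearest")
    smoothed = np.clip(np.rint(smoothed).astype(np.int64), 0, n_rows - 1)
    # anatomical ordering: BM never above the RPE curve
    smoothed = np.maximum(smoothed, np.asarray(rpe.rows, dtype=np.int64))
    return BoundaryCurve(smoothed)


def zero_above(image: BScanImage, boundary: BoundaryCurve) -> BScanImage:
    """Return a copy of ``image`` with pixels strictly above ``boundary`` set to 0."""
    boundary.validate_for(image)
    out = image.pixels.copy()
    row_idx = np.arange(image.n_rows)[:, None]
    out[row_idx < np.asarray(boundary.rows)[None, :]] = 0.0
    return BScanImage(
        out,
        axial_res_um=image.axial_res_um,
        transversal_res_um=image.transversal_res_um,
    )
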