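"""Spatially coherent multi-label segmentation by graph cuts.

The segmentation minimizes a data term, ``-log(p + eps)`` of the
per-pixel class posteriors, plus a constant Potts smoothness term that
charges ``r`` for every 4-connected neighbor pair with different labels.
The two-label case is solved exactly as a single minimum s-t cut; with
three or more labels an exact multiway cut is NP-hard, so alpha
expansion is used: each move (letting any pixel switch to label alpha)
is itself an exact binary min-cut, and sweeps continue until no move
lowers the energy.  Max-flow problems are solved with
:func:`scipy.sparse.csgraph.maximum_flow` on integer-scaled capacities.

After labeling, the choroid-sclera interface is read off the label map
as the deepest choroid-labeled row of each column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .core import BoundaryCurve
from .mixture import LABEL_CHOROID, ResponsibilityMaps

__all__ = [
    "UnaryCostVolume",
    "PairwiseCostMatrix",
    "LabelMap",
    "build_data_term",
    "build_smooth_term",
    "total_energy",
    "segment_labels",
    "extract_csi",
]

log = logging.getLogger(__name__)

MACHINE_EPS = float(np.finfo(float).eps)  # 2.220446049250313e-16


@dataclass
class UnaryCostVolume:
    """Per-pixel, per-label assignment costs, shape ``(K, rows, cols)``."""

    costs: np.ndarray

    def __post_init__(self) -> None:
        self.costs = np.asarray(self.costs, dtype=float)
        if self.costs.ndim != 3:
            raise ValueError("unary costs must be (K, rows, cols)")
        if not np.all(np.isfinite(self.costs)):
            raise ValueError("unary costs must be finite")
        if np.any(self.costs < 0):
            raise ValueError("unary costs must be non-negative")

    @property
    def K(self) -> int:
        return self.costs.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.costs.shape[1:]


@dataclass
class PairwiseCostMatrix:
    """Constant Potts label-interaction costs: 0 diagonal, ``r`` elsewhere."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        K = self.matrix.shape[0]
        if self.matrix.shape != (K, K) or K < 2:
            raise ValueError("pairwise matrix must be square, K >= 2")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("pairwise matrix must have a zero diagonal")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("pairwise matrix must be symmetric")
        off = self.matrix[~np.eye(K, dtype=bool)]
        if not np.allclose(off, off[0]) or off[0] <= 0:
            raise ValueError("off-diagonal entries must be one positive constant")

    @property
    def K(self) -> int:
        return self.matrix.shape[0]

    @property
    def r(self) -> float:
        return float(self.matrix[0, 1])


@dataclass
class LabelMap:
    """Per-pixel labels in ``{1, ..., K}``."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        if np.any(self.labels < 1):
            raise ValueError("labels start at 1; every pixel must be labeled")


def build_data_term(
    probs: ResponsibilityMaps, eps: float = MACHINE_EPS
) -> UnaryCostVolume:
    """Data term ``-log(p + eps)``, clamped below at zero."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    return UnaryCostVolume(np.maximum(-np.log(probs.probs + eps), 0.0))


def build_smooth_term(K: int = 3, r: float = 4.0) -> PairwiseCostMatrix:
    """Constant Potts matrix: zeros on the diagonal, ``r`` off it."""
    if K < 2:
        raise ValueError("need at least two labels")
    if r <= 0:
        raise ValueError("smoothness constant r must be positive")
    return PairwiseCostMatrix(r * (1.0 - np.eye(K)))


def total_energy(
    labels: LabelMap, unary: UnaryCostVolume, pairwise: PairwiseCostMatrix
) -> float:
    """Energy of a labeling: unary costs plus Potts costs over 4-neighbors."""
    l0 = labels.labels - 1
    if l0.shape != unary.image_shape:
        raise ValueError("label map shape does not match the unary volume")
    rows, cols = np.indices(l0.shape)
    data = unary.costs[l0, rows, cols].sum()
    smooth = (
        pairwise.matrix[l0[:, :-1], l0[:, 1:]].sum()
        + pairwise.matrix[l0[:-1, :], l0[1:, :]].sum()
    )
    return float(data + smooth)


def _neighbor_pairs(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Flattened indices of 4-connected neighbor pairs (p, q)."""
    h, w = shape
    idx = np.arange(h * w).reshape(h, w)
    p = np.concatenate([idx[:, :-1].ravel(), idx[:-1, :].ravel()])
    q = np.concatenate([idx[:, 1:].ravel(), idx[1:, :].ravel()])
    return p, q


def _solve_cut(
    n_pixels: int,
    src_cap: np.ndarray,
    snk_cap: np.ndarray,
    edge_p: np.ndarray,
    edge_q: np.ndarray,
    edge_cap: np.ndarray,
    scale: float,
) -> np.ndarray:
    """Exact binary min-cut; returns a boolean mask of source-side pixels.

    Capacities are scaled by ``scale`` and rounded to integers for the
    max-flow solver.  The capacity matrix is symmetrized, which leaves
    every s-t cut's (directed) cost unchanged.
    """
    s, t = n_pixels, n_pixels + 1
    pix = np.arange(n_pixels)
    rows = np.concatenate([np.full(n_pixels, s), pix, edge_p])
    cols = np.concatenate([pix, np.full(n_pixels, t), edge_q])
    caps = np.concatenate([src_cap, snk_cap, edge_cap])
    icaps = np.rint(caps * scale).astype(np.int64)
    keep = icaps > 0
    graph = csr_matrix(
        (icaps[keep], (rows[keep], cols[keep])), shape=(n_pixels + 2, n_pixels + 2)
    )
    graph = graph + graph.T
    try:
        result = maximum_flow(graph, s, t)
    except Exception as exc:  # pragma: no cover - solver failure surface
        raise RuntimeError(f"max-flow solver failed: {exc}") from exc
    residual = graph - result.flow
    residual.data[residual.data < 0] = 0
    residual.eliminate_zeros()
    reached = breadth_first_order(residual, s, directed=True, return_predecessors=False)
    mask = np.zeros(n_pixels, dtype=bool)
    reached = reached[reached < n_pixels]
    mask[reached] = True
    return mask


def _expansion_move(
    labels0: np.ndarray,
    unary: np.ndarray,
    r: float,
    alpha: int,
    scale: float,
) -> np.ndarray:
    """One alpha-expansion move (0-based labels), solved as a binary cut.

    Pixels end up on the source side of the cut iff they switch to
    ``alpha``.  The Potts interaction of a pair with two different
    current labels (neither alpha) is split symmetrically: r/2 on each
    pixel's keep-cost plus an r/2 link.
    """
    shape = labels0.shape
    n = labels0.size
    flat = labels0.ravel()
    is_alpha = flat == alpha
    rows, cols = np.indices(shape)
    d_keep = unary[flat.reshape(shape), rows, cols].ravel()
    d_alpha = unary[alpha].ravel()

    src = np.where(is_alpha, 0.0, d_keep)  # cut when pixel keeps its label
    snk = np.where(is_alpha, 0.0, d_alpha)  # cut when pixel takes alpha

    p, q = _neighbor_pairs(shape)
    lp, lq = flat[p], flat[q]
    pa, qa = lp == alpha, lq == alpha

    m = pa & ~qa  # neighbor fixed at alpha: charge q for keeping
    np.add.at(src, q[m], r)
    m = qa & ~pa
    np.add.at(src, p[m], r)

    same = (lp == lq) & ~pa
    diff = (lp != lq) & ~pa & ~qa
    np.add.at(src, p[diff], r / 2)
    np.add.at(src, q[diff], r / 2)

    edge_p = np.concatenate([p[same], p[diff]])
    edge_q = np.concatenate([q[same], q[diff]])
    edge_cap = np.concatenate(
        [np.full(same.sum(), r), np.full(diff.sum(), r / 2)]
    )

    take_alpha = _solve_cut(n, src, snk, edge_p, edge_q, edge_cap, scale)
    out = flat.copy()
    out[take_alpha] = alpha
    return out.reshape(shape)


def segment_labels(
    unary: UnaryCostVolume,
    pairwise: PairwiseCostMatrix,
    init: LabelMap | None = None,
    scale: float = 1e4,
    max_sweeps: int = 10,
) -> LabelMap:
    """Minimize unary + Potts energy over labelings.

    ``K = 2`` is solved exactly with a single cut; for larger ``K``
    alpha-expansion starts from ``init`` (default: per-pixel unary
    argmin) and accepts a move only if it strictly lowers the energy, so
    the result never has higher energy than the initialization.
    """
    K = unary.K
    if pairwise.K != K:
        raise ValueError("unary and pairwise label counts differ")
    r = pairwise.r
    shape = unary.image_shape
    if init is None:
        labels0 = np.argmin(unary.costs, axis=0)
    else:
        if init.labels.shape != shape:
            raise ValueError("init label map shape mismatch")
        if np.any(init.labels > K):
            raise ValueError("init labels exceed K")
        labels0 = init.labels.astype(np.int64) - 1

    if K == 2:
        # exact: source side <-> label 2
        p, q = _neighbor_pairs(shape)
        take = _solve_cut(
            labels0.size,
            unary.costs[0].ravel(),
            unary.costs[1].ravel(),
            p,
            q,
            np.full(p.size, r),
            scale,
        )
        out = np.where(take.reshape(shape), 2, 1)
        return LabelMap(out)

    current = labels0
    energy = total_energy(LabelMap(current + 1), unary, pairwise)
    for sweep in range(max_sweeps):
        improved = False
        for alpha in range(K):
            try:
                proposal = _expansion_move(current, unary.costs, r, alpha, scale)
            except RuntimeError as exc:
                raise RuntimeError(
                    f"expansion move for label {alpha + 1} (sweep {sweep}) "
                    f"failed: {exc}"
                ) from exc
            e_new = total_energy(LabelMap(proposal + 1), unary, pairwise)
            if e_new < energy:
                current, energy = proposal, e_new
                improved = True
        if not improved:
            break
    return LabelMap(current + 1)


def extract_csi(labels: LabelMap, smooth_window: int = 15) -> BoundaryCurve:
    """Choroid-sclera interface: deepest choroid-labeled row per column.

    Columns with no choroid pixel are filled by linear interpolation
    from neighboring columns; the curve is then median-smoothed.
    """
    grid = labels.labels == LABEL_CHOROID
    if not grid.any():
        raise ValueError("label map contains no choroid pixels")
    n_rows, n_cols = grid.shape
    has = grid.any(axis=0)
    deepest = n_rows - 1 - np.argmax(grid[::-1, :], axis=0)
    cols = np.arange(n_cols)
    filled = np.interp(cols, cols[has], deepest[has].astype(float))
    smoothed = median_filter(filled, size=smooth_window, mode="nearest")
    return BoundaryCurve(np.clip(np.rint(smoothed).astype(np.int64), 0, n_rows - 1))
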