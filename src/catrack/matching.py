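"""Cross-session cell matching.

Cell masks from one session are mapped into the other session's
coordinate frame (registration module), then matched by solving the
linear sum assignment problem with cost = 1 − IoU, set to exactly 1
for pairs whose centroids are more than 10 px apart, keeping only
matches with cost < 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .masks import CellMask
from .registration import ShiftField, apply_shift_field

GATE_DIST_PX = 10.0
COST_THRESHOLD = 0.8


def iou(mask_a: CellMask, mask_b: CellMask) -> float:
    """Binary intersection over union of two pixel sets; 0 if disjoint."""
    if mask_a.area_px2 == 0 or mask_b.area_px2 == 0:
        raise ValueError("IoU undefined for an empty mask")
    a = {tuple(p) for p in mask_a.pixels}
    b = {tuple(p) for p in mask_b.pixels}
    inter = len(a & b)
    union = len(a | b)
    return inter / union


@dataclass
class CostMatrix:
    """1 − IoU costs with a hard centroid-distance gate."""

    values: np.ndarray  # (n_a, n_b) in [0, 1]
    gate_dist_px: float


def build_cost_matrix(
    masks_a: list[CellMask],
    masks_b: list[CellMask],
    gate_dist_px: float = GATE_DIST_PX,
) -> CostMatrix:
    """cost[i, j] = 1 − IoU(a_i, b_j); exactly 1 beyond the distance gate.

    Masks must already live in a common coordinate frame.  Masks in
    different imaging planes never match (cost 1).
    """
    n_a, n_b = len(masks_a), len(masks_b)
    values = np.ones((n_a, n_b))
    if n_a == 0 or n_b == 0:
        return CostMatrix(values=values, gate_dist_px=gate_dist_px)
    cent_a = np.array([m.centroid_px for m in masks_a])
    cent_b = np.array([m.centroid_px for m in masks_b])
    sets_b = [{tuple(p) for p in m.pixels} for m in masks_b]
    for i, ma in enumerate(masks_a):
        sa = {tuple(p) for p in ma.pixels}
        for j in range(n_b):
            if masks_a[i].plane_index != masks_b[j].plane_index:
                continue
            d = np.hypot(*(cent_a[i] - cent_b[j]))
            if d > gate_dist_px:
                continue  # gated: stays exactly 1
            inter = len(sa & sets_b[j])
            union = len(sa) + len(sets_b[j]) - inter
            values[i, j] = 1.0 - inter / union
    return CostMatrix(values=values, gate_dist_px=gate_dist_px)


def solve_assignment(cost: "CostMatrix | np.ndarray") -> list[tuple[int, int, float]]:
    """Minimum-total-cost partial bijection over a rectangular matrix.

    Returns (row, col, cost) triples sorted by row index (the
    deterministic tie-break).
    """
    values = cost.values if isinstance(cost, CostMatrix) else np.asarray(cost,
                                                                         dtype=float)
    if values.size == 0:
        return []
    if not np.all(np.isfinite(values)):
        raise ValueError("cost matrix must be finite")
    rows, cols = linear_sum_assignment(values)
    pairs = [(int(i), int(j), float(values[i, j])) for i, j in zip(rows, cols)]
    pairs.sort(key=lambda p: p[0])
    return pairs


@dataclass
class MatchResult:
    """Kept cross-session pairings plus the leftovers on each side."""

    pairs: list[tuple[int, int, float]]  # (i in A, j in B, cost)
    unmatched_a: list[int]
    unmatched_b: list[int]
    threshold: float


def match_cells(
    masks_a: list[CellMask],
    masks_b: list[CellMask],
    shift_field: ShiftField | None = None,
    *,
    threshold: float = COST_THRESHOLD,
    gate_dist_px: float = GATE_DIST_PX,
    frame_shape: tuple[int, int] | None = None,
) -> MatchResult:
    """Map session-A masks into B's frame, assign, and threshold.

    Assigned pairs with cost ≥ ``threshold`` are dropped into the
    unmatched sets (gated pairs at cost exactly 1 can enter the
    assignment but can never pass the 0.8 cutoff).
    """
    mapped = (apply_shift_field(masks_a, shift_field, shape=frame_shape)
              if shift_field is not None else masks_a)
    cost = build_cost_matrix(mapped, masks_b, gate_dist_px=gate_dist_px)
    assigned = solve_assignment(cost)
    kept = [(i, j, c) for i, j, c in assigned if c < threshold]
    in_a = {i for i, _, _ in kept}
    in_b = {j for _, j, _ in kept}
    return MatchResult(
        pairs=kept,
        unmatched_a=sorted(set(range(len(masks_a))) - in_a),
        unmatched_b=sorted(set(range(len(masks_b))) - in_b),
        threshold=threshold,
    )


def split_matched_unique(
    match: MatchResult, n_cells_a: int, n_cells_b: int
) -> dict:
    """Partition both sessions into matched pairs and session-unique sets."""
    matched_a = {i for i, _, _ in match.pairs}
    matched_b = {j for _, j, _ in match.pairs}
    return {
        "matched": list(match.pairs),
        "unique_a": sorted(set(range(n_cells_a)) - matched_a),
        "unique_b": sorted(set(range(n_cells_b)) - matched_b),
    }
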