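"""Trial-aligned activity maps.

Aligns ΔF/F traces to the behavioral choice time, averages them into
pre-choice time bins, 0–1 normalizes each cell, sorts cells by their
peak bin, and compares matched vs session-unique cells across two
sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matching import MatchResult
from .synthetic import BehaviorLog

DEFAULT_WINDOW_S = (-4.0, 0.0)  # relative to choice time
DEFAULT_BIN_S = 0.5


@dataclass
class TrialTensor:
    """Mean ΔF/F per (cell, trial, pre-choice time bin)."""

    values: np.ndarray  # (n_cells, n_trials, n_bins)
    bin_width_s: float
    window_s: tuple[float, float]
    bin_edges_s: np.ndarray  # relative to choice
    n_excluded_trials: int
    truncated_trials: list[int]

    def mean_over_trials(self) -> np.ndarray:
        return np.nanmean(self.values, axis=1)


def align_to_choice(
    dff: np.ndarray,
    behavior: BehaviorLog,
    *,
    frame_rate_hz: float,
    window_s: tuple[float, float] = DEFAULT_WINDOW_S,
    bin_width_s: float = DEFAULT_BIN_S,
) -> TrialTensor:
    """Bin each cell's ΔF/F into time bins ending at the choice time.

    ``dff`` is (n_cells, n_frames) on the same clock as the behavior
    log (frame t at time t/frame_rate).  Timeout trials have no choice
    time and are excluded (their count is reported); trials whose
    window extends before the recording start are flagged truncated.
    Raises when no alignable trial remains.
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    t0, t1 = window_s
    if t1 <= t0:
        raise ValueError("window must satisfy t_min < t_max")
    n_bins = int(round((t1 - t0) / bin_width_s))
    if not np.isclose(n_bins * bin_width_s, t1 - t0):
        raise ValueError("bins must tile the window exactly")
    edges = t0 + bin_width_s * np.arange(n_bins + 1)

    usable = [t for t in behavior.trials if t.t_choice is not None]
    n_excluded = behavior.n_trials - len(usable)
    if not usable:
        raise ValueError("no alignable trials")

    n_cells, n_frames = dff.shape
    frame_times = np.arange(n_frames) / frame_rate_hz
    values = np.full((n_cells, len(usable), n_bins), np.nan)
    truncated = []
    for k, trial in enumerate(usable):
        abs_edges = trial.t_choice + edges
        if abs_edges[0] < 0:
            truncated.append(k)
        for b in range(n_bins):
            in_bin = (frame_times >= abs_edges[b]) & (frame_times < abs_edges[b + 1])
            if in_bin.any():
                values[:, k, b] = dff[:, in_bin].mean(axis=1)
    return TrialTensor(values=values, bin_width_s=bin_width_s,
                       window_s=(t0, t1), bin_edges_s=edges,
                       n_excluded_trials=n_excluded,
                       truncated_trials=truncated)


@dataclass
class SortedActivityMap:
    """0–1 normalized per-cell activity, cells ordered by peak bin."""

    normalized: np.ndarray  # (n_cells, n_bins) rows in [0, 1]
    order: np.ndarray  # permutation applied to rows
    peak_bin: np.ndarray  # per original cell


def normalize_and_sort(mean_map: np.ndarray,
                       order: np.ndarray | None = None) -> SortedActivityMap:
    """Min-max normalize each cell to [0, 1] and sort by peak bin.

    A degenerate (zero-range) cell becomes an all-zero row and sorts
    last; ties in peak bin break by cell index.  Passing ``order``
    applies a fixed permutation instead (for cross-session comparison
    on one session's ordering).
    """
    m = np.atleast_2d(np.asarray(mean_map, dtype=float))
    lo = np.nanmin(m, axis=1, keepdims=True)
    hi = np.nanmax(m, axis=1, keepdims=True)
    rng = hi - lo
    degenerate = (rng[:, 0] == 0) | ~np.isfinite(rng[:, 0])
    safe = np.where(rng == 0, 1.0, rng)
    norm = (m - lo) / safe
    norm[degenerate] = 0.0
    peak = np.nanargmax(m, axis=1).astype(float)
    peak[degenerate] = np.inf  # sorted last
    if order is None:
        order = np.lexsort((np.arange(m.shape[0]), peak))
    peak_out = np.where(degenerate, -1, np.nanargmax(m, axis=1)).astype(int)
    return SortedActivityMap(normalized=norm[order], order=np.asarray(order),
                             peak_bin=peak_out)


def top_k_cells(dff: np.ndarray, k: int = 10) -> np.ndarray:
    """Indices of the k cells with the highest session-mean ΔF/F.

    Descending by mean; ties break toward the lower cell index.
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    if k <= 0:
        raise ValueError("k must be positive")
    if k > dff.shape[0]:
        raise ValueError("k exceeds the number of cells")
    means = dff.mean(axis=1)
    order = np.lexsort((np.arange(means.size), -means))
    return order[:k]


def compare_sessions(
    map_a: np.ndarray,
    map_b: np.ndarray,
    match: MatchResult,
) -> dict:
    """Matched and session-unique activity maps for two sessions.

    Matched cells are sorted by their session-A peak bin and that
    ordering is applied to both sessions' maps; unique cells are sorted
    within their own session.  Maps must share the bin layout.
    """
    map_a = np.atleast_2d(np.asarray(map_a, dtype=float))
    map_b = np.atleast_2d(np.asarray(map_b, dtype=float))
    if map_a.shape[1] != map_b.shape[1]:
        raise ValueError("sessions analyzed with different bin layouts")
    idx_a = np.array([i for i, _, _ in match.pairs], dtype=int)
    idx_b = np.array([j for _, j, _ in match.pairs], dtype=int)
    out: dict = {}
    if len(idx_a):
        sub_a = map_a[idx_a]
        sorted_a = normalize_and_sort(sub_a)
        out["matched_a"] = sorted_a
        out["matched_b"] = normalize_and_sort(map_b[idx_b],
                                              order=sorted_a.order)
    else:
        out["matched_a"] = out["matched_b"] = None
    ua = np.array(match.unmatched_a, dtype=int)
    ub = np.array(match.unmatched_b, dtype=int)
    out["unique_a"] = normalize_and_sort(map_a[ua]) if len(ua) else None
    out["unique_b"] = normalize_and_sort(map_b[ub]) if len(ub) else None
    return out
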