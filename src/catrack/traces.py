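"""ΔF/F computation, in both variants the pipeline uses.

The CNMF-style variant detrends the denoised trace by removing its
8th percentile in 500-frame moving windows, estimates the baseline F0
as the detrending residual plus the moving 8th percentile of the global
background under the cell's mask, and divides (unitless output).

The simple variant subtracts a blood-vessel background trace, takes F0
as the mean of a ~2 s inactive stretch of the trace, and reports
ΔF/F0 = (F − F0)/F0 × 100 in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DETREND_WINDOW_FRAMES = 500
DETREND_PERCENTILE = 8.0


@dataclass
class DffTrace:
    dff: np.ndarray
    f0: np.ndarray
    frame_rate_hz: float
    variant: str  # "cnmf" | "simple"


def moving_percentile(
    trace: np.ndarray,
    window_frames: int = DETREND_WINDOW_FRAMES,
    q: float = DETREND_PERCENTILE,
    *,
    causal: bool = False,
) -> np.ndarray:
    """Per-frame q-th percentile over a moving window.

    The window is centered and truncated at the edges (causal mode
    looks back only); a trace shorter than the window gets its global
    percentile everywhere.  Percentiles interpolate linearly between
    order statistics.
    """
    x = np.asarray(trace, dtype=float)
    if x.size == 0:
        raise ValueError("empty trace")
    if window_frames < 2:
        raise ValueError("window must be >= 2 frames")
    if not 0.0 <= q <= 100.0:
        raise ValueError("percentile must lie in [0, 100]")
    n = x.size
    if n <= window_frames:
        return np.full(n, np.percentile(x, q))
    out = np.empty(n)
    half = window_frames // 2
    for t in range(n):
        if causal:
            lo, hi = max(0, t - window_frames + 1), t + 1
        else:
            lo = max(0, t - half)
            hi = min(n, t + (window_frames - half))
        out[t] = np.percentile(x[lo:hi], q)
    return out


def detrend_trace(
    denoised: np.ndarray,
    window_frames: int = DETREND_WINDOW_FRAMES,
    q: float = DETREND_PERCENTILE,
    **kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove the moving 8th percentile; return (detrended, trend)."""
    trend = moving_percentile(denoised, window_frames, q, **kwargs)
    return np.asarray(denoised, dtype=float) - trend, trend


def baseline_f0_cnmf(
    trend: np.ndarray,
    background_in_mask: np.ndarray,
    window_frames: int = DETREND_WINDOW_FRAMES,
    q: float = DETREND_PERCENTILE,
    **kwargs,
) -> np.ndarray:
    """Baseline F0 = detrending residual + moving background percentile.

    ``background_in_mask`` is the global background component averaged
    over the cell's spatial mask (see
    ``BackgroundModel.trace_in_mask``).  Raises on a non-positive
    baseline, which would make ΔF/F undefined.
    """
    trend = np.asarray(trend, dtype=float)
    bg = np.asarray(background_in_mask, dtype=float)
    if bg.shape != trend.shape:
        raise ValueError("background trace must match the trend length")
    f0 = trend + moving_percentile(bg, window_frames, q, **kwargs)
    if np.any(f0 <= 0):
        raise ValueError("non-positive baseline")
    return f0


def dff_cnmf(detrended: np.ndarray, f0: np.ndarray,
             frame_rate_hz: float = 1.0) -> DffTrace:
    """Unitless ΔF/F: denoised-and-detrended trace divided by F0."""
    f0 = np.asarray(f0, dtype=float)
    if np.any(f0 <= 0):
        raise ValueError("non-positive baseline")
    return DffTrace(dff=np.asarray(detrended, dtype=float) / f0, f0=f0,
                    frame_rate_hz=frame_rate_hz, variant="cnmf")


def find_inactive_window(trace: np.ndarray, frame_rate_hz: float,
                         seconds: float = 2.0) -> slice:
    """Contiguous ~2 s window minimizing trace variance.

    A reproducible stand-in for the manual selection of an inactive
    stretch when estimating the simple-variant baseline.
    """
    x = np.asarray(trace, dtype=float)
    w = max(int(round(seconds * frame_rate_hz)), 2)
    if x.size <= w:
        return slice(0, x.size)
    c1 = np.cumsum(np.insert(x, 0, 0.0))
    c2 = np.cumsum(np.insert(x ** 2, 0, 0.0))
    s1 = c1[w:] - c1[:-w]
    s2 = c2[w:] - c2[:-w]
    var = s2 / w - (s1 / w) ** 2
    start = int(np.argmin(var))
    return slice(start, start + w)


def dff_simple(
    raw_trace: np.ndarray,
    background_trace: "np.ndarray | float",
    frame_rate_hz: float,
    *,
    inactive_seconds: float = 2.0,
) -> DffTrace:
    """Percent ΔF/F with background subtraction.

    F = raw − background (per-frame mean of a GCaMP-free region such as
    a blood vessel); F0 = mean of the lowest-variance ~2 s stretch of
    F; ΔF/F0 = (F − F0)/F0 × 100.
    """
    raw = np.asarray(raw_trace, dtype=float)
    f = raw - np.asarray(background_trace, dtype=float)
    win = find_inactive_window(f, frame_rate_hz, inactive_seconds)
    f0 = float(f[win].mean())
    if f0 <= 0:
        raise ValueError("non-positive baseline F0")
    dff = (f - f0) / f0 * 100.0
    return DffTrace(dff=dff, f0=np.full_like(f, f0),
                    frame_rate_hz=frame_rate_hz, variant="simple")


def dff_pipeline_cnmf(component, background_model,
                      frame_rate_hz: float = 1.0,
                      window_frames: int = DETREND_WINDOW_FRAMES,
                      q: float = DETREND_PERCENTILE) -> DffTrace:
    """Full CNMF-style ΔF/F for one extracted component.

    detrend(denoised + baseline offset) → F0 from trend + background →
    divide.  The component's 8th-percentile raw offset (stored at
    extraction) is added back so the trend carries the cell's resting
    fluorescence rather than sitting at zero.
    """
    if component.denoised_trace is None:
        raise ValueError("component has no denoised trace")
    offset = component.meta.get("baseline8", 0.0)
    detrended, trend = detrend_trace(component.denoised_trace + offset,
                                     window_frames, q)
    bg = background_model.trace_in_mask(component.mask)
    f0 = baseline_f0_cnmf(trend, bg, window_frames, q)
    return dff_cnmf(detrended, f0, frame_rate_hz)
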