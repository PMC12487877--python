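"""Fluorescence quantification: brightness, SNR, longevity and spatial spread.

Per-session quantification proceeds in three steps: a rolling per-pixel
background (nonoverlapping blocks, default 1500 frames) is subtracted from
the fluorescence stack; the per-frame maximum (optionally restricted to a
subject mask) forms an intensity trace; and the trace is summarized by its
mean and 95th percentile.  Longevity of a marker is the first post-injection
day on which a session summary falls below the 99th percentile of pooled
control (vehicle/blank) sessions; sessions that never cross are censored.

Spatial spread of the fluorescence is estimated from the 2-D spatial
autocorrelation of background-subtracted frames (sampled every 200th frame,
each map normalized to 1 at zero lag); the standard deviations of a bivariate
Gaussian fitted to the averaged map serve as spread estimates along x and y.
For an isotropic Gaussian spot of SD sigma the autocorrelation is a Gaussian
of SD sigma*sqrt(2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, signal

from .io_core import SessionKey

logger = logging.getLogger(__name__)


@dataclass
class IntensityTrace:
    """Per-fluorescence-frame scalar summary for one session."""

    session: SessionKey
    per_frame_values: np.ndarray
    statistic_name: str = "frame_max"

    def __post_init__(self) -> None:
        self.per_frame_values = np.asarray(self.per_frame_values, dtype=np.float64)


@dataclass
class SessionSummary:
    session: SessionKey
    mean_value: float
    p95_value: float


@dataclass
class LongevityResult:
    """First day the session summary drops below the control threshold."""

    mouse_camera_id: str
    crossing_day: float | None  # None => censored
    censored: bool
    last_day: float
    control_threshold: float


@dataclass
class AutocorrMap:
    """Averaged zero-lag-centered spatial autocorrelation surface."""

    values: np.ndarray  # (2H-1, 2W-1), value 1.0 at the center lag
    n_frames_used: int
    spread_x: float | None = None
    spread_y: float | None = None

    @property
    def center(self) -> tuple[int, int]:
        return (self.values.shape[0] // 2, self.values.shape[1] // 2)


# ---------------------------------------------------------------------------
# background subtraction and traces
# ---------------------------------------------------------------------------

_BLOCK_STATS = {"median": np.median, "mean": np.mean, "min": np.min}


def subtract_rolling_background(
    stack: np.ndarray, window: int = 1500, stat: str = "median"
) -> np.ndarray:
    """Subtract a per-pixel block background from a fluorescence stack.

    The stack is cut into nonoverlapping blocks of ``window`` frames (the
    final, possibly shorter block uses its own frames); the per-pixel
    ``stat`` over each block is subtracted from that block and negative
    values are clamped to zero.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("stack must be a non-empty (frame, row, col) array")
    if window < 1:
        raise ValueError("window must be >= 1")
    if stat not in _BLOCK_STATS:
        raise ValueError(f"stat must be one of {sorted(_BLOCK_STATS)}")
    reducer = _BLOCK_STATS[stat]
    out = np.empty_like(stack, dtype=np.float64)
    for start in range(0, stack.shape[0], window):
        block = stack[start : start + window].astype(np.float64)
        background = reducer(block, axis=0)
        out[start : start + window] = np.clip(block - background, 0.0, None)
    return out


def frame_max_trace(
    stack: np.ndarray,
    mask: np.ndarray | None = None,
    session: SessionKey | None = None,
) -> IntensityTrace:
    """Per-frame maximum pixel value, optionally restricted to a subject mask.

    ``mask`` may be a single 2-D mask applied to all frames or a per-frame
    3-D boolean stack.  A frame whose mask is empty yields NaN and a log entry.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if mask is None:
        values = stack.max(axis=(1, 2))
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim == 2:
            mask = np.broadcast_to(mask, stack.shape)
        if mask.shape != stack.shape:
            raise ValueError(f"mask shape {mask.shape} incompatible with stack {stack.shape}")
        values = np.full(stack.shape[0], np.nan)
        for i in range(stack.shape[0]):
            m = mask[i]
            if m.any():
                values[i] = stack[i][m].max()
            else:
                logger.warning("frame %d: empty mask, recording missing value", i)
    return IntensityTrace(session=session or SessionKey(), per_frame_values=values)


def summarize_session(trace: IntensityTrace) -> SessionSummary:
    """Mean and linear-interpolation 95th percentile of a per-frame trace."""
    values = trace.per_frame_values
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("cannot summarize an empty trace")
    return SessionSummary(
        session=trace.session,
        mean_value=float(values.mean()),
        p95_value=float(np.percentile(values, 95, method="linear")),
    )


# ---------------------------------------------------------------------------
# SNR metrics
# ---------------------------------------------------------------------------


def snr_mean_ratio(
    qd_summaries: Sequence[SessionSummary], control_summaries: Sequence[SessionSummary]
) -> float:
    """Mean of marker-session means divided by mean of control-session means."""
    if not qd_summaries or not control_summaries:
        raise ValueError("need at least one marker and one control session")
    qd = float(np.mean([s.mean_value for s in qd_summaries]))
    control = float(np.mean([s.mean_value for s in control_summaries]))
    if control <= 0:
        raise ValueError("control mean must be positive")
    return qd / control


def snr_spatial_sd(stack: np.ndarray) -> float:
    """Per-frame SD of all pixel values, averaged over frames."""
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("stack must be a non-empty (frame, row, col) array")
    return float(stack.std(axis=(1, 2)).mean())


# ---------------------------------------------------------------------------
# longevity
# ---------------------------------------------------------------------------


def control_threshold(control_traces: Sequence[IntensityTrace], q: float = 99.0) -> float:
    """Pooled percentile (default 99th) of control per-frame values."""
    if not control_traces:
        raise ValueError("need at least one control session")
    pooled = np.concatenate([t.per_frame_values for t in control_traces])
    pooled = pooled[np.isfinite(pooled)]
    return float(np.percentile(pooled, q, method="linear"))


def longevity(
    days: Sequence[float],
    summaries: Sequence[float],
    control_traces: Sequence[IntensityTrace] | None = None,
    threshold: float | None = None,
    mouse_camera_id: str = "",
) -> LongevityResult:
    """Find the first imaging day whose summary value drops below threshold.

    ``threshold`` may be given directly or derived as the pooled 99th
    percentile of ``control_traces``.  When the trace never crosses, the
    result is censored at the last imaged day.
    """
    days = np.asarray(days, dtype=np.float64)
    summaries = np.asarray(summaries, dtype=np.float64)
    if days.size == 0 or days.size != summaries.size:
        raise ValueError("days and summaries must be equal-length and non-empty")
    if np.any(np.diff(days) < 0):
        raise ValueError("days must be sorted ascending")
    if threshold is None:
        if not control_traces:
            raise ValueError("provide either control_traces or an explicit threshold")
        threshold = control_threshold(control_traces)
    below = np.nonzero(summaries < threshold)[0]
    if below.size:
        return LongevityResult(
            mouse_camera_id=mouse_camera_id,
            crossing_day=float(days[below[0]]),
            censored=False,
            last_day=float(days[-1]),
            control_threshold=float(threshold),
        )
    return LongevityResult(
        mouse_camera_id=mouse_camera_id,
        crossing_day=None,
        censored=True,
        last_day=float(days[-1]),
        control_threshold=float(threshold),
    )


# ---------------------------------------------------------------------------
# spatial autocorrelation and spread
# ---------------------------------------------------------------------------


def spatial_autocorrelation(stack: np.ndarray, frame_stride: int = 200) -> AutocorrMap:
    """Average full 2-D autocorrelation of every ``frame_stride``-th frame.

    Each sampled frame is correlated with itself (FFT convolution with its
    point reflection, 'full' mode), normalized so the zero-lag center equals
    1, then averaged.  All-zero frames have no defined normalization and are
    skipped with a warning.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("stack must be a non-empty (frame, row, col) array")
    if frame_stride < 1:
        raise ValueError("frame_stride must be >= 1")
    h, w = stack.shape[1:]
    acc = np.zeros((2 * h - 1, 2 * w - 1))
    n_used = 0
    for i in range(0, stack.shape[0], frame_stride):
        frame = stack[i]
        corr = signal.fftconvolve(frame, frame[::-1, ::-1], mode="full")
        center = corr[h - 1, w - 1]
        if center <= 0:
            warnings.warn(f"frame {i} is all-zero; skipped in autocorrelation", stacklevel=2)
            continue
        acc += corr / center
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable frames for autocorrelation (all sampled frames zero)")
    return AutocorrMap(values=acc / n_used, n_frames_used=n_used)


def _gaussian2d(params: np.ndarray, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    amp, cx, cy, sx, sy, off = params
    return amp * np.exp(-((xx - cx) ** 2 / (2 * sx**2) + (yy - cy) ** 2 / (2 * sy**2))) + off


def fit_bivariate_gaussian(
    surface: np.ndarray, mask: np.ndarray | None = None
) -> tuple[np.ndarray, bool, float]:
    """Least-squares axis-aligned bivariate Gaussian fit to a 2-D surface.

    Returns ``(params, converged, residual)`` with params
    ``[amplitude, cx, cy, sigma_x, sigma_y, offset]`` in pixel coordinates
    (x = column, y = row).  Initialization: amplitude from the peak, center
    at the peak location, sigmas from second moments, offset from the
    minimum.  A flat or degenerate surface is flagged unconverged.
    """
    surface = np.asarray(surface, dtype=np.float64)
    yy, xx = np.mgrid[0 : surface.shape[0], 0 : surface.shape[1]].astype(np.float64)
    if mask is None:
        sel = np.ones_like(surface, dtype=bool)
    else:
        sel = np.asarray(mask, dtype=bool)
    z = surface[sel]
    xs, ys = xx[sel], yy[sel]
    if z.size < 6 or np.ptp(z) <= 0:
        return np.full(6, np.nan), False, float("nan")
    off0 = float(z.min())
    peak = np.argmax(z)
    amp0 = float(z[peak] - off0)
    cx0, cy0 = float(xs[peak]), float(ys[peak])
    wpos = np.clip(z - off0, 0, None)
    wsum = wpos.sum()
    if wsum > 0:
        mx = float((wpos * xs).sum() / wsum)
        my = float((wpos * ys).sum() / wsum)
        sx0 = float(np.sqrt(np.clip((wpos * (xs - mx) ** 2).sum() / wsum, 0.25, None)))
        sy0 = float(np.sqrt(np.clip((wpos * (ys - my) ** 2).sum() / wsum, 0.25, None)))
    else:
        sx0 = sy0 = 1.0
    p0 = np.array([amp0, cx0, cy0, sx0, sy0, off0])

    def residuals(p: np.ndarray) -> np.ndarray:
        return _gaussian2d(p, xs, ys) - z

    span = max(surface.shape)
    lower = [0.0, xs.min() - span, ys.min() - span, 1e-3, 1e-3, -np.inf]
    upper = [np.inf, xs.max() + span, ys.max() + span, 10.0 * span, 10.0 * span, np.inf]
    try:
        res = optimize.least_squares(
            residuals, p0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14
        )
    except Exception:  # pragma: no cover - defensive
        return np.full(6, np.nan), False, float("nan")
    converged = bool(res.success) and np.all(np.isfinite(res.x))
    residual = float(np.sqrt(np.mean(res.fun**2)))
    return res.x, converged, residual


def estimate_spread(acmap: AutocorrMap) -> AutocorrMap:
    """Fit a bivariate Gaussian to an autocorrelation map; fill spread_x/y (px).

    A degenerate (flat) map leaves the spreads as None.
    """
    params, converged, _ = fit_bivariate_gaussian(acmap.values)
    if not converged:
        logger.warning("autocorrelation spread fit did not converge; flagged degenerate")
        return AutocorrMap(values=acmap.values, n_frames_used=acmap.n_frames_used)
    return AutocorrMap(
        values=acmap.values,
        n_frames_used=acmap.n_frames_used,
        spread_x=float(params[3]),
        spread_y=float(params[4]),
    )
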