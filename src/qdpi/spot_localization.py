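"""Sub-pixel localization of fluorescent markers and keypoint refinement.

A tracker's keypoint prediction is refined to the center of the nearest
fluorescent blob within a fixed search radius (default 10 px): the crop
around the prediction is thresholded (Otsu within the crop, with an absolute
floor against noise-only crops), the connected component whose centroid is
closest to the prediction is kept, and its center is estimated either by an
axis-aligned bivariate Gaussian fit (default) or by the intensity-weighted
center of mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .fluor_quant import fit_bivariate_gaussian
from .histology_quant import otsu_threshold
from .io_core import KeypointTable

logger = logging.getLogger(__name__)

GAUSSIAN_FIT = "gaussian_fit"
CENTER_OF_MASS = "center_of_mass"


@dataclass
class SpotFit:
    """Axis-aligned bivariate Gaussian parameters for one fluorescent spot."""

    cx: float
    cy: float
    sigma_x: float
    sigma_y: float
    amplitude: float
    offset: float
    converged: bool
    residual: float


@dataclass
class ComponentSelection:
    mask: np.ndarray  # boolean, same shape as the input frame/crop
    empty: bool
    centroid: tuple[float, float] | None  # (x, y)
    peak_value: float


def select_nearest_component(
    frame: np.ndarray, point: tuple[float, float], threshold: float, min_size: int = 1
) -> ComponentSelection:
    """Keep the supra-threshold 8-connected component nearest to ``point``.

    Distance is measured from ``point`` (x, y) to each component's
    intensity-weighted centroid (L2).  Ties are broken by larger integrated
    intensity, then by lower component label.  Components with fewer than
    ``min_size`` pixels are ignored (isolated noise pixels can otherwise
    out-compete a real spot on distance alone).  Pixels outside the chosen
    component are zeroed (the returned mask is False there).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    frame = np.asarray(frame, dtype=np.float64)
    binary = frame > threshold
    if not binary.any():
        return ComponentSelection(
            mask=np.zeros_like(binary), empty=True, centroid=None, peak_value=0.0
        )
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    px, py = float(point[0]), float(point[1])
    best: tuple[float, float, int] | None = None  # (distance, -integrated, label)
    for lab in range(1, n + 1):
        sel = labels == lab
        if sel.sum() < min_size:
            continue
        weights = frame[sel]
        ys, xs = np.nonzero(sel)
        wsum = weights.sum()
        cx = float((weights * xs).sum() / wsum)
        cy = float((weights * ys).sum() / wsum)
        dist = float(np.hypot(cx - px, cy - py))
        key = (dist, -float(wsum), lab)
        if best is None or key < best:
            best = key
            best_mask, best_centroid = sel, (cx, cy)
    if best is None:  # every component smaller than min_size
        return ComponentSelection(
            mask=np.zeros_like(binary), empty=True, centroid=None, peak_value=0.0
        )
    return ComponentSelection(
        mask=best_mask,
        empty=False,
        centroid=best_centroid,
        peak_value=float(frame[best_mask].max()),
    )


def fit_spot(crop: np.ndarray, mask: np.ndarray | None = None) -> SpotFit:
    """Least-squares bivariate Gaussian fit to a masked crop.

    Pixels where ``mask`` is False (or, absent a mask, zero-valued pixels)
    are excluded from the fit.  Fewer than 6 support pixels leaves the six
    parameters unidentifiable and the fit is flagged unconverged.
    """
    crop = np.asarray(crop, dtype=np.float64)
    if mask is None:
        mask = crop != 0
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 6:
        return SpotFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False, np.nan)
    params, converged, residual = fit_bivariate_gaussian(crop, mask=mask)
    amp, cx, cy, sx, sy, off = params
    if converged:
        h, w = crop.shape
        if not (-0.5 <= cx <= w - 0.5 and -0.5 <= cy <= h - 0.5):
            converged = False
    return SpotFit(
        cx=float(cx),
        cy=float(cy),
        sigma_x=float(sx),
        sigma_y=float(sy),
        amplitude=float(amp),
        offset=float(off),
        converged=bool(converged),
        residual=float(residual),
    )


def center_of_mass(crop: np.ndarray, mask: np.ndarray | None = None) -> tuple[float, float]:
    """Intensity-weighted centroid (x, y) of a masked crop."""
    crop = np.asarray(crop, dtype=np.float64)
    if mask is not None:
        crop = np.where(np.asarray(mask, dtype=bool), crop, 0.0)
    total = crop.sum()
    if total <= 0:
        raise ValueError("zero total intensity; center of mass undefined")
    ys, xs = np.mgrid[0 : crop.shape[0], 0 : crop.shape[1]]
    return float((crop * xs).sum() / total), float((crop * ys).sum() / total)


def _crop_window(
    shape: tuple[int, int], x: float, y: float, radius: int
) -> tuple[int, int, int, int]:
    """Square crop of half-width ``radius`` around (x, y), clipped at borders."""
    h, w = shape
    cx, cy = int(round(x)), int(round(y))
    x0 = max(0, cx - radius)
    x1 = min(w, cx + radius + 1)
    y0 = max(0, cy - radius)
    y1 = min(h, cy + radius + 1)
    return y0, y1, x0, x1


def localize_near(
    frame: np.ndarray,
    point: tuple[float, float],
    radius: int = 10,
    method: str = GAUSSIAN_FIT,
    threshold_floor: float = 10.0,
    min_component_size: int = 5,
) -> dict:
    """Locate the fluorescence center nearest ``point`` within ``radius`` px.

    Returns a dict with keys ``refined`` (bool), ``x``, ``y``,
    ``peak_value``, ``distance``.  The crop threshold is the Otsu threshold
    of the crop, floored at ``threshold_floor`` to suppress noise-only
    crops; components below ``min_component_size`` pixels are treated as
    noise.
    """
    frame = np.asarray(frame, dtype=np.float64)
    y0, y1, x0, x1 = _crop_window(frame.shape, point[0], point[1], radius)
    crop = frame[y0:y1, x0:x1]
    if crop.size == 0:
        return {"refined": False, "x": np.nan, "y": np.nan, "peak_value": 0.0, "distance": np.nan}
    if np.ptp(crop) > 0:
        thresh = max(float(otsu_threshold(crop)), threshold_floor)
    else:
        thresh = threshold_floor
    local_point = (point[0] - x0, point[1] - y0)
    comp = select_nearest_component(crop, local_point, thresh, min_size=min_component_size)
    if comp.empty:
        return {"refined": False, "x": np.nan, "y": np.nan, "peak_value": 0.0, "distance": np.nan}
    if method == GAUSSIAN_FIT:
        fit = fit_spot(crop, mask=comp.mask)
        if fit.converged:
            lx, ly = fit.cx, fit.cy
        else:
            lx, ly = center_of_mass(crop, mask=comp.mask)
    elif method == CENTER_OF_MASS:
        lx, ly = center_of_mass(crop, mask=comp.mask)
    else:
        raise ValueError(f"unknown method {method!r}")
    gx, gy = lx + x0, ly + y0
    dist = float(np.hypot(gx - point[0], gy - point[1]))
    if dist > radius:
        # center landed outside the search radius (e.g. a corner component);
        # leave the prediction unrefined rather than move it farther than allowed
        return {
            "refined": False,
            "x": np.nan,
            "y": np.nan,
            "peak_value": comp.peak_value,
            "distance": dist,
        }
    return {"refined": True, "x": gx, "y": gy, "peak_value": comp.peak_value, "distance": dist}


def refine_keypoints(
    table: KeypointTable,
    fluorescence: np.ndarray,
    radius: int = 10,
    method: str = GAUSSIAN_FIT,
    threshold_floor: float = 10.0,
) -> KeypointTable:
    """Refine each predicted keypoint to the nearest fluorescence center.

    ``fluorescence`` frames are indexed by the table's ``frame`` column.
    The result carries the original records plus ``refined_x, refined_y,
    distance_moved, peak_value, refined_flag`` columns; keypoints with no
    supra-threshold fluorescence in range keep their original position with
    ``refined_flag`` False.
    """
    fluorescence = np.asarray(fluorescence)
    records = table.records.copy()
    refined_x = np.full(len(records), np.nan)
    refined_y = np.full(len(records), np.nan)
    moved = np.full(len(records), np.nan)
    peaks = np.zeros(len(records))
    flags = np.zeros(len(records), dtype=bool)
    for i, row in enumerate(records.itertuples(index=False)):
        if not np.isfinite(row.x) or not np.isfinite(row.y):
            continue
        fidx = int(row.frame)
        if not 0 <= fidx < fluorescence.shape[0]:
            logger.warning("frame %d outside fluorescence stack; keypoint left unrefined", fidx)
            continue
        loc = localize_near(
            fluorescence[fidx], (row.x, row.y), radius=radius, method=method,
            threshold_floor=threshold_floor,
        )
        peaks[i] = loc["peak_value"]
        if loc["refined"]:
            refined_x[i] = loc["x"]
            refined_y[i] = loc["y"]
            moved[i] = loc["distance"]
            flags[i] = True
    records["refined_x"] = np.where(flags, refined_x, records["x"])
    records["refined_y"] = np.where(flags, refined_y, records["y"])
    records["distance_moved"] = moved
    records["peak_value"] = peaks
    records["refined_flag"] = flags
    out = KeypointTable(
        records=records[["frame", "camera", "node", "x", "y", "score"]],
        node_set=table.node_set,
    )
    out.records = records  # keep the extra evidence columns
    return out
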