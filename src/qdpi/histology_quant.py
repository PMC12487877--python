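"""Confocal-image quantification: intracellular enrichment and colocalization.

Two ratio metrics summarize where injected marker fluorescence sits in
tissue sections.  The cell-enrichment ratio compares mean marker intensity
inside segmented cell ROIs with the mean outside and reports their quotient;
values above 1 indicate uptake into cells.  The colocalization ratio
thresholds an antibody-target channel (e.g. collagen I) and a nucleus
channel (DAPI) with Otsu's method and reports the marker intensity summed
over the target mask divided by the sum over the nucleus mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class HistologyField:
    """One confocal field of view: marker (QD), target and nucleus channels."""

    qd_channel: np.ndarray
    marker_channel: np.ndarray
    nucleus_channel: np.ndarray
    roi_masks: np.ndarray | None = None  # labeled integer mask of cell regions
    field_id: str = ""

    def __post_init__(self) -> None:
        self.qd_channel = np.asarray(self.qd_channel, dtype=np.float64)
        self.marker_channel = np.asarray(self.marker_channel, dtype=np.float64)
        self.nucleus_channel = np.asarray(self.nucleus_channel, dtype=np.float64)
        shapes = {self.qd_channel.shape, self.marker_channel.shape, self.nucleus_channel.shape}
        if self.roi_masks is not None:
            self.roi_masks = np.asarray(self.roi_masks)
            shapes.add(self.roi_masks.shape)
            if self.roi_masks.min() < 0:
                raise ValueError("ROI labels must be non-negative integers")
        if len(shapes) != 1:
            raise ValueError("all channels/masks must share one shape")


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance (Otsu).

    The image is binned into ``nbins`` equal-width bins spanning its value
    range (16-bit data is thereby rescaled to 256 bins); the returned
    threshold is the center of the highest bin assigned to the lower class,
    so ``image > threshold`` selects the upper class.
    """
    image = np.asarray(image, dtype=np.float64).ravel()
    lo, hi = image.min(), image.max()
    if lo == hi:
        raise ValueError("constant image has no Otsu threshold")
    counts, edges = np.histogram(image, bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    counts = counts.astype(np.float64)
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    m0 = np.cumsum(counts * centers)
    mu0 = np.divide(m0, w0, out=np.zeros_like(m0), where=w0 > 0)
    mu1 = np.divide(m0[-1] - m0, w1, out=np.zeros_like(m0), where=w1 > 0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    # the last cut (everything in class 0) is degenerate
    idx = int(np.argmax(between[:-1]))
    return float(centers[idx])


def cell_enrichment_ratio(field: HistologyField, per_roi: bool = False) -> float:
    """Mean marker intensity inside cell ROIs over the mean outside.

    With ``per_roi=True`` the inside term is the average of per-ROI means
    instead of a pooled pixel mean.  Raises if the outside mean is not
    positive (ratio undefined).
    """
    if field.roi_masks is None:
        raise ValueError("field has no ROI masks")
    inside = field.roi_masks > 0
    if not inside.any() or inside.all():
        raise ValueError("ROI masks must be non-empty and not cover the full frame")
    qd = field.qd_channel
    if per_roi:
        labels = np.unique(field.roi_masks[inside])
        inside_mean = float(np.mean([qd[field.roi_masks == lab].mean() for lab in labels]))
    else:
        inside_mean = float(qd[inside].mean())
    outside_mean = float(qd[~inside].mean())
    if outside_mean <= 0:
        raise ValueError("mean intensity outside ROIs is <= 0; ratio undefined")
    return inside_mean / outside_mean


def colocalization_ratio(field: HistologyField, exclusive: bool = False) -> float:
    """Marker intensity in the Otsu target mask over that in the nucleus mask.

    Masks are computed independently and may overlap; ``exclusive=True``
    removes overlapping pixels from both masks before summing.  Raises when
    the nucleus-mask marker sum is zero (ratio undefined).
    """
    marker_mask = field.marker_channel > otsu_threshold(field.marker_channel)
    nucleus_mask = field.nucleus_channel > otsu_threshold(field.nucleus_channel)
    if exclusive:
        overlap = marker_mask & nucleus_mask
        marker_mask &= ~overlap
        nucleus_mask &= ~overlap
    denom = float(field.qd_channel[nucleus_mask].sum())
    if denom <= 0:
        raise ValueError("no marker intensity in the nucleus mask; ratio undefined")
    return float(field.qd_channel[marker_mask].sum()) / denom
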