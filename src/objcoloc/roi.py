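"""Region-of-interest (nucleus) detection from the DNA counterstain channel.

ROIs are nuclei segmented from the blue (DAPI) channel by Otsu's global
threshold on the exact intensity histogram, followed by 8-connected
component labelling, a minimum-area filter and optional hole filling.
Externally supplied label masks are also accepted and validated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = ["RoiMask", "detect_rois", "remove_border_rois", "accept_external_mask"]

# 8-connectivity structuring element shared across the package
EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass
class RoiMask:
    """Integer-labelled ROI map: 0 outside any ROI, k>=1 inside ROI k.

    Labels are contiguous 1..n_rois with no gaps, each an 8-connected
    region, assigned in raster-scan order of first encounter.
    """

    labels: np.ndarray
    roi_areas: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("ROI label grid must be 2-D")
        present = np.unique(self.labels)
        present = present[present > 0]
        n = len(present)
        if n and (present.min() < 1 or present.max() != n):
            raise ValueError(f"ROI labels must be contiguous 1..n, got {present}")
        if not self.roi_areas:
            counts = np.bincount(self.labels.ravel(), minlength=n + 1)
            self.roi_areas = {k: int(counts[k]) for k in range(1, n + 1)}

    @property
    def n_rois(self) -> int:
        return len(self.roi_areas)

    @property
    def roi_ids(self) -> list[int]:
        return sorted(self.roi_areas)

    def area(self, roi_id: int) -> int:
        return self.roi_areas[roi_id]

    def pixels_of(self, roi_id: int) -> np.ndarray:
        """(n, 2) array of (row, col) coordinates of one ROI."""
        return np.argwhere(self.labels == roi_id)


def _relabel_raster_order(binary_labels: np.ndarray) -> np.ndarray:
    """Compact labels to 1..n in raster-scan order of first encounter."""
    flat = binary_labels.ravel()
    order: dict[int, int] = {}
    out = np.zeros_like(binary_labels, dtype=np.int32)
    nonzero = np.flatnonzero(flat)
    for idx in nonzero:
        lbl = flat[idx]
        if lbl not in order:
            order[lbl] = len(order) + 1
    lut = np.zeros(int(flat.max()) + 1, dtype=np.int32)
    for old, new in order.items():
        lut[old] = new
    out = lut[binary_labels]
    return out


def detect_rois(
    blue: np.ndarray,
    min_roi_area_px: int = 500,
    fill_holes: bool = True,
) -> RoiMask:
    """Segment nuclei from the blue channel by Otsu thresholding.

    The Otsu threshold is computed on the exact integer histogram (one bin
    per intensity level), so the result is invariant to a constant shift
    of all intensities.  Pixels at or above the threshold are foreground;
    8-connected components smaller than ``min_roi_area_px`` are discarded;
    with ``fill_holes`` interior background holes are absorbed into their
    surrounding component.

    Raises ``ValueError`` for a constant channel, on which no threshold
    separates foreground from background.
    """
    blue = np.asarray(blue)
    if blue.size == 0:
        raise ValueError("empty blue channel")
    if not np.issubdtype(blue.dtype, np.integer):
        raise ValueError("blue channel must be integer-valued")
    lo, hi = int(blue.min()), int(blue.max())
    if lo == hi:
        raise ValueError("no ROI separable: blue channel is constant")
    counts = np.bincount((blue - lo).ravel())
    centers = np.arange(lo, hi + 1)
    thresh = threshold_otsu(hist=(counts, centers))
    # skimage's convention is foreground > t on bin centres; with integer
    # centres that equals foreground >= t+1, preserving shift invariance.
    binary = blue > thresh
    if fill_holes:
        binary = ndimage.binary_fill_holes(binary)
    labels = measure.label(binary, connectivity=2)
    if min_roi_area_px > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_roi_area_px)
        labels[np.isin(labels, small[small > 0])] = 0
    labels = _relabel_raster_order(labels)
    return RoiMask(labels=labels)


def remove_border_rois(mask: RoiMask) -> RoiMask:
    """Drop every ROI with at least one pixel on the image border.

    Remaining ROIs are relabelled 1..n preserving raster order.  Idempotent.
    """
    labels = mask.labels
    border = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    touching = np.unique(border[border > 0])
    out = labels.copy()
    out[np.isin(out, touching)] = 0
    return RoiMask(labels=_relabel_raster_order(out))


def accept_external_mask(labels: np.ndarray, shape: tuple[int, int]) -> RoiMask:
    """Validate a user-supplied label image and compact it to 1..n.

    Each supplied label that splits into several 8-connected components
    becomes several ROIs, with a warning.  Raises ``ValueError`` on a
    dimension mismatch with the target image.
    """
    labels = np.asarray(labels)
    if labels.shape != tuple(shape):
        raise ValueError(
            f"ROI mask shape {labels.shape} does not match image shape {tuple(shape)}"
        )
    if labels.ndim != 2:
        raise ValueError("ROI mask must be 2-D")
    relabelled = measure.label(labels > 0, connectivity=2)
    # a single connected blob may carry two original labels: split on value
    combined = np.zeros_like(relabelled)
    next_id = 0
    seen: dict[tuple[int, int], int] = {}
    flat_orig = labels.ravel()
    flat_conn = relabelled.ravel()
    out_flat = combined.ravel()
    for idx in np.flatnonzero(flat_conn):
        key = (int(flat_orig[idx]), int(flat_conn[idx]))
        if key not in seen:
            next_id += 1
            seen[key] = next_id
        out_flat[idx] = seen[key]
    n_orig = len(np.unique(labels[labels > 0]))
    if next_id > n_orig:
        logger.warning(
            "external mask: %d labels split into %d 8-connected ROIs",
            n_orig,
            next_id,
        )
    return RoiMask(labels=_relabel_raster_order(combined))
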