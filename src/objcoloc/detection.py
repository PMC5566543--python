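"""Per-ROI background thresholding and 8-connected object segmentation.

Each ROI gets its own background threshold computed from its own pixels,

    T = ceil(mu) + M * ceil(sigma)

with mu the mean and sigma the population standard deviation of the ROI's
intensities, and M a user multiplier (default 2).  Pixels strictly below T
are background; pixels at or above T are candidate signal.  Because T is
local, ROIs with different background luminance lose different amounts of
background.  Candidate pixels are grouped into 8-connected objects
(diagonal neighbours count as connected) within each ROI, subject to
optional size limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .roi import RoiMask

__all__ = [
    "ThresholdConfig",
    "SegmentedObject",
    "local_threshold",
    "binarize_channel",
    "segment_objects",
]


@dataclass
class ThresholdConfig:
    """Threshold multiplier and object-size limits.

    ``multiplier_M`` scales the standard-deviation term: detection becomes
    more stringent as it increases.  Objects outside
    [min_object_px, max_object_px] are discarded after segmentation.
    """

    multiplier_M: float = 2.0
    min_object_px: int = 1
    max_object_px: int | None = None

    def __post_init__(self) -> None:
        if self.multiplier_M <= 0:
            raise ValueError("multiplier_M must be positive")
        if self.min_object_px < 0:
            raise ValueError("min_object_px must be non-negative")
        if self.max_object_px is not None and self.max_object_px < self.min_object_px:
            raise ValueError("max_object_px must be >= min_object_px")


@dataclass(frozen=True)
class SegmentedObject:
    """One 8-connected foreground component in one channel within one ROI.

    ``pixels`` is a frozen set of (row, col) coordinates;
    ``intensity_sum`` is the sum of raw (pre-filter) intensities over them.
    """

    object_id: int
    channel: str
    roi_id: int
    pixels: frozenset[tuple[int, int]]
    intensity_sum: int

    @property
    def area_px(self) -> int:
        return len(self.pixels)

    def coords(self) -> np.ndarray:
        """(n, 2) coordinate array sorted in raster order."""
        return np.array(sorted(self.pixels), dtype=np.intp)

    def normalized_shape(self) -> frozenset[tuple[int, int]]:
        """Pixel set translated so its bounding box starts at (0, 0)."""
        rows = [p[0] for p in self.pixels]
        cols = [p[1] for p in self.pixels]
        r0, c0 = min(rows), min(cols)
        return frozenset((r - r0, c - c0) for r, c in self.pixels)


def local_threshold(roi_pixels, multiplier_M: float = 2.0) -> float:
    """Background threshold T = ceil(mean) + M * ceil(population sd).

    The mean and the standard deviation are each rounded up to the next
    integer before combining, so a region with mean 25 and sd 3 yields
    T = 26 + M*3 ... unless the mean is already integral: mean exactly 25
    gives ceil 25 and T = 25 + 2*3 = 31 at the default M = 2.  Intensities
    strictly below T are background.  T may be non-integral when
    M * ceil(sd) is; the same strict-inequality rule applies.
    """
    arr = np.asarray(roi_pixels, dtype=np.float64).ravel()
    if arr.size == 0:
        raise ValueError("cannot compute a threshold from an empty pixel collection")
    if multiplier_M <= 0:
        raise ValueError("multiplier_M must be positive")
    mu = float(np.mean(arr))
    sigma = float(np.std(arr))  # population (1/n) standard deviation
    return math.ceil(mu) + multiplier_M * math.ceil(sigma)


def binarize_channel(
    channel: np.ndarray,
    mask: RoiMask,
    cfg: ThresholdConfig | None = None,
) -> np.ndarray:
    """Threshold one channel ROI-locally; outside all ROIs is background.

    For each ROI independently, T is computed from that ROI's pixels of
    this channel and applied within that ROI only, so different ROIs may
    keep different amounts of background.
    """
    cfg = cfg or ThresholdConfig()
    channel = np.asarray(channel)
    if channel.shape != mask.labels.shape:
        raise ValueError("channel and ROI mask shapes differ")
    binary = np.zeros(channel.shape, dtype=bool)
    for roi_id in mask.roi_ids:
        inside = mask.labels == roi_id
        t = local_threshold(channel[inside], cfg.multiplier_M)
        binary[inside] = channel[inside] >= t
    return binary


def roi_thresholds(
    channel: np.ndarray, mask: RoiMask, cfg: ThresholdConfig | None = None
) -> dict[int, float]:
    """The per-ROI threshold values that `binarize_channel` applies."""
    cfg = cfg or ThresholdConfig()
    return {
        roi_id: local_threshold(channel[mask.labels == roi_id], cfg.multiplier_M)
        for roi_id in mask.roi_ids
    }


def _connected_parts(coords: np.ndarray) -> list[np.ndarray]:
    """Split a coordinate set into its 8-connected components."""
    r0, c0 = coords.min(axis=0)
    local = coords - (r0, c0)
    grid = np.zeros(local.max(axis=0) + 1, dtype=bool)
    grid[local[:, 0], local[:, 1]] = True
    lab = measure.label(grid, connectivity=2)
    return [
        np.argwhere(lab == k) + (r0, c0) for k in range(1, lab.max() + 1)
    ]


def segment_objects(
    binary: np.ndarray,
    mask: RoiMask,
    channel_raw: np.ndarray,
    cfg: ThresholdConfig | None = None,
    channel_name: str = "",
    start_id: int = 1,
) -> list[SegmentedObject]:
    """8-connected components of the foreground, per ROI, with size limits.

    Components are formed within each ROI (a foreground pixel outside all
    ROIs is ignored); those with area outside the configured limits are
    dropped.  ``intensity_sum`` is taken from ``channel_raw`` so it always
    reflects pre-filter intensities.  Object ids are assigned in raster
    order of each component's first pixel, ROI by ROI, starting at
    ``start_id`` and globally unique within the call.
    """
    cfg = cfg or ThresholdConfig()
    binary = np.asarray(binary, dtype=bool)
    if binary.shape != mask.labels.shape or binary.shape != channel_raw.shape:
        raise ValueError("binary grid, ROI mask and raw channel shapes differ")
    objects: list[SegmentedObject] = []
    next_id = start_id
    fg = binary & (mask.labels > 0)
    comp = measure.label(fg, connectivity=2)
    # a component could in principle straddle two touching ROIs: split by ROI
    raw = np.asarray(channel_raw)
    for region in measure.regionprops(comp):
        coords = region.coords
        roi_of = mask.labels[coords[:, 0], coords[:, 1]]
        roi_ids = np.unique(roi_of)
        for roi_id in roi_ids:
            sub = coords[roi_of == roi_id]
            # splitting by ROI can disconnect a straddling component
            for part in _connected_parts(sub) if len(roi_ids) > 1 else [sub]:
                area = len(part)
                if area < cfg.min_object_px:
                    continue
                if cfg.max_object_px is not None and area > cfg.max_object_px:
                    continue
                pixels = frozenset((int(r), int(c)) for r, c in part)
                objects.append(
                    SegmentedObject(
                        object_id=0,  # provisional; reassigned in raster order below
                        channel=channel_name,
                        roi_id=int(roi_id),
                        pixels=pixels,
                        intensity_sum=int(raw[part[:, 0], part[:, 1]].sum()),
                    )
                )
    # raster order within ROI, ROIs ascending
    objects.sort(key=lambda o: (o.roi_id, min(o.pixels)))
    out = []
    for obj in objects:
        out.append(
            SegmentedObject(
                object_id=next_id,
                channel=obj.channel,
                roi_id=obj.roi_id,
                pixels=obj.pixels,
                intensity_sum=obj.intensity_sum,
            )
        )
        next_id += 1
    return out
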