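"""Monte Carlo significance of an observed colocalisation count.

The empirical null is built by repeatedly re-placing every detected object
uniformly at random inside its own ROI (pure translation: shape and size
are preserved, orientation untouched), re-segmenting — objects of the same
channel that land on each other merge into one larger object — and
re-counting colocalised pairs with the identical criterion.  A one-sample
Student's t-test then compares the randomised counts against the observed
count as hypothesised mean.

The randomisation null is only meaningful when objects are small relative
to their ROI; a warning is emitted when any object exceeds 1/600 of its
ROI's area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .colocalisation import OverlapCriterion, count_colocalisations
from .detection import SegmentedObject, ThresholdConfig, segment_objects
from .roi import RoiMask

__all__ = [
    "SignificanceConfig",
    "SignificanceResult",
    "randomize_objects",
    "monte_carlo_significance",
]

# randomisation validity bound: ROI should dwarf the objects inside it
SPATIAL_RATIO_BOUND = 600


class PlacementError(RuntimeError):
    """An object cannot be placed anywhere inside its ROI."""


@dataclass
class SignificanceConfig:
    """Monte Carlo iteration count, seed and test sidedness."""

    n_iterations: int = 100
    seed: int | None = None
    max_placement_attempts: int = 1000
    sidedness: str = "two_sided"

    def __post_init__(self) -> None:
        if self.n_iterations < 2:
            raise ValueError("n_iterations must be >= 2 (the t-test needs variance)")
        if self.max_placement_attempts < 1:
            raise ValueError("max_placement_attempts must be positive")
        if self.sidedness not in ("two_sided", "greater"):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")


@dataclass
class SignificanceResult:
    """Observed count, the Monte Carlo null sample, t statistic and p-value."""

    observed_count: int
    random_counts: np.ndarray
    t_statistic: float
    p_value: float

    @property
    def mean_random(self) -> float:
        return float(np.mean(self.random_counts))

    @property
    def n_iterations(self) -> int:
        return len(self.random_counts)


def _valid_anchors(shape_offsets: np.ndarray, roi_grid: np.ndarray) -> np.ndarray:
    """All (row, col) anchors at which every shape pixel lies inside the ROI."""
    h, w = roi_grid.shape
    max_r = shape_offsets[:, 0].max()
    max_c = shape_offsets[:, 1].max()
    anchors = []
    for r in range(h - max_r):
        for c in range(w - max_c):
            rr = shape_offsets[:, 0] + r
            cc = shape_offsets[:, 1] + c
            if roi_grid[rr, cc].all():
                anchors.append((r, c))
    return np.array(anchors, dtype=np.intp)


def _place_object(
    obj: SegmentedObject,
    roi_grid: np.ndarray,
    roi_bbox: tuple[int, int, int, int],
    rng: np.random.Generator,
    max_attempts: int,
) -> np.ndarray:
    """Uniformly random in-ROI position for one object; returns its coords.

    Rejection-samples anchors over the ROI bounding box, falling back to
    exhaustive enumeration of valid anchors once ``max_attempts`` draws all
    fail.  Raises ``PlacementError`` if no valid anchor exists.
    """
    offsets = np.array(sorted(obj.pixels), dtype=np.intp)
    offsets = offsets - offsets.min(axis=0)
    r_min, c_min, r_max, c_max = roi_bbox
    span_r = r_max - r_min - offsets[:, 0].max()
    span_c = c_max - c_min - offsets[:, 1].max()
    if span_r >= 1 and span_c >= 1:
        for _ in range(max_attempts):
            r = r_min + int(rng.integers(span_r))
            c = c_min + int(rng.integers(span_c))
            rr = offsets[:, 0] + r
            cc = offsets[:, 1] + c
            if roi_grid[rr, cc].all():
                return np.column_stack([rr, cc])
    anchors = _valid_anchors(offsets, roi_grid)
    if len(anchors) == 0:
        raise PlacementError(
            f"object {obj.object_id} (area {obj.area_px}) fits nowhere in "
            f"ROI {obj.roi_id}"
        )
    r, c = anchors[int(rng.integers(len(anchors)))]
    return np.column_stack([offsets[:, 0] + r, offsets[:, 1] + c])


def randomize_objects(
    objects: list[SegmentedObject],
    mask: RoiMask,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> np.ndarray:
    """Translate each object to a uniformly random position inside its ROI.

    Returns the resulting binary foreground grid for the channel.  Objects
    may land on each other; overlapping placements stay merged in the grid
    (the merged region later re-segments as one larger object).
    """
    grid = np.zeros(mask.labels.shape, dtype=bool)
    bboxes: dict[int, tuple[int, int, int, int]] = {}
    roi_grids: dict[int, np.ndarray] = {}
    for obj in objects:
        roi_id = obj.roi_id
        if roi_id not in roi_grids:
            roi_grids[roi_id] = mask.labels == roi_id
            coords = np.argwhere(roi_grids[roi_id])
            r0, c0 = coords.min(axis=0)
            r1, c1 = coords.max(axis=0)
            bboxes[roi_id] = (int(r0), int(c0), int(r1) + 1, int(c1) + 1)
        r_min, c_min, r_max, c_max = bboxes[roi_id]
        placed = _place_object(
            obj,
            roi_grids[roi_id],
            (r_min, c_min, r_max, c_max),
            rng,
            max_attempts,
        )
        grid[placed[:, 0], placed[:, 1]] = True
    return grid


def check_spatial_ratio(objects: list[SegmentedObject], mask: RoiMask) -> bool:
    """Warn when an object is too large for its ROI for a valid null.

    Returns True when all objects respect the ROI > 600 x object bound.
    """
    ok = True
    for obj in objects:
        if obj.area_px * SPATIAL_RATIO_BOUND > mask.area(obj.roi_id):
            warnings.warn(
                f"object {obj.object_id} (area {obj.area_px} px) exceeds "
                f"1/{SPATIAL_RATIO_BOUND} of ROI {obj.roi_id} "
                f"(area {mask.area(obj.roi_id)} px); the randomisation "
                "p-value may not be a valid significance indicator",
                stacklevel=2,
            )
            ok = False
    return ok


def monte_carlo_significance(
    red_objects: list[SegmentedObject],
    green_objects: list[SegmentedObject],
    mask: RoiMask,
    criterion: OverlapCriterion | None = None,
    cfg: SignificanceConfig | None = None,
    threshold_cfg: ThresholdConfig | None = None,
    observed_count: int | None = None,
) -> SignificanceResult:
    """Monte Carlo randomisation test of the observed colocalisation count.

    Each iteration randomises both channels, re-segments the randomised
    grids (8-connected, same size filters) and pair-counts with the same
    criterion.  The one-sample t-test compares the null counts against the
    observed count: t = (mean_random - observed) / (sd / sqrt(n)), with
    n - 1 degrees of freedom.  Bit-reproducible for a fixed seed:
    per-iteration child generators are spawned deterministically from the
    master seed, so iterations are order-independent.

    When the null counts have zero variance the t-test is degenerate:
    p = 1.0 if their mean equals the observed count, else 0.0, with a
    warning.
    """
    criterion = criterion or OverlapCriterion()
    cfg = cfg or SignificanceConfig()
    threshold_cfg = threshold_cfg or ThresholdConfig()
    check_spatial_ratio(list(red_objects) + list(green_objects), mask)
    if observed_count is None:
        observed_count = count_colocalisations(
            red_objects, green_objects, criterion, roi_ids=mask.roi_ids
        ).n_coloc

    child_seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_iterations)
    dummy_raw = np.zeros(mask.labels.shape, dtype=np.uint16)
    counts = np.empty(cfg.n_iterations, dtype=np.int64)
    for i, ss in enumerate(child_seeds):
        rng = np.random.default_rng(ss)
        red_grid = randomize_objects(
            red_objects, mask, rng, cfg.max_placement_attempts
        )
        green_grid = randomize_objects(
            green_objects, mask, rng, cfg.max_placement_attempts
        )
        reds = segment_objects(
            red_grid, mask, dummy_raw, threshold_cfg, channel_name="red"
        )
        greens = segment_objects(
            green_grid, mask, dummy_raw, threshold_cfg, channel_name="green"
        )
        counts[i] = count_colocalisations(
            reds, greens, criterion, roi_ids=mask.roi_ids
        ).n_coloc

    mean_random = float(np.mean(counts))
    if np.all(counts == counts[0]):
        warnings.warn(
            "Monte Carlo null counts have zero variance; t-test degenerate",
            stacklevel=2,
        )
        t_stat = (
            0.0
            if mean_random == observed_count
            else float(np.sign(mean_random - observed_count) * np.inf)
        )
        p = 1.0 if mean_random == observed_count else 0.0
    else:
        alternative = "two-sided" if cfg.sidedness == "two_sided" else "less"
        res = stats.ttest_1samp(counts, popmean=observed_count, alternative=alternative)
        t_stat = float(res.statistic)
        p = float(res.pvalue)
    return SignificanceResult(
        observed_count=int(observed_count),
        random_counts=counts,
        t_statistic=t_stat,
        p_value=p,
    )
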