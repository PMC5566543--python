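"""Counting colocalised object pairs between the red and green channels.

Two objects colocalise when their pixel sets overlap by at least a minimum
number of pixels, or by a minimum percentage of the smaller object's area.
Every qualifying (red, green) pair within a ROI counts: one green object
overlapped by two red objects contributes two colocalisations.

The default minimum of 3 overlapping pixels follows from the optics: the
lateral resolution limit d = 0.61*lambda/NA (Rayleigh criterion) converted
to pixels.  Two spots closer than d are not optically resolvable, so an
overlap smaller than d in pixels carries no evidence of true coincidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .detection import SegmentedObject

__all__ = [
    "OverlapCriterion",
    "ChannelSummary",
    "ColocalisationReport",
    "count_colocalisations",
    "min_overlap_from_resolution",
    "rayleigh_d",
    "summarize_channel",
]


@dataclass(frozen=True)
class OverlapCriterion:
    """Minimum spatial overlap for a (red, green) pair to colocalise.

    ``mode`` selects between an absolute pixel count (``min_pixels``) and a
    percentage of the smaller object's area (``percentage``).  The
    smaller-object denominator keeps the criterion symmetric between
    channels.
    """

    mode: str = "min_pixels"
    min_pixels: int = 3
    percentage: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("min_pixels", "percentage"):
            raise ValueError(f"unknown overlap mode {self.mode!r}")
        if self.mode == "min_pixels":
            if self.min_pixels < 1:
                raise ValueError("min_pixels must be a positive integer")
        else:
            if self.percentage is None or not (0 < self.percentage <= 100):
                raise ValueError("percentage must lie in (0, 100]")

    def required_overlap(self, area_a: int, area_b: int) -> float:
        """Overlap (pixels) required for two objects of the given areas."""
        if self.mode == "min_pixels":
            return self.min_pixels
        return self.percentage / 100.0 * min(area_a, area_b)


@dataclass(frozen=True)
class ChannelSummary:
    """Aggregate statistics over one channel's segmented objects."""

    n_objects: int
    total_pixels: int
    localized_intensity_sum: int


@dataclass
class ColocalisationReport:
    """Per-ROI and whole-image colocalisation counts.

    ``per_roi`` maps roi_id -> (n_red, n_green, n_coloc);
    ``coloc_pairs`` lists every qualifying (red_object_id, green_object_id,
    overlap_px).  ``n_red_colocalised``/``n_green_colocalised`` count the
    distinct objects per channel involved in at least one pair — an
    extension beyond the pair count for users wanting per-channel object
    counts.
    """

    per_roi: dict[int, tuple[int, int, int]]
    coloc_pairs: list[tuple[int, int, int]]
    red_summary: ChannelSummary
    green_summary: ChannelSummary

    @property
    def image_totals(self) -> tuple[int, int, int]:
        n_red = sum(v[0] for v in self.per_roi.values())
        n_green = sum(v[1] for v in self.per_roi.values())
        n_coloc = sum(v[2] for v in self.per_roi.values())
        return (n_red, n_green, n_coloc)

    @property
    def n_coloc(self) -> int:
        return self.image_totals[2]

    @property
    def n_red_colocalised(self) -> int:
        return len({r for r, _, _ in self.coloc_pairs})

    @property
    def n_green_colocalised(self) -> int:
        return len({g for _, g, _ in self.coloc_pairs})


def count_colocalisations(
    red_objects: list[SegmentedObject],
    green_objects: list[SegmentedObject],
    criterion: OverlapCriterion | None = None,
    roi_ids: list[int] | None = None,
) -> ColocalisationReport:
    """Count qualifying (red, green) object pairs within each ROI.

    Every pair of objects sharing a ROI is tested; a pair qualifies when
    its pixel intersection meets the criterion.  ``roi_ids`` optionally
    fixes the set of ROIs to report (zero rows included); objects
    referencing a ROI outside it raise a consistency error.
    """
    criterion = criterion or OverlapCriterion()
    if roi_ids is None:
        roi_ids = sorted(
            {o.roi_id for o in red_objects} | {o.roi_id for o in green_objects}
        )
    known = set(roi_ids)
    for obj in list(red_objects) + list(green_objects):
        if obj.roi_id not in known:
            raise ValueError(
                f"object {obj.object_id} references unknown ROI {obj.roi_id}"
            )
    reds_by_roi: dict[int, list[SegmentedObject]] = {k: [] for k in roi_ids}
    greens_by_roi: dict[int, list[SegmentedObject]] = {k: [] for k in roi_ids}
    for o in red_objects:
        reds_by_roi[o.roi_id].append(o)
    for o in green_objects:
        greens_by_roi[o.roi_id].append(o)

    per_roi: dict[int, tuple[int, int, int]] = {}
    pairs: list[tuple[int, int, int]] = []
    for roi_id in roi_ids:
        reds = reds_by_roi[roi_id]
        greens = greens_by_roi[roi_id]
        n_coloc = 0
        for r in reds:
            for g in greens:
                overlap = len(r.pixels & g.pixels)
                if overlap >= criterion.required_overlap(r.area_px, g.area_px):
                    n_coloc += 1
                    pairs.append((r.object_id, g.object_id, overlap))
        per_roi[roi_id] = (len(reds), len(greens), n_coloc)

    return ColocalisationReport(
        per_roi=per_roi,
        coloc_pairs=pairs,
        red_summary=summarize_channel(red_objects),
        green_summary=summarize_channel(green_objects),
    )


def rayleigh_d(lambda_um: float, numerical_aperture: float) -> float:
    """Lateral resolution limit d = 0.61 * lambda / NA, in micrometres."""
    if lambda_um <= 0 or numerical_aperture <= 0:
        raise ValueError("wavelength and numerical aperture must be positive")
    return 0.61 * lambda_um / numerical_aperture


def min_overlap_from_resolution(d_um: float, pixel_size_um: float) -> int:
    """Minimum pixel overlap implied by the optical resolution limit.

    Rounds the resolution limit, expressed in pixels, up to a whole pixel:
    e.g. d = 0.29 um at 0.144 um/pixel gives ceil(2.01) ... = 3 pixels.
    """
    if d_um <= 0 or pixel_size_um <= 0:
        raise ValueError("d_um and pixel_size_um must be positive")
    return math.ceil(d_um / pixel_size_um)


def summarize_channel(objects: list[SegmentedObject]) -> ChannelSummary:
    """Object count, total pixel count and localised intensity sum."""
    return ChannelSummary(
        n_objects=len(objects),
        total_pixels=sum(o.area_px for o in objects),
        localized_intensity_sum=sum(o.intensity_sum for o in objects),
    )
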