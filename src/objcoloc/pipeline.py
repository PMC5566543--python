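"""End-to-end single-image analysis: filters -> ROIs -> objects -> counts.

Shared by the batch CLI and the test suite.  The steps mirror how the
tool is used interactively: optional denoising of the signal channels,
nucleus detection from blue, per-ROI thresholding and segmentation of red
and green, pair counting, and (optionally) the Monte Carlo significance
test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colocalisation import ColocalisationReport, OverlapCriterion, count_colocalisations
from .detection import (
    SegmentedObject,
    ThresholdConfig,
    binarize_channel,
    segment_objects,
)
from .image_io import MultiChannelImage
from .preprocessing import FilterConfig, apply_filters
from .roi import RoiMask, detect_rois, remove_border_rois
from .significance import SignificanceConfig, SignificanceResult, monte_carlo_significance

__all__ = ["AnalysisResult", "analyze_image"]


@dataclass
class AnalysisResult:
    """Everything one image's analysis produced."""

    mask: RoiMask
    red_objects: list[SegmentedObject]
    green_objects: list[SegmentedObject]
    report: ColocalisationReport
    significance: SignificanceResult | None = None
    red_binary: np.ndarray | None = None
    green_binary: np.ndarray | None = None


def analyze_image(
    image: MultiChannelImage,
    filter_cfg: FilterConfig | None = None,
    threshold_cfg: ThresholdConfig | None = None,
    criterion: OverlapCriterion | None = None,
    significance_cfg: SignificanceConfig | None = None,
    mask: RoiMask | None = None,
    min_roi_area_px: int = 500,
    fill_holes: bool = True,
    remove_border: bool = False,
    run_significance: bool = False,
    keep_binaries: bool = False,
) -> AnalysisResult:
    """Run the full object-based colocalisation analysis on one image.

    ``mask`` bypasses nucleus auto-detection with an externally supplied
    ROI mask.  Thresholds are computed on the filtered intensities (that
    is the point of denoising) while object intensity sums always use the
    raw channel values.
    """
    filter_cfg = filter_cfg or FilterConfig()
    threshold_cfg = threshold_cfg or ThresholdConfig()
    criterion = criterion or OverlapCriterion()
    if mask is None:
        mask = detect_rois(image.blue, min_roi_area_px, fill_holes)
        if remove_border:
            mask = remove_border_rois(mask)

    red_f = apply_filters(image.red, filter_cfg)
    green_f = apply_filters(image.green, filter_cfg)
    red_bin = binarize_channel(red_f, mask, threshold_cfg)
    green_bin = binarize_channel(green_f, mask, threshold_cfg)
    red_objects = segment_objects(
        red_bin, mask, image.red, threshold_cfg, channel_name="red"
    )
    green_objects = segment_objects(
        green_bin, mask, image.green, threshold_cfg, channel_name="green",
        start_id=len(red_objects) + 1,
    )
    report = count_colocalisations(
        red_objects, green_objects, criterion, roi_ids=mask.roi_ids
    )
    significance = None
    if run_significance:
        significance = monte_carlo_significance(
            red_objects,
            green_objects,
            mask,
            criterion,
            significance_cfg or SignificanceConfig(),
            threshold_cfg,
            observed_count=report.n_coloc,
        )
    return AnalysisResult(
        mask=mask,
        red_objects=red_objects,
        green_objects=green_objects,
        report=report,
        significance=significance,
        red_binary=red_bin if keep_binaries else None,
        green_binary=green_bin if keep_binaries else None,
    )
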