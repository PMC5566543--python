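"""Optional denoising of signal channels: median and adaptive Wiener filters.

The median filter removes impulse ("salt and pepper") noise by replacing
each pixel with the middle value of its window.  The adaptive Wiener filter
smooths more where the local variance is low and less where it is high:
with local window mean mu and variance s2, and an image-wide noise variance
v2 (the average of all local variances),

    b = mu + ((s2 - v2) / s2) * (a - mu)

Both filters use zero padding at the borders; window sizes must be odd.
When both are enabled the median filter runs first, so impulse noise does
not inflate the Wiener variance estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["FilterConfig", "median_filter", "wiener_filter", "apply_filters"]


class FilterConfigError(ValueError):
    """Invalid filter window configuration."""


def _check_window(window: tuple[int, int]) -> tuple[int, int]:
    rows, cols = int(window[0]), int(window[1])
    if rows < 1 or cols < 1 or rows % 2 == 0 or cols % 2 == 0:
        raise FilterConfigError(
            f"filter window must have odd positive dimensions, got {window}"
        )
    return rows, cols


@dataclass
class FilterConfig:
    """Which denoising filters to run and their window sizes."""

    use_median: bool = True
    median_window: tuple[int, int] = (3, 3)
    use_wiener: bool = True
    wiener_window: tuple[int, int] = (5, 5)

    def __post_init__(self) -> None:
        _check_window(self.median_window)
        _check_window(self.wiener_window)


def median_filter(channel: np.ndarray, window: tuple[int, int] = (3, 3)) -> np.ndarray:
    """Window median of each pixel, with zero padding at the borders."""
    rows, cols = _check_window(window)
    return ndimage.median_filter(channel, size=(rows, cols), mode="constant", cval=0)


def wiener_filter(
    channel: np.ndarray,
    window: tuple[int, int] = (5, 5),
    noise_variance: float | None = None,
) -> np.ndarray:
    """Adaptive Wiener filter with an image-wide noise-variance estimate.

    Per pixel, the local mean and population variance are taken over the
    zero-padded window; the noise variance v2 defaults to the mean of all
    local variances.  Where the local variance falls below v2 the gain is
    clamped to zero (output = local mean); where it is exactly zero the
    output is likewise the local mean.  The result is real-valued, clipped
    to the representable range of the input dtype.

    ``noise_variance`` overrides the v2 estimate (0 makes the filter the
    identity), mainly for testing.
    """
    rows, cols = _check_window(window)
    a = np.asarray(channel, dtype=np.float64)
    size = (rows, cols)
    local_mean = ndimage.uniform_filter(a, size=size, mode="constant", cval=0.0)
    local_sqmean = ndimage.uniform_filter(a * a, size=size, mode="constant", cval=0.0)
    local_var = np.maximum(local_sqmean - local_mean**2, 0.0)
    v2 = float(np.mean(local_var)) if noise_variance is None else float(noise_variance)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(local_var > 0, (local_var - v2) / local_var, 0.0)
    gain = np.clip(gain, 0.0, None)
    out = local_mean + gain * (a - local_mean)
    upper = _dtype_max(channel)
    return np.clip(out, 0.0, upper)


def _dtype_max(channel: np.ndarray) -> float:
    if np.issubdtype(channel.dtype, np.integer):
        return float(np.iinfo(channel.dtype).max)
    return float(np.max(channel)) if channel.size else 0.0


def round_half_up(filtered: np.ndarray, dtype=np.uint16) -> np.ndarray:
    """Round a real-valued filtered channel half-up to integers for export."""
    return np.floor(np.asarray(filtered, dtype=np.float64) + 0.5).astype(dtype)


def apply_filters(channel: np.ndarray, cfg: FilterConfig) -> np.ndarray:
    """Run the configured filters (median first, then Wiener) on one channel.

    Returns a float array when the Wiener filter is enabled, otherwise an
    integer array of the input dtype.
    """
    out = channel
    if cfg.use_median:
        out = median_filter(out, cfg.median_window)
    if cfg.use_wiener:
        out = wiener_filter(out, cfg.wiener_window)
    return out
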