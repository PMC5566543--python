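"""Reading and writing multichannel fluorescence TIFF images.

Input images are RGB lossless TIFFs in which blue carries the nuclear
counterstain (DAPI) and red/green carry the two labelled targets.  The
sample order in the file is assumed to be R, G, B; no colour-space
inference is attempted.  Only 8- and 16-bit unsigned integer data are
accepted, matching CCD camera exports.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "MultiChannelImage",
    "read_rgb_tiff",
    "save_channels",
    "discover_batch",
]


class FormatError(ValueError):
    """The file exists but is not an acceptable RGB integer TIFF."""


@dataclass
class MultiChannelImage:
    """Aligned red/green/blue intensity grids with optional pixel size.

    All three channels are 2-D unsigned-integer arrays of identical shape.
    ``pixel_size_um`` is micrometres per pixel when known (used to convert
    an optical resolution limit into a minimum pixel overlap).
    """

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    pixel_size_um: float | None = None
    source_path: str = ""

    def __post_init__(self) -> None:
        for name in ("red", "green", "blue"):
            ch = getattr(self, name)
            if ch.ndim != 2:
                raise ValueError(f"{name} channel must be 2-D, got {ch.ndim}-D")
            if not np.issubdtype(ch.dtype, np.integer):
                raise ValueError(f"{name} channel must be integer-valued")
        if not (self.red.shape == self.green.shape == self.blue.shape):
            raise ValueError(
                "channel shapes differ: "
                f"{self.red.shape}, {self.green.shape}, {self.blue.shape}"
            )
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def height_px(self) -> int:
        return self.red.shape[0]

    @property
    def width_px(self) -> int:
        return self.red.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    def channel(self, name: str) -> np.ndarray:
        """Return a channel by name ('red', 'green' or 'blue')."""
        try:
            return {"red": self.red, "green": self.green, "blue": self.blue}[name]
        except KeyError:
            raise KeyError(f"unknown channel {name!r}") from None


def read_rgb_tiff(path: str | Path) -> MultiChannelImage:
    """Read an RGB TIFF and split it into red, green and blue channels.

    Only the first page of a multi-page file is read (widefield images are
    single-plane); a warning is logged in that case.  An alpha channel, if
    present, is ignored.  Floating-point and sub-3-channel files are
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            if len(tif.pages) > 1:
                logger.warning(
                    "%s has %d pages; only the first is read", path, len(tif.pages)
                )
            page = tif.pages[0]
            data = page.asarray()
            pixel_size = _pixel_size_from_tags(page)
    except tifffile.TiffFileError as exc:
        raise FormatError(f"{path} is not a readable TIFF: {exc}") from exc

    if data.ndim == 2:
        raise FormatError(f"{path} has 1 channel; an RGB image (>=3) is required")
    if data.ndim != 3:
        raise FormatError(f"{path} has unexpected dimensionality {data.shape}")
    # tifffile may deliver planar (C,H,W) or interleaved (H,W,C) data
    if data.shape[0] in (1, 2, 3, 4) and data.shape[0] < data.shape[-1]:
        data = np.moveaxis(data, 0, -1)
    n_channels = data.shape[-1]
    if n_channels < 3:
        raise FormatError(
            f"{path} has {n_channels} channels; an RGB image (>=3) is required"
        )
    if not np.issubdtype(data.dtype, np.unsignedinteger):
        raise FormatError(
            f"{path} has dtype {data.dtype}; only 8/16-bit unsigned integer "
            "TIFFs are supported"
        )
    red, green, blue = (np.ascontiguousarray(data[..., i]) for i in range(3))
    return MultiChannelImage(
        red=red,
        green=green,
        blue=blue,
        pixel_size_um=pixel_size,
        source_path=str(path),
    )


def _pixel_size_from_tags(page) -> float | None:
    """Derive micrometres per pixel from TIFF resolution tags, if present."""
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags["ResolutionUnit"].value
    except KeyError:
        return None
    num, den = (xres if isinstance(xres, tuple) else (xres, 1))
    if not num:
        return None
    pixels_per_unit = num / den
    unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit))  # inch, centimetre
    if unit_um is None or pixels_per_unit <= 0:
        return None
    return unit_um / pixels_per_unit


def save_channels(image: MultiChannelImage, out_dir: str | Path) -> list[Path]:
    """Write each channel as a separate single-channel lossless TIFF.

    Filenames append the channel name to the source stem
    (``img.tif`` -> ``img_red.tif`` ...), so the original file is never
    overwritten.  Re-reading each output reproduces the channel bit-exactly.
    """
    out_dir = Path(out_dir)
    if not out_dir.is_dir():
        raise IOError(f"output directory does not exist: {out_dir}")
    stem = Path(image.source_path).stem if image.source_path else "image"
    written: list[Path] = []
    resolution = None
    if image.pixel_size_um:
        ppcm = 10000.0 / image.pixel_size_um
        resolution = (ppcm, ppcm)
    for name in ("red", "green", "blue"):
        out_path = out_dir / f"{stem}_{name}.tif"
        kwargs = {}
        if resolution is not None:
            kwargs = {"resolution": resolution, "resolutionunit": "CENTIMETER"}
        tifffile.imwrite(out_path, image.channel(name), compression=None, **kwargs)
        written.append(out_path)
    return written


def discover_batch(root: str | Path, pattern: str = "*.tif") -> list[Path]:
    """List files under ``root`` matching a glob pattern, lexicographically.

    Recursive patterns (``**/*.tif``) are supported.  An empty result is
    valid and returned as an empty list.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"batch root does not exist: {root}")
    return sorted(p for p in root.glob(pattern) if p.is_file())


def assemble_rgb(image: MultiChannelImage) -> np.ndarray:
    """Stack the three channels into an (H, W, 3) array in R,G,B order."""
    return np.stack([image.red, image.green, image.blue], axis=-1)
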