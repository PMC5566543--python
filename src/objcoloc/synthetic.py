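"""Synthetic fluorescence scenes with known ground truth.

Generates RGB images that emulate widefield immunofluorescence data:
elliptical nuclei on the blue channel, compact bright objects (by default
10-15 px, the typical size of nuclear foci such as PML bodies) on red and
green, per-nucleus background offsets that differ between nuclei and
channels, additive Gaussian noise and optional impulse noise.  A
controllable fraction of green objects is planted to overlap a red object
by an exact, known number of pixels, so overlap-criterion boundary cases
are directly testable and every downstream count has a ground truth.

Planted objects are kept at least 2 px (Chebyshev) apart from all other
objects except their designated partner, so no accidental same-channel
merges or cross-channel overlaps occur and noise-free pipeline output can
be compared against the ground truth exactly.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage import draw, measure

from .image_io import MultiChannelImage
from .roi import RoiMask, _relabel_raster_order

__all__ = ["SceneSpec", "GroundTruth", "generate_scene", "write_fixture_set"]

_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


class GenerationError(RuntimeError):
    """Object or nucleus placement failed within the attempt budget."""


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    ``signal_intensity`` is the brightness of object pixels above the
    local (per-nucleus) background; ``background_mean_range`` is the range
    the per-nucleus, per-channel background offsets are drawn from,
    emulating background that varies among cells and channels.
    """

    image_size: tuple[int, int] = (256, 256)
    n_nuclei: int = 5
    nucleus_axes_px: tuple[int, int] = (18, 26)
    objects_per_channel_per_nucleus: tuple[int, int] = (2, 4)
    object_size_px: tuple[int, int] = (10, 15)
    planted_coloc_fraction: float = 0.5
    planted_overlap_px: int = 4
    background_mean_range: tuple[float, float] = (10.0, 40.0)
    noise_sd: float = 0.0
    signal_intensity: float = 160.0
    impulse_noise_fraction: float = 0.0
    blue_background: float = 10.0
    blue_signal: float = 200.0
    bit_depth: int = 8
    seed: int = 0
    max_attempts: int = 500

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if not (0 <= self.planted_coloc_fraction <= 1):
            raise ValueError("planted_coloc_fraction must lie in [0, 1]")
        if self.planted_overlap_px < 1:
            raise ValueError("planted_overlap_px must be >= 1")
        if self.object_size_px[0] > self.object_size_px[1]:
            raise ValueError("object_size_px range reversed")
        if self.planted_overlap_px >= self.object_size_px[0]:
            raise ValueError("planted_overlap_px must be below the object size")

    @property
    def dtype(self):
        return np.uint8 if self.bit_depth == 8 else np.uint16

    @property
    def intensity_max(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass
class GroundTruth:
    """Everything the generator knows about a scene.

    ``red_objects``/``green_objects`` map nucleus id -> list of planted
    pixel sets; ``planted_pairs`` lists (nucleus_id, red_index,
    green_index, overlap_px) for the deliberately colocalised pairs.
    """

    mask: RoiMask
    red_objects: dict[int, list[frozenset]] = field(default_factory=dict)
    green_objects: dict[int, list[frozenset]] = field(default_factory=dict)
    planted_pairs: list[tuple[int, int, int, int]] = field(default_factory=list)

    def counts_per_nucleus(self, min_pixels: int = 1) -> dict[int, tuple[int, int, int]]:
        """(n_red, n_green, n_coloc) per nucleus, under an overlap minimum."""
        out = {}
        for roi_id in self.mask.roi_ids:
            n_coloc = sum(
                1
                for (nid, _, _, ov) in self.planted_pairs
                if nid == roi_id and ov >= min_pixels
            )
            out[roi_id] = (
                len(self.red_objects.get(roi_id, [])),
                len(self.green_objects.get(roi_id, [])),
                n_coloc,
            )
        return out

    def totals(self, min_pixels: int = 1) -> tuple[int, int, int]:
        per = self.counts_per_nucleus(min_pixels)
        return tuple(int(sum(v[i] for v in per.values())) for i in range(3))


def _compact_blob(size: int, rng: np.random.Generator) -> np.ndarray:
    """A compact, 8-connected pixel blob of exactly ``size`` pixels.

    Pixels of a disc neighbourhood are ranked by squared distance from the
    centre with sub-unit random jitter (shuffles ties without reordering
    distance rings, which keeps every prefix 8-connected).
    """
    radius = int(np.ceil(np.sqrt(size / np.pi))) + 2
    ys, xs = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    key = ys**2 + xs**2 + rng.uniform(0, 0.9, ys.shape)
    order = np.argsort(key.ravel())[:size]
    pts = np.column_stack([ys.ravel()[order], xs.ravel()[order]])
    return pts - pts.min(axis=0)


def _is_8_connected(pixels: set[tuple[int, int]]) -> bool:
    if not pixels:
        return False
    start = next(iter(pixels))
    seen = {start}
    stack = [start]
    while stack:
        r, c = stack.pop()
        for dr, dc in _NEIGHBOURS:
            q = (r + dr, c + dc)
            if q in pixels and q not in seen:
                seen.add(q)
                stack.append(q)
    return len(seen) == len(pixels)


def _halo(pixels, shape, radius: int = 2) -> set[tuple[int, int]]:
    """Pixels within Chebyshev ``radius`` of the set (clipped to bounds)."""
    out = set()
    h, w = shape
    for r, c in pixels:
        for dr in range(-radius, radius + 1):
            for dc in range(-radius, radius + 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    out.add((rr, cc))
    return out


def _place_nuclei(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.image_size
    labels = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)
    lo, hi = spec.nucleus_axes_px
    for k in range(1, spec.n_nuclei + 1):
        for _ in range(spec.max_attempts):
            a = rng.integers(lo, hi + 1)
            b = rng.integers(lo, hi + 1)
            margin = int(max(a, b)) + 2
            if 2 * margin >= min(h, w):
                continue
            cy = int(rng.integers(margin, h - margin))
            cx = int(rng.integers(margin, w - margin))
            rr, cc = draw.ellipse(cy, cx, a, b, shape=(h, w))
            # 2-px clearance keeps nuclei from merging into one ROI
            grown = draw.ellipse(cy, cx, a + 2, b + 2, shape=(h, w))
            if occupied[grown].any():
                continue
            labels[rr, cc] = k
            occupied[grown] = True
            break
        else:
            raise GenerationError(
                f"could not place nucleus {k} of {spec.n_nuclei} in "
                f"{spec.image_size} after {spec.max_attempts} attempts"
            )
    # raster-scan label order, matching what detect_rois assigns
    return _relabel_raster_order(labels)


def _grow_green_partner(
    red_pixels: frozenset,
    overlap_px: int,
    target_size: int,
    allowed: set[tuple[int, int]],
    forbidden: set[tuple[int, int]],
    all_red: set[tuple[int, int]],
    rng: np.random.Generator,
) -> frozenset | None:
    """Green blob overlapping ``red_pixels`` by exactly ``overlap_px``.

    Seeds the overlap with the ``overlap_px`` red pixels nearest an extreme
    point of the red blob, then grows outward into pixels that belong to no
    red object, so the intersection with every red object is exact by
    construction.  Returns None if growth stalls.
    """
    direction = rng.normal(size=2)
    direction /= np.linalg.norm(direction)
    red_arr = np.array(sorted(red_pixels), dtype=float)
    proj = red_arr @ direction
    anchor = red_arr[int(np.argmax(proj))]
    d2 = ((red_arr - anchor) ** 2).sum(axis=1) + rng.uniform(0, 0.9, len(red_arr))
    order = np.argsort(d2)[:overlap_px]
    seed_px = {tuple(int(v) for v in red_arr[i]) for i in order}
    if not _is_8_connected(seed_px):
        return None
    green = set(seed_px)
    heap: list[tuple[float, tuple[int, int]]] = []
    visited = set(green)

    def push_neighbours(p):
        for dr, dc in _NEIGHBOURS:
            q = (p[0] + dr, p[1] + dc)
            if q in visited:
                continue
            visited.add(q)
            if q in all_red or q in forbidden or q not in allowed:
                continue
            cost = (q[0] - anchor[0]) ** 2 + (q[1] - anchor[1]) ** 2
            heapq.heappush(heap, (cost + rng.uniform(0, 0.9), q))

    for p in green:
        push_neighbours(p)
    while len(green) < target_size:
        if not heap:
            return None
        _, q = heapq.heappop(heap)
        green.add(q)
        push_neighbours(q)
    return frozenset(green)


def generate_scene(spec: SceneSpec) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one synthetic scene and its exhaustive ground truth.

    Fully reproducible from ``spec.seed``.  Raises ``GenerationError``
    when nuclei or objects cannot be placed within the attempt budget.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    labels = _place_nuclei(spec, rng)
    mask = RoiMask(labels=labels)
    truth = GroundTruth(mask=mask)

    # objects must sit strictly inside the nucleus so the detected ROI
    # (the ellipse itself) always contains them
    interior = ndimage.binary_erosion(labels > 0, np.ones((3, 3)))
    obj_lo, obj_hi = spec.objects_per_channel_per_nucleus
    size_lo, size_hi = spec.object_size_px

    all_red_px: set[tuple[int, int]] = set()
    # per-object exclusion halos, so a planted partner's halo can be lifted
    halos: list[tuple[frozenset, set[tuple[int, int]]]] = []

    def forbidden_except(skip: frozenset | None = None) -> set[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for pix, halo in halos:
            if skip is not None and pix is skip:
                continue
            out |= halo
        return out

    def place_blob(roi_id: int, size: int) -> frozenset | None:
        region = np.argwhere((labels == roi_id) & interior)
        forbidden = forbidden_except()
        for _ in range(spec.max_attempts):
            shape = _compact_blob(size, rng)
            anchor = region[int(rng.integers(len(region)))]
            pts = shape + anchor
            pix = {(int(r), int(c)) for r, c in pts}
            if len(pix) != size:
                continue
            if any(
                not (0 <= r < h and 0 <= c < w)
                or not interior[r, c]
                or labels[r, c] != roi_id
                for r, c in pix
            ):
                continue
            if pix & forbidden:
                continue
            return frozenset(pix)
        return None

    for roi_id in mask.roi_ids:
        n_red = int(rng.integers(obj_lo, obj_hi + 1))
        n_green = int(rng.integers(obj_lo, obj_hi + 1))
        n_pairs = min(int(round(spec.planted_coloc_fraction * n_green)), n_red)
        reds: list[frozenset] = []
        greens: list[frozenset] = []
        for _ in range(n_red):
            blob = place_blob(roi_id, int(rng.integers(size_lo, size_hi + 1)))
            if blob is None:
                raise GenerationError(f"red object placement failed in nucleus {roi_id}")
            reds.append(blob)
            all_red_px |= blob
            halos.append((blob, _halo(blob, (h, w))))
        allowed = {
            (int(r), int(c))
            for r, c in np.argwhere((labels == roi_id) & interior)
        }
        pair_red_idx = list(rng.permutation(n_red)[:n_pairs])
        for gi in range(n_green):
            size = int(rng.integers(size_lo, size_hi + 1))
            if gi < n_pairs:
                ri = int(pair_red_idx[gi])
                green = None
                for _ in range(spec.max_attempts):
                    green = _grow_green_partner(
                        reds[ri],
                        spec.planted_overlap_px,
                        size,
                        allowed,
                        forbidden_except(skip=reds[ri]),
                        all_red_px,
                        rng,
                    )
                    if green is not None:
                        break
                if green is None:
                    raise GenerationError(
                        f"planted pair growth failed in nucleus {roi_id}"
                    )
                truth.planted_pairs.append(
                    (roi_id, ri, gi, spec.planted_overlap_px)
                )
            else:
                green = place_blob(roi_id, size)
                if green is None:
                    raise GenerationError(
                        f"green object placement failed in nucleus {roi_id}"
                    )
            greens.append(green)
            halos.append((green, _halo(green, (h, w))))
        truth.red_objects[roi_id] = reds
        truth.green_objects[roi_id] = greens

    red, green, blue = _render(spec, labels, truth, rng)
    image = MultiChannelImage(
        red=red, green=green, blue=blue, source_path=f"synthetic_seed{spec.seed}"
    )
    return image, truth


def _render(spec: SceneSpec, labels, truth: GroundTruth, rng) -> tuple:
    h, w = spec.image_size
    red = np.full((h, w), 2.0)
    green = np.full((h, w), 2.0)
    blue = np.full((h, w), spec.blue_background)
    blue[labels > 0] = spec.blue_signal
    lo, hi = spec.background_mean_range
    for roi_id in truth.mask.roi_ids:
        inside = labels == roi_id
        red[inside] = rng.uniform(lo, hi)
        green[inside] = rng.uniform(lo, hi)
        for pix in truth.red_objects.get(roi_id, []):
            for r, c in pix:
                red[r, c] += spec.signal_intensity
        for pix in truth.green_objects.get(roi_id, []):
            for r, c in pix:
                green[r, c] += spec.signal_intensity
    channels = []
    for ch in (red, green, blue):
        if spec.noise_sd > 0:
            ch = ch + rng.normal(0.0, spec.noise_sd, ch.shape)
        ch = np.clip(np.rint(ch), 0, spec.intensity_max).astype(spec.dtype)
        channels.append(ch)
    red, green, blue = channels
    if spec.impulse_noise_fraction > 0:
        for ch in (red, green):
            n_hit = int(round(spec.impulse_noise_fraction * ch.size))
            idx = rng.choice(ch.size, size=n_hit, replace=False)
            vals = rng.choice([0, spec.intensity_max], size=n_hit)
            ch.ravel()[idx] = vals
    return red, green, blue


def write_fixture_set(
    out_dir: str | Path, specs: list[SceneSpec]
) -> Path:
    """Write RGB TIFFs, label-mask TIFFs and a ground-truth manifest.

    Returns the manifest path.  The tab-delimited manifest has one row per
    nucleus: image path, nucleus id, n_red, n_green, n_coloc (planted
    pairs).  Deterministic: rerunning with the same specs reproduces the
    files byte-for-byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ["image\tnucleus_id\tn_red\tn_green\tn_coloc"]
    manifest_path = out_dir / "ground_truth.tsv"
    for i, spec in enumerate(specs):
        image, truth = generate_scene(spec)
        name = f"scene_{i:03d}_seed{spec.seed}"
        img_path = out_dir / f"{name}.tif"
        rgb = np.stack([image.red, image.green, image.blue], axis=-1)
        tifffile.imwrite(img_path, rgb, compression=None, photometric="rgb")
        tifffile.imwrite(
            out_dir / f"{name}_mask.tif",
            truth.mask.labels.astype(np.uint16),
            compression=None,
        )
        for roi_id, (n_red, n_green, n_coloc) in sorted(
            truth.counts_per_nucleus(min_pixels=1).items()
        ):
            rows.append(f"{img_path.name}\t{roi_id}\t{n_red}\t{n_green}\t{n_coloc}")
    manifest_path.write_text("\n".join(rows) + "\n")
    return manifest_path
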