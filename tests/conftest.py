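import numpy as np
import pytest

from objcoloc.detection import SegmentedObject
from objcoloc.roi import RoiMask


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def square_roi_mask():
    """One 10x10 ROI (100 px) with a 1-px background margin."""
    labels = np.zeros((12, 12), dtype=np.int32)
    labels[1:11, 1:11] = 1
    return RoiMask(labels=labels)


def make_object(pixels, object_id=1, channel="red", roi_id=1, intensity_sum=0):
    return SegmentedObject(
        object_id=object_id,
        channel=channel,
        roi_id=roi_id,
        pixels=frozenset(pixels),
        intensity_sum=intensity_sum,
    )


# ---- independent brute-force oracles --------------------------------------

def median_oracle(grid, window):
    """Per-pixel sort-and-pick-middle over the zero-padded grid."""
    rows, cols = window
    pr, pc = rows // 2, cols // 2
    padded = np.pad(np.asarray(grid), ((pr, pr), (pc, pc)))
    out = np.empty_like(np.asarray(grid))
    for r in range(out.shape[0]):
        for c in range(out.shape[1]):
            win = padded[r : r + rows, c : c + cols].ravel()
            out[r, c] = np.sort(win)[len(win) // 2]
    return out


def wiener_oracle(grid, window):
    """Direct double-loop local mean/variance Wiener filter, zero padding."""
    rows, cols = window
    pr, pc = rows // 2, cols // 2
    a = np.asarray(grid, dtype=float)
    padded = np.pad(a, ((pr, pr), (pc, pc)))
    h, w = a.shape
    mu = np.empty((h, w))
    var = np.empty((h, w))
    nm = rows * cols
    for r in range(h):
        for c in range(w):
            win = padded[r : r + rows, c : c + cols]
            mu[r, c] = win.sum() / nm
            var[r, c] = (win**2).sum() / nm - mu[r, c] ** 2
    v2 = var.mean()
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            s2 = var[r, c]
            if s2 <= v2 or s2 == 0:
                out[r, c] = mu[r, c]
            else:
                out[r, c] = mu[r, c] + (s2 - v2) / s2 * (a[r, c] - mu[r, c])
    upper = np.iinfo(grid.dtype).max if np.issubdtype(grid.dtype, np.integer) else a.max()
    return np.clip(out, 0, upper)


def flood_fill_components(binary):
    """Recursive-style flood fill returning the list of 8-connected pixel sets."""
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros_like(binary)
    comps = []
    h, w = binary.shape
    for r0 in range(h):
        for c0 in range(w):
            if not binary[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            comp = set()
            while stack:
                r, c = stack.pop()
                comp.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and binary[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            comps.append(frozenset(comp))
    return comps


def pair_count_oracle(red_objects, green_objects, required):
    """Exhaustive all-pairs set-intersection count.

    ``required`` is a callable (area_red, area_green) -> minimum overlap.
    """
    count = 0
    for r in red_objects:
        for g in green_objects:
            if r.roi_id != g.roi_id:
                continue
            if len(r.pixels & g.pixels) >= required(r.area_px, g.area_px):
                count += 1
    return count
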