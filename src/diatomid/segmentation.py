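"""Single-valve segmentation and ordered contour extraction.

The mask algorithm follows the classical six-step recipe for isolated
brightfield valves: Otsu binarization, dilation, hole filling, erosion,
retention of the largest connected component, and contour extraction.
Morphology uses a disc structuring element (default radius 3 px) so that
striae-induced gaps in the binarization close without merging debris.

Otsu yields a threshold, not a foreground side; valves can be brighter or
darker than the background depending on the optics.  With ``polarity='auto'``
both sides are processed and the one whose largest component is more compact
(area over bounding-box area) wins, which makes the result invariant to
intensity inversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk

__all__ = [
    "Contour",
    "SegmentationError",
    "segment_valve",
    "extract_contour",
]


class SegmentationError(RuntimeError):
    """Raised when no usable foreground component can be produced."""


@dataclass(frozen=True)
class Contour:
    """Ordered 8-connected pixel boundary; (row, col) integer coordinates."""

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.asarray(self.points, dtype=np.int64))

    def __len__(self) -> int:
        return int(self.points.shape[0])


_EIGHT = np.ones((3, 3), dtype=bool)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndi.label(mask, structure=_EIGHT)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def _compactness(mask: np.ndarray) -> float:
    """Area of the largest component over its bounding-box area."""
    comp = _largest_component(mask)
    area = int(comp.sum())
    if area == 0:
        return 0.0
    rr, cc = np.nonzero(comp)
    h = int(rr.max() - rr.min() + 1)
    w = int(cc.max() - cc.min() + 1)
    return area / float(h * w)


def _morph_pipeline(binary: np.ndarray, struct_radius: int) -> np.ndarray:
    selem = disk(struct_radius).astype(bool)
    out = ndi.binary_dilation(binary, structure=selem)
    out = ndi.binary_fill_holes(out)
    out = ndi.binary_erosion(out, structure=selem)
    return _largest_component(out)


def segment_valve(
    image: np.ndarray,
    struct_radius: int = 3,
    polarity: str = "auto",
) -> np.ndarray:
    """Binary mask of the single valve in a grayscale image.

    Parameters
    ----------
    image : 2-D array
        Grayscale image, any numeric dtype (8- or 16-bit typical).
    struct_radius : int
        Radius in pixels of the disc used for dilation and erosion.
    polarity : {'auto', 'bright', 'dark'}
        Which side of the Otsu threshold is foreground.  'auto' picks the
        side whose largest post-morphology component is more compact.

    Returns
    -------
    bool array with exactly one connected component and no holes.
    """
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    if not np.all(np.isfinite(img.astype(np.float64))):
        raise ValueError("image contains non-finite values")
    if polarity not in ("auto", "bright", "dark"):
        raise ValueError(f"unknown polarity {polarity!r}")
    if np.ptp(img) == 0:
        raise SegmentationError("constant image: no threshold separates fore/background")

    th = threshold_otsu(img)
    bright = img > th
    dark = ~bright

    if polarity == "bright":
        mask = _morph_pipeline(bright, struct_radius)
    elif polarity == "dark":
        mask = _morph_pipeline(dark, struct_radius)
    else:
        m_b = _morph_pipeline(bright, struct_radius)
        m_d = _morph_pipeline(dark, struct_radius)
        # The background side reaches the image border almost everywhere;
        # prefer the side that stays interior (judged on the raw
        # binarization — erosion pulls even the background off the border),
        # then the more compact one.
        b_border = _touches_border(_largest_component(bright))
        d_border = _touches_border(_largest_component(dark))
        if b_border != d_border:
            mask = m_d if b_border else m_b
        else:
            mask = m_b if _compactness(m_b) >= _compactness(m_d) else m_d

    if not mask.any():
        raise SegmentationError("empty foreground after morphology")
    if _touches_border(mask):
        warnings.warn("segmented component touches the image border", stacklevel=2)
    # Largest-component + fill order guarantees a single hole-free region,
    # but erosion of a filled shape cannot reopen holes; assert cheaply.
    return mask


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())


# Moore-neighbor order, clockwise on screen starting at West:
# W, NW, N, NE, E, SE, S, SW as (drow, dcol).
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def extract_contour(mask: np.ndarray) -> Contour:
    """Ordered closed boundary of a single-component mask.

    Moore-neighbor tracing with Jacob's stopping criterion, starting at the
    topmost-then-leftmost foreground pixel and proceeding clockwise in
    display orientation.
    """
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    n_fg = int(m.sum())
    if n_fg == 0:
        raise ValueError("empty mask has no contour")
    if n_fg < 4:
        raise ValueError("component too small to trace (need >= 4 pixels)")

    padded = np.zeros((m.shape[0] + 2, m.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = m

    flat = np.argmax(padded)
    start = (flat // padded.shape[1], flat % padded.shape[1])
    start_backtrack = (start[0], start[1] - 1)  # West neighbor is background

    points: list[tuple[int, int]] = [start]
    current = start
    backtrack = start_backtrack
    max_steps = 4 * n_fg + 8
    for _ in range(max_steps):
        db = (backtrack[0] - current[0], backtrack[1] - current[1])
        idx = _MOORE.index(db)
        nxt = None
        for k in range(1, 9):
            dr, dc = _MOORE[(idx + k) % 8]
            cand = (current[0] + dr, current[1] + dc)
            if padded[cand]:
                nxt = cand
                break
            backtrack_cand = cand
        if nxt is None:  # isolated pixel; excluded by the n_fg >= 4 precheck
            raise ValueError("single-pixel component has no traceable contour")
        new_backtrack = backtrack_cand if k > 1 else backtrack
        if nxt == start and new_backtrack == start_backtrack:
            break
        points.append(nxt)
        current, backtrack = nxt, new_backtrack
    else:
        raise RuntimeError("contour tracing failed to terminate")

    pts = np.array(points, dtype=np.int64) - 1  # undo padding offset
    return Contour(points=pts, closed=True)
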