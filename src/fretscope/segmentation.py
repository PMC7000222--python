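"""Per-frame cell segmentation and derived geometry.

Masks are built from the acceptor channel (the most uniform label) by global
thresholding, optional erosion smoothing, hole filling and small-particle
removal.  Every downstream stage — quadrant statistics, linescans, sector
kymographs, morphodynamics — consumes the resulting ``CellMaskStack``.

Coordinate convention: (row, col), 0-based, pixel centers at integer
coordinates.  Distances are in pixels; conversion to µm happens only at
reporting time via ``pixel_size_um``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature as _skfeature
from skimage import filters as _skfilters
from skimage import measure as _skmeasure
from skimage import morphology as _skmorph

from .errors import DataError, SegmentationError

__all__ = [
    "CellMaskStack",
    "build_mask",
    "detect_boundary",
    "trace_boundary",
    "boundary_chain_length",
    "quadrant_labels",
    "edge_distance",
]

# Moore neighbourhood scanned clockwise, starting from the pixel above.
_MOORE = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
)


@dataclass
class CellMaskStack:
    """Binary cell footprints with centroids and ordered boundaries.

    ``masks`` is T×H×W boolean with one connected component per frame;
    ``centroids`` holds per-frame (row, col) in float pixels; ``boundaries``
    holds per-frame (N, 2) integer arrays tracing a closed 8-connected loop.
    """

    masks: np.ndarray
    centroids: list = field(default_factory=list)
    boundaries: list = field(default_factory=list)
    pixel_size_um: float = 0.2

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim == 2:
            self.masks = self.masks[None]
        if self.masks.ndim != 3:
            raise DataError(f"masks must be T×H×W, got shape {self.masks.shape}")
        if not self.centroids:
            self.centroids = [_centroid(m) for m in self.masks]
        if not self.boundaries:
            self.boundaries = [trace_boundary(m) for m in self.masks]

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]

    def areas(self) -> np.ndarray:
        """Foreground pixel count per frame."""
        return self.masks.sum(axis=(1, 2)).astype(float)

    def perimeters(self) -> np.ndarray:
        """Boundary chain length per frame (diagonal steps weighted √2)."""
        return np.array([boundary_chain_length(b) for b in self.boundaries])


def _centroid(mask: np.ndarray) -> tuple[float, float]:
    rs, cs = np.nonzero(mask)
    if rs.size == 0:
        raise SegmentationError("empty mask has no centroid")
    return float(rs.mean()), float(cs.mean())


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered closed boundary of a single-component mask (Moore tracing).

    Returns an (N, 2) array of (row, col) pixels forming an 8-connected loop
    traversed clockwise from the topmost-leftmost foreground pixel.  A
    single-pixel mask yields a degenerate boundary of length 1.
    """
    mask = np.asarray(mask, dtype=bool)
    rs, cs = np.nonzero(mask)
    if rs.size == 0:
        raise SegmentationError("cannot trace the boundary of an empty mask")
    start = (int(rs[0]), int(cs[0]))  # row-major order: topmost, then leftmost

    h, w = mask.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    if not any(fg(start[0] + dr, start[1] + dc) for dr, dc in _MOORE):
        return np.array([start])

    dir_index = {tuple(d): i for i, d in enumerate(_MOORE)}
    boundary = [start]
    # Enter the start pixel from its left neighbour (background by choice of
    # start); scan the Moore neighbourhood clockwise from the backtrack pixel.
    cur = start
    backtrack = (start[0], start[1] - 1)
    initial_state = None
    while True:
        k = dir_index[(backtrack[0] - cur[0], backtrack[1] - cur[1])]
        for step in range(1, 9):
            j = (k + step) % 8
            cand = (cur[0] + _MOORE[j][0], cur[1] + _MOORE[j][1])
            if fg(*cand):
                backtrack = (cur[0] + _MOORE[(j - 1) % 8][0],
                             cur[1] + _MOORE[(j - 1) % 8][1])
                cur = cand
                break
        state = (cur, backtrack)
        if initial_state is None:
            initial_state = state
        elif state == initial_state:  # loop closed: same pixel, same entry
            break
        boundary.append(cur)
        if len(boundary) > 4 * (h * w):  # safety net; unreachable on valid input
            raise SegmentationError("boundary tracing did not close")
    if len(boundary) > 1 and boundary[-1] == boundary[0]:
        boundary.pop()
    return np.array(boundary)


def boundary_chain_length(boundary: np.ndarray) -> float:
    """Closed chain length: axial steps count 1, diagonal steps √2."""
    b = np.asarray(boundary, dtype=float)
    if len(b) < 2:
        return 0.0
    steps = np.diff(np.vstack([b, b[:1]]), axis=0)
    return float(np.where(np.abs(steps).sum(axis=1) == 2, np.sqrt(2.0), 1.0).sum())


def _select_component(labeled: np.ndarray, n: int,
                      prev_centroid: tuple[float, float] | None) -> np.ndarray:
    """Largest component on the first frame; nearest-centroid linkage after."""
    if n == 1:
        return labeled == 1
    props = _skmeasure.regionprops(labeled)
    if prev_centroid is None:
        best = max(props, key=lambda p: p.area)
    else:
        pc = np.asarray(prev_centroid)
        best = min(props, key=lambda p: np.hypot(*(np.asarray(p.centroid) - pc)))
    return labeled == best.label


def build_mask(
    stack: np.ndarray,
    threshold: float | None = None,
    min_area_px: int = 50,
    erosion_radius_px: int = 0,
    pixel_size_um: float = 0.2,
) -> CellMaskStack:
    """Segment the cell footprint in every frame of an intensity stack.

    Per frame: global threshold (Otsu when ``threshold`` is None, else the
    given fixed value) → optional erosion with a disk of ``erosion_radius_px``
    (a smoothing step, off by default so clean data is not shrunk) → fill
    holes → drop components smaller than ``min_area_px`` → keep the largest
    component (first frame) or the one nearest the previous frame's centroid.
    """
    arr = np.asarray(stack, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    masks = np.zeros(arr.shape, dtype=bool)
    prev_centroid = None
    for t, frame in enumerate(arr):
        thr = threshold
        if thr is None:
            if np.ptp(frame) == 0:
                raise SegmentationError(f"frame {t}: no cell detected (flat image)")
            thr = _skfilters.threshold_otsu(frame)
        binary = frame > thr
        if erosion_radius_px > 0:
            binary = _skmorph.binary_erosion(binary, _skmorph.disk(erosion_radius_px))
        binary = ndimage.binary_fill_holes(binary)
        # drop components with area < min_area_px (max_size is inclusive)
        binary = _skmorph.remove_small_objects(binary, max_size=min_area_px - 1)
        labeled, n = ndimage.label(binary)
        if n == 0:
            raise SegmentationError(f"frame {t}: no cell detected")
        masks[t] = _select_component(labeled, n, prev_centroid)
        prev_centroid = _centroid(masks[t])
    return CellMaskStack(masks=masks, pixel_size_um=pixel_size_um)


def detect_boundary(
    mask_or_image: np.ndarray,
    method: str = "mask-trace",
    sigma: float = 2.0,
    low: float = 0.1,
    high: float = 0.3,
) -> np.ndarray:
    """Ordered closed cell boundary from a mask or a contrasted image.

    ``mask-trace`` runs Moore tracing on a binary mask.  ``canny`` runs edge
    detection (hysteresis thresholds ``low``/``high`` as fractions of the
    intensity range), closes the outermost contour by hole filling, keeps the
    largest component and traces it; on clean masks both methods agree to
    within one pixel.
    """
    arr = np.asarray(mask_or_image)
    if method == "mask-trace":
        return trace_boundary(arr.astype(bool))
    if method == "canny":
        img = arr.astype(float)
        rng = np.ptp(img)
        if rng == 0:
            raise SegmentationError("flat image: no edges to detect")
        edges = _skfeature.canny(
            img, sigma=sigma, low_threshold=low * rng, high_threshold=high * rng
        )
        filled = ndimage.binary_fill_holes(edges)
        labeled, n = ndimage.label(filled)
        if n == 0:
            raise SegmentationError("Canny found no closed contour")
        sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, range(1, n + 1))
        return trace_boundary(labeled == (1 + int(np.argmax(sizes))))
    raise ValueError(f"unknown boundary method {method!r}")


def quadrant_labels(mask_stack: CellMaskStack) -> np.ndarray:
    """Axis-aligned quadrant labels through each frame's centroid.

    Returns a T×H×W integer array: 0 outside the cell, 1..4 inside with
    Q1 = top-left, Q2 = top-right, Q3 = bottom-left, Q4 = bottom-right.
    Pixels exactly on a dividing line belong to the right/bottom side.
    """
    masks = mask_stack.masks
    labels = np.zeros(masks.shape, dtype=np.uint8)
    rows = np.arange(masks.shape[1])[:, None]
    cols = np.arange(masks.shape[2])[None, :]
    for t, (mask, (cr, cc)) in enumerate(zip(masks, mask_stack.centroids)):
        top = rows < cr
        left = cols < cc
        q = np.where(top, np.where(left, 1, 2), np.where(left, 3, 4))
        labels[t] = np.where(mask, q, 0)
    return labels


def edge_distance(mask: np.ndarray) -> np.ndarray:
    """Euclidean distance of every foreground pixel to the nearest
    background pixel; 0 outside the mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SegmentationError("empty mask has no edge distances")
    return ndimage.distance_transform_edt(mask)
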