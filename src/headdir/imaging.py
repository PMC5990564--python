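"""Species-independent image processing.

Every stage of the per-frame chain lives here: absolute background
differencing, greyscale morphological opening, binarization, Canny-based
contour extraction with the minimum bounding rectangle (MBR), and the
motion statistic that gates whether the (more expensive) species-specific
geometry runs at all.

Images are plain numpy arrays: RGB frames are ``(H, W, 3) uint8``,
greyscale images ``(H, W) uint8`` and binary masks ``(H, W) uint8`` with
values in ``{0, 255}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import canny
from skimage.measure import label, regionprops

from .errors import DimensionMismatchError

__all__ = [
    "BoundingRect",
    "ContourInfo",
    "to_gray",
    "background_difference",
    "morph_open",
    "binarize",
    "detect_contours",
    "motion_metric",
    "has_motion",
]

@dataclass(frozen=True)
class BoundingRect:
    """Axis-aligned rectangle ``(x, y, w, h)`` with (x, y) the upper-left corner.

    Built from a point set it is the minimum bounding rectangle: ``w`` and
    ``h`` are coordinate extents (max - min), so every input point p
    satisfies ``x <= p_x <= x + w`` and ``y <= p_y <= y + h``.  Used as a
    region of interest or crop, ``w`` and ``h`` are pixel counts.
    """

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 0 or self.h < 0:
            raise ValueError(f"negative rectangle extent: w={self.w}, h={self.h}")

    @classmethod
    def from_points(cls, points: np.ndarray) -> "BoundingRect":
        """MBR of an ``(N, 2)`` array of (x, y) points."""
        pts = np.asarray(points)
        if pts.size == 0:
            raise ValueError("cannot bound an empty point set")
        x0, y0 = pts.min(axis=0)
        x1, y1 = pts.max(axis=0)
        return cls(int(x0), int(y0), int(x1 - x0), int(y1 - y0))

    def contains(self, px: float, py: float) -> bool:
        return self.x <= px <= self.x + self.w and self.y <= py <= self.y + self.h

    @property
    def longer_side(self) -> int:
        return max(self.w, self.h)


@dataclass(frozen=True)
class ContourInfo:
    """One traced contour: its points, bounding-box centre and half girth.

    ``half_girth`` is the contour's own bounding-box width + height, the
    quantity the ``contourTh`` parameter filters on.
    """

    points: np.ndarray  # (N, 2) int array of (x, y)
    center: tuple[float, float] = field(default=(0.0, 0.0))
    half_girth: int = 0

    @classmethod
    def from_points(cls, points: np.ndarray) -> "ContourInfo":
        rect = BoundingRect.from_points(points)
        center = (rect.x + rect.w / 2.0, rect.y + rect.h / 2.0)
        return cls(points=np.asarray(points), center=center, half_girth=rect.w + rect.h)


def to_gray(rgb: np.ndarray) -> np.ndarray:
    """BT.601 luma conversion, rounded to the nearest integer intensity.

    Computed in exact integer arithmetic ((299R + 587G + 114B) / 1000,
    ties rounding up) so results are bit-reproducible across platforms.
    """
    arr = np.asarray(rgb)
    if arr.ndim == 2:
        return arr.astype(np.uint8)
    a = arr[..., :3].astype(np.int64)
    t = 299 * a[..., 0] + 587 * a[..., 1] + 114 * a[..., 2]
    return ((t + 500) // 1000).astype(np.uint8)


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise DimensionMismatchError(
            f"image dimensions differ: {a.shape} vs {b.shape}"
        )


def background_difference(frame: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Per-channel absolute difference |F - BG|, collapsed to greyscale."""
    frame = np.asarray(frame)
    background = np.asarray(background)
    _check_same_shape(frame, background)
    diff = np.abs(frame.astype(np.int16) - background.astype(np.int16)).astype(np.uint8)
    return to_gray(diff)


def morph_open(gray: np.ndarray, iterations: int) -> np.ndarray:
    """Greyscale opening with the 3x3 8-neighbourhood: n erosions then n dilations.

    Border neighbourhoods are clipped to the image (edge replication is
    equivalent for min/max filters).  ``iterations=0`` returns the input
    unchanged.  Removes bright features narrower than roughly
    ``2 * iterations + 1`` pixels.
    """
    if iterations < 0:
        raise ValueError(f"iterations must be >= 0, got {iterations}")
    out = np.asarray(gray)
    if iterations == 0:
        return out.copy()
    for _ in range(iterations):
        out = ndimage.grey_erosion(out, size=(3, 3), mode="nearest")
    for _ in range(iterations):
        out = ndimage.grey_dilation(out, size=(3, 3), mode="nearest")
    return out


def binarize(gray: np.ndarray, th_param: int) -> np.ndarray:
    """Binary mask: 255 where intensity is strictly greater than ``th_param``."""
    if not 0 <= th_param <= 255:
        raise ValueError(f"thParam must be in [0, 255], got {th_param}")
    return np.where(np.asarray(gray) > th_param, 255, 0).astype(np.uint8)


def detect_contours(
    mask: np.ndarray, contour_th: int
) -> tuple[list[ContourInfo], BoundingRect | None]:
    """Canny edges on the mask, traced into contours, filtered by half girth.

    Contours are the 8-connected components of the Canny edge map; each
    component's bounding-box centre and half girth (w + h) are recorded,
    components with half girth below ``contour_th`` are discarded, and the
    MBR over all surviving contour points is returned.  An empty result is
    ``([], None)`` — a valid outcome callers must handle.
    """
    mask = np.asarray(mask)
    edges = canny(mask.astype(float) / 255.0, sigma=1.0)
    labelled, n = label(edges, connectivity=2, return_num=True)
    contours: list[ContourInfo] = []
    for region in regionprops(labelled):
        # regionprops coords are (row, col) = (y, x)
        pts = region.coords[:, ::-1]
        info = ContourInfo.from_points(pts)
        if info.half_girth >= contour_th:
            contours.append(info)
    if not contours:
        return [], None
    all_pts = np.vstack([c.points for c in contours])
    return contours, BoundingRect.from_points(all_pts)


def motion_metric(frame: np.ndarray, reference: np.ndarray) -> float:
    """sqrt(sum |grey(frame) - grey(reference)| / 255): the motion statistic."""
    frame = np.asarray(frame)
    reference = np.asarray(reference)
    _check_same_shape(frame, reference)
    g1 = to_gray(frame).astype(np.int64)
    g2 = to_gray(reference).astype(np.int64)
    return float(np.sqrt(np.abs(g1 - g2).sum() / 255.0))


def has_motion(metric: float, motion_th: tuple[float, float]) -> bool:
    """Gate: true iff theta_l <= metric < theta_u.

    The upper bound rejects global changes (e.g. lighting shifts) that are
    not animal motion.
    """
    lo, hi = motion_th
    if not lo < hi:
        raise ValueError(f"motionTh requires theta_l < theta_u, got {motion_th}")
    return lo <= metric < hi
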