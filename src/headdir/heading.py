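"""Species-specific head geometry.

Two marker-free algorithms share one heading convention: degrees
counterclockwise from image-east with the image's downward y-axis negated,
so image-up is +90 deg and the range is (-180, 180].

* Cluster algorithm (alligator/gerbil archetype): k-means over the
  foreground pixels; the cluster nearest a point projected ahead along the
  previous heading becomes the head cluster, its nearest neighbouring
  cluster's centroid the base point.
* Ear-tuft algorithm (marmoset archetype): the two largest surviving
  contours are the ear tufts; the heading is perpendicular to the ear
  line, disambiguated by the previous heading.

A colour-tag variant substitutes an HSV-detected tag centroid for the
cluster algorithm's base point, and ``apply_deg_th`` rejects heading jumps
larger than the per-species ``degTh``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from skimage.color import rgb2hsv
from sklearn.cluster import KMeans

from .errors import (
    DegenerateGeometryError,
    EarsNotFoundError,
    InsufficientForegroundError,
    TagNotFoundError,
)
from .evaluate import circular_diff
from .imaging import BoundingRect, ContourInfo
from .params import SpeciesParams

__all__ = [
    "HeadingState",
    "head_angle",
    "project_head_point",
    "cluster_heading",
    "tuft_heading",
    "color_tag_bpos",
    "apply_deg_th",
]

Point = tuple[float, float]


@dataclass(frozen=True)
class HeadingState:
    """Per-frame head state: anterior point, base point, heading, manual flags.

    ``hpos`` is the anterior end of the head; ``bpos`` the base of the
    head-direction line (head-cluster neighbour centroid, ear midpoint or
    tag centroid).  ``m_hpos`` marks an explicit manual positioning on
    this frame; ``m_hd`` marks a manually determined direction, which
    includes every frame of continuous-manual mode.
    """

    hpos: Point
    bpos: Point
    hdir: float
    m_hpos: bool = False
    m_hd: bool = False


def head_angle(hpos: Point, bpos: Point) -> float:
    """Heading of the bPos->hPos line: atan2(-(h_y - b_y), h_x - b_x) in degrees.

    Negating dy converts image-down pixel coordinates to mathematical
    orientation; the result lies in (-180, 180].
    """
    hx, hy = hpos
    bx, by = bpos
    if hx == bx and hy == by:
        raise DegenerateGeometryError("hPos equals bPos; head direction undefined")
    deg = math.degrees(math.atan2(-(hy - by), hx - bx))
    if deg <= -180.0:
        deg += 360.0
    return deg


def project_head_point(
    prev_bpos: Point, prev_hdir: float, mbr: BoundingRect
) -> Point:
    """Project a point from bPos along the previous heading.

    The projection length is the longer side of the contours' MBR — a
    body-scale step that lands near where the head should be if the
    animal kept its heading.
    """
    length = mbr.longer_side
    rad = math.radians(prev_hdir)
    bx, by = prev_bpos
    return (bx + math.cos(rad) * length, by - math.sin(rad) * length)


def cluster_heading(
    mask: np.ndarray,
    prev: HeadingState,
    params: SpeciesParams,
    mbr: BoundingRect,
    seed: int = 0,
) -> HeadingState:
    """k-means body-part clustering with projected head-cluster selection.

    Foreground (x, y) points are clustered into ``params.k`` groups with
    k-means (k-means++ start, fixed seed, iteration cap 100).  The cluster
    whose centroid lies nearest the projected head point becomes the head
    cluster; hPos is that cluster's foreground point nearest the
    projection, bPos the centroid of the neighbouring cluster closest to
    the head cluster's centroid.
    """
    ys, xs = np.nonzero(np.asarray(mask))
    pts = np.column_stack([xs, ys]).astype(float)
    if len(pts) < params.k:
        raise InsufficientForegroundError(
            f"{len(pts)} foreground points < k={params.k}"
        )
    km = KMeans(
        n_clusters=params.k,
        init="k-means++",
        n_init=1,
        max_iter=100,
        random_state=seed,
    ).fit(pts)
    centroids = km.cluster_centers_
    hpt = np.array(project_head_point(prev.bpos, prev.hdir, mbr))

    head_idx = int(np.argmin(np.linalg.norm(centroids - hpt, axis=1)))
    head_pts = pts[km.labels_ == head_idx]
    hpos_arr = head_pts[np.argmin(np.linalg.norm(head_pts - hpt, axis=1))]
    hpos = (float(hpos_arr[0]), float(hpos_arr[1]))

    others = np.flatnonzero(np.arange(params.k) != head_idx)
    d = np.linalg.norm(centroids[others] - centroids[head_idx], axis=1)
    bpos_arr = centroids[others[int(np.argmin(d))]]
    bpos = (float(bpos_arr[0]), float(bpos_arr[1]))

    return HeadingState(hpos, bpos, head_angle(hpos, bpos))


def tuft_heading(contours: Sequence[ContourInfo], prev: HeadingState) -> HeadingState:
    """Ear-tuft heading: perpendicular to the line joining the two ear contours.

    The two largest contours (by half girth) are the ears; bPos is the
    midpoint of their centres.  Rotating the ear line by 90 deg about
    bPos gives two candidate anterior points, each half the ear
    separation from bPos; the candidate whose heading is circularly
    closer to the previous heading wins.  On an exact tie the candidate
    from the +90 deg (counterclockwise) rotation is chosen.
    """
    if len(contours) < 2:
        raise EarsNotFoundError(f"{len(contours)} contour(s); need two ear tufts")
    two = sorted(contours, key=lambda c: c.half_girth, reverse=True)[:2]
    # order ears deterministically so the +90 candidate is well defined
    (c1, c2) = sorted((two[0].center, two[1].center))
    bx, by = ((c1[0] + c2[0]) / 2.0, (c1[1] + c2[1]) / 2.0)
    ex, ey = (c2[0] - c1[0], c2[1] - c1[1])
    # +90 deg CCW rotation of the ear vector, in image coordinates
    px, py = (ey / 2.0, -ex / 2.0)
    cand_plus = (bx + px, by + py)
    cand_minus = (bx - px, by - py)
    ang_plus = head_angle(cand_plus, (bx, by))
    ang_minus = head_angle(cand_minus, (bx, by))
    if circular_diff(ang_plus, prev.hdir) <= circular_diff(ang_minus, prev.hdir):
        hpos, hdir = cand_plus, ang_plus
    else:
        hpos, hdir = cand_minus, ang_minus
    return HeadingState(hpos, (bx, by), hdir)


# OpenCV-convention HSV bounds of the red tag: H in [175, 180], S in
# [100, 255], V in [90, 255].
_TAG_H = (175.0, 180.0)
_TAG_S = (100.0, 255.0)
_TAG_V = (90.0, 255.0)


def color_tag_bpos(frame: np.ndarray) -> Point:
    """Centroid of the red colour tag, via an inclusive HSV in-range mask.

    Hue is expressed on the half-degree scale (H in [0, 180)) so the
    published red range applies verbatim; the centroid is the zeroth/first
    moment ratio of the binary mask.
    """
    hsv = rgb2hsv(np.asarray(frame)[..., :3])
    h = hsv[..., 0] * 180.0
    s = hsv[..., 1] * 255.0
    v = hsv[..., 2] * 255.0
    mask = (
        (h >= _TAG_H[0]) & (h <= _TAG_H[1])
        & (s >= _TAG_S[0]) & (s <= _TAG_S[1])
        & (v >= _TAG_V[0]) & (v <= _TAG_V[1])
    )
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        raise TagNotFoundError("no pixel in the red tag HSV range")
    return (float(xs.mean()), float(ys.mean()))


def apply_deg_th(
    prev: HeadingState, candidate: HeadingState, deg_th: float
) -> HeadingState:
    """Reject heading jumps larger than ``deg_th``: hold the previous state.

    Reject-and-hold (rather than clamping) keeps implausible frames
    visibly stale so they attract manual review.
    """
    if circular_diff(prev.hdir, candidate.hdir) > deg_th:
        return replace(prev, m_hpos=False, m_hd=False)
    return candidate
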