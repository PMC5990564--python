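"""Species-specific tuning parameters.

Six parameters steer the general image-processing chain and the heading
gates, plus ``k`` (cluster count) for the cluster-based species.  Values
are per-species and per-setup: the presets below are starting points for
the two archetypes, matched to the synthetic scenes this package generates.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path

__all__ = ["SpeciesParams", "CLUSTER_DEFAULTS", "TUFT_DEFAULTS", "load_params"]


@dataclass(frozen=True)
class SpeciesParams:
    """Tuning knobs for one species.

    mexo_iter
        Iterations of greyscale morphological opening (``mExOIter``);
        removes bright features narrower than ~2n+1 px.
    th_param
        Binarization threshold in [0, 255] applied to the opened
        difference image.
    contour_th
        Minimum contour half girth (bounding-box w + h) in px; smaller
        contours are discarded as noise.
    motion_th
        ``(theta_l, theta_u)`` bounds on the motion statistic; the
        species algorithm runs only when ``theta_l <= m < theta_u``.
    deg_th
        Maximum accepted frame-to-frame heading change in degrees;
        larger jumps are rejected and the previous state held.
    hd_line_len
        Length in px of the heading line drawn on overlay frames.
    k
        Number of k-means clusters (cluster species only; >= 2).
    """

    mexo_iter: int
    th_param: int
    contour_th: int
    motion_th: tuple[float, float]
    deg_th: float
    hd_line_len: int
    k: int = 4

    def __post_init__(self) -> None:
        if self.mexo_iter < 0:
            raise ValueError("mExOIter must be >= 0")
        if not 0 <= self.th_param <= 255:
            raise ValueError("thParam must be in [0, 255]")
        lo, hi = self.motion_th
        if not lo < hi:
            raise ValueError("motionTh requires theta_l < theta_u")
        if not 0 < self.deg_th <= 180:
            raise ValueError("degTh must be in (0, 180]")
        if self.k < 2:
            raise ValueError("k must be >= 2")


#: Cluster archetype (alligator/gerbil style): light opening, k blob clusters.
CLUSTER_DEFAULTS = SpeciesParams(
    mexo_iter=1,
    th_param=60,
    contour_th=10,
    motion_th=(0.5, 10_000.0),
    deg_th=40.0,
    hd_line_len=30,
    k=4,
)

#: Tufted archetype (marmoset style): heavy opening isolates the two
#: bright ear tufts; k is unused.
TUFT_DEFAULTS = SpeciesParams(
    mexo_iter=8,
    th_param=120,
    contour_th=10,
    motion_th=(0.5, 10_000.0),
    deg_th=60.0,
    hd_line_len=40,
    k=2,
)

_KEYS = {
    "mExOIter": "mexo_iter",
    "thParam": "th_param",
    "contourTh": "contour_th",
    "motionTh": "motion_th",
    "degTh": "deg_th",
    "hdLineLen": "hd_line_len",
    "k": "k",
}


def load_params(path: str | Path) -> SpeciesParams:
    """Read a TOML parameter file with the seven species keys.

    Expected keys: mExOIter, thParam, contourTh, motionTh (two-element
    array), degTh, hdLineLen and (optionally) k.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    kwargs = {}
    for toml_key, attr in _KEYS.items():
        if toml_key in raw:
            val = raw[toml_key]
            if attr == "motion_th":
                val = (float(val[0]), float(val[1]))
            kwargs[attr] = val
    missing = {k for k, a in _KEYS.items() if a not in kwargs and a != "k"}
    if missing:
        raise ValueError(f"parameter file {path} missing keys: {sorted(missing)}")
    return SpeciesParams(**kwargs)
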