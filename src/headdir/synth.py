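"""Ground-truthed synthetic scenes for every pipeline stage.

The generators emulate the overhead-camera footage the coder works from:
a dark static background, a bright animal, and (for synchronization) an
infrared LED region that switches to white at a planted time.

* Cluster archetype — an elongated chain of bright blobs (a long-bodied
  animal seen from above); the leading, slightly smaller blob is the
  head, so the k-means head cluster is geometrically identifiable.
* Tuft archetype — a dim body disk plus two bright ear-tuft disks placed
  symmetrically about the planted head axis; heavy morphological opening
  plus thresholding isolates the tufts.
* LED session — dark frames with a white block inside the LED region
  from a planted onset time, paired with a session log in the
  extraction-stage format.

Every generator is deterministic for a given seed and writes the planted
per-frame head state (or onset frame) beside the images, so each
downstream stage can be scored against known truth.  Frames are written
as lossless PNG so planted intensities survive encoding exactly.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .heading import HeadingState, head_angle
from .imaging import BoundingRect
from .imgio import write_image
from .sync import LedROI

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "make_arc_trajectory",
    "generate_cluster_scene",
    "generate_tuft_scene",
    "generate_led_session",
]


def _norm_deg(d: float) -> float:
    d = (d + 180.0) % 360.0 - 180.0
    return 180.0 if d == -180.0 else d


@dataclass
class GroundTruth:
    """Planted per-frame head state; for LED sessions, the planted onset."""

    frame_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    hpos: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    bpos: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    hdir: np.ndarray = field(default_factory=lambda: np.array([]))
    onset_frame: int | None = None
    stimulus_times_ms: list[int] = field(default_factory=list)

    def initial_state(self) -> HeadingState:
        """Planted state of the first frame, to seed a pipeline run."""
        return HeadingState(
            hpos=tuple(self.hpos[0]), bpos=tuple(self.bpos[0]), hdir=float(self.hdir[0])
        )

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["frame", "hPosX", "hPosY", "bPosX", "bPosY", "hDir"])
            for i in range(len(self.frame_index)):
                writer.writerow(
                    [
                        int(self.frame_index[i]),
                        f"{self.hpos[i, 0]:.3f}",
                        f"{self.hpos[i, 1]:.3f}",
                        f"{self.bpos[i, 0]:.3f}",
                        f"{self.bpos[i, 1]:.3f}",
                        f"{self.hdir[i]:.3f}",
                    ]
                )


@dataclass
class SceneSpec:
    """Description of a synthetic scene and its planted trajectory.

    The trajectory is a list of ``((x, y), heading_deg)`` pairs, one per
    frame: the anchor point (head-blob centre for the cluster archetype,
    ear midpoint for the tufted one) and the planted heading in
    (-180, 180].  Geometry defaults are sized so the documented default
    species parameters segment the animal cleanly.
    """

    archetype: str  # 'cluster' | 'tuft'
    trajectory: list[tuple[tuple[float, float], float]]
    width: int = 320
    height: int = 240
    # cluster-archetype geometry (blob chain)
    n_blobs: int = 4
    body_radius: int = 9
    head_radius: int = 6
    blob_spacing: int = 22
    blob_intensity: int = 200
    # tuft-archetype geometry
    tuft_radius: int = 12
    tuft_separation: int = 44
    tuft_intensity: int = 230
    body_disk_radius: int = 26
    body_intensity: int = 70
    body_offset: int = 10
    background_intensity: int = 12
    noise_amp: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ("cluster", "tuft"):
            raise ValueError(f"archetype must be 'cluster' or 'tuft': {self.archetype!r}")
        if not self.trajectory:
            raise ValueError("trajectory must contain at least one frame")
        if self.archetype == "tuft":
            if self.tuft_separation <= 2 * self.tuft_radius:
                raise ValueError("tufts overlap: separation must exceed 2 * radius")
            # the documented tuft defaults (mExOIter=8, thParam=120) must
            # isolate the tufts: they survive 8 erosions and only they
            # clear the threshold
            if self.tuft_radius <= 8:
                raise ValueError("tuft radius must exceed the opening scale (8)")
            if not (
                self.tuft_intensity - self.background_intensity
                > 120
                >= self.body_intensity - self.background_intensity
            ):
                raise ValueError(
                    "intensity contrast must straddle the binarization threshold"
                )
        for (x, y), d in self.trajectory:
            if not -180.0 < _norm_deg(d) <= 180.0:  # pragma: no cover - by construction
                raise ValueError("trajectory heading outside (-180, 180]")


def make_arc_trajectory(
    n_frames: int,
    width: int = 320,
    height: int = 240,
    radius: float = 55.0,
    step_deg: float = 2.5,
    seed: int = 0,
) -> list[tuple[tuple[float, float], float]]:
    """Smooth circular-arc walk: anchor on a circle, heading tangent to it.

    The start phase and turning direction are drawn from the seed, the
    per-frame heading change is ``step_deg`` — well inside the default
    degTh gate.
    """
    rng = np.random.default_rng(seed)
    phase = float(rng.uniform(0.0, 360.0))
    direction = 1.0 if rng.random() < 0.5 else -1.0
    cx, cy = width / 2.0, height / 2.0
    traj = []
    for i in range(n_frames):
        phi = math.radians(phase + direction * step_deg * i)
        pos = (cx + radius * math.cos(phi), cy - radius * math.sin(phi))
        heading = _norm_deg(math.degrees(phi) + direction * 90.0)
        traj.append((pos, heading))
    return traj


def _blank(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    base = np.full((spec.height, spec.width), spec.background_intensity, dtype=np.int16)
    if spec.noise_amp > 0:
        base = base + rng.integers(
            -spec.noise_amp, spec.noise_amp + 1, size=base.shape, dtype=np.int16
        )
    return base


def _draw_disk(img: np.ndarray, cx: float, cy: float, r: float, value: int) -> None:
    yy, xx = np.ogrid[: img.shape[0], : img.shape[1]]
    img[(xx - cx) ** 2 + (yy - cy) ** 2 <= r * r] = value


def _check_inside(spec: SceneSpec, cx: float, cy: float, r: float) -> None:
    if not (r <= cx <= spec.width - 1 - r and r <= cy <= spec.height - 1 - r):
        raise ValueError(
            f"trajectory leaves the image: disk at ({cx:.1f}, {cy:.1f}) r={r}"
        )


def _finish(img: np.ndarray) -> np.ndarray:
    return np.clip(img, 0, 255).astype(np.uint8)


def _write_scene(
    outdir: Path, bg: np.ndarray, frames: list[np.ndarray], truth: GroundTruth
) -> tuple[Path, list[Path]]:
    outdir.mkdir(parents=True, exist_ok=True)
    bg_path = outdir / "bg.png"
    write_image(bg_path, bg)
    paths = []
    for i, frame in enumerate(frames, start=1):
        p = outdir / f"f{i:06d}.png"
        write_image(p, frame)
        paths.append(p)
    truth.write_csv(outdir / "truth.csv")
    return bg_path, paths


def generate_cluster_scene(
    spec: SceneSpec, outdir: str | Path
) -> tuple[Path, list[Path], GroundTruth]:
    """Render a blob-chain animal along the planted trajectory.

    The chain has ``n_blobs`` bright disks trailing the head blob along
    the reversed heading; the planted hPos is the head blob's anterior
    tip, the planted bPos the centre of the head's neighbouring blob, so
    planted hDir = head_angle(hPos, bPos) = the trajectory heading.
    """
    if spec.archetype != "cluster":
        raise ValueError("spec archetype must be 'cluster'")
    rng = np.random.default_rng(spec.seed)
    bg = _finish(_blank(spec, rng))
    n = len(spec.trajectory)
    truth = GroundTruth(
        frame_index=np.arange(1, n + 1),
        hpos=np.zeros((n, 2)),
        bpos=np.zeros((n, 2)),
        hdir=np.zeros(n),
    )
    frames = []
    for i, ((x, y), d) in enumerate(spec.trajectory):
        img = _blank(spec, rng)
        rad = math.radians(d)
        ux, uy = math.cos(rad), -math.sin(rad)
        for b in range(spec.n_blobs):
            cx = x - ux * spec.blob_spacing * b
            cy = y - uy * spec.blob_spacing * b
            r = spec.head_radius if b == 0 else spec.body_radius
            _check_inside(spec, cx, cy, r)
            _draw_disk(img, cx, cy, r, spec.blob_intensity)
        frames.append(_finish(img))
        truth.hpos[i] = (x + ux * spec.head_radius, y + uy * spec.head_radius)
        truth.bpos[i] = (x - ux * spec.blob_spacing, y - uy * spec.blob_spacing)
        truth.hdir[i] = head_angle(tuple(truth.hpos[i]), tuple(truth.bpos[i]))
    bg_path, paths = _write_scene(Path(outdir), bg, frames, truth)
    return bg_path, paths, truth


def generate_tuft_scene(
    spec: SceneSpec, outdir: str | Path
) -> tuple[Path, list[Path], GroundTruth]:
    """Render a dim body with two bright ear tufts straddling the head axis.

    The ear line is perpendicular to the planted heading with midpoint at
    the planted bPos; the planted hPos sits half the ear separation ahead
    of bPos, matching the candidate geometry of the ear-tuft algorithm.
    """
    if spec.archetype != "tuft":
        raise ValueError("spec archetype must be 'tuft'")
    rng = np.random.default_rng(spec.seed)
    bg = _finish(_blank(spec, rng))
    n = len(spec.trajectory)
    truth = GroundTruth(
        frame_index=np.arange(1, n + 1),
        hpos=np.zeros((n, 2)),
        bpos=np.zeros((n, 2)),
        hdir=np.zeros(n),
    )
    frames = []
    half = spec.tuft_separation / 2.0
    for i, ((x, y), d) in enumerate(spec.trajectory):
        img = _blank(spec, rng)
        rad = math.radians(d)
        ux, uy = math.cos(rad), -math.sin(rad)
        px, py = -uy, ux  # ear-line direction, perpendicular to the heading
        bcx, bcy = x - ux * spec.body_offset, y - uy * spec.body_offset
        _check_inside(spec, bcx, bcy, spec.body_disk_radius)
        _draw_disk(img, bcx, bcy, spec.body_disk_radius, spec.body_intensity)
        for sign in (+1.0, -1.0):
            tx, ty = x + sign * px * half, y + sign * py * half
            _check_inside(spec, tx, ty, spec.tuft_radius)
            _draw_disk(img, tx, ty, spec.tuft_radius, spec.tuft_intensity)
        frames.append(_finish(img))
        truth.hpos[i] = (x + ux * half, y + uy * half)
        truth.bpos[i] = (x, y)
        truth.hdir[i] = head_angle(tuple(truth.hpos[i]), tuple(truth.bpos[i]))
    bg_path, paths = _write_scene(Path(outdir), bg, frames, truth)
    return bg_path, paths, truth


def generate_led_session(
    duration_s: float,
    fps: float,
    led_on_ms: float,
    stimulus_times_ms: list[int],
    roi: LedROI,
    outdir: str | Path,
    width: int = 64,
    height: int = 48,
    background_intensity: int = 8,
    noise_amp: int = 2,
    seed: int = 0,
) -> tuple[list[Path], Path, GroundTruth]:
    """Dark frames with a white LED block from ``led_on_ms`` onward, plus a log.

    Frame i (1-based) samples video time ``(i - 1) * 1000 / fps`` ms; the
    LED region is pure white on every frame at or after ``led_on_ms``, so
    the planted onset frame is the first index whose sample time reaches
    ``led_on_ms`` (``led_on_ms * fps / 1000 + 1`` when that is integral).
    The log places session_start at time 0 and one stimulus_play per
    entry of ``stimulus_times_ms`` (ms after session start).
    """
    total_ms = duration_s * 1000.0
    if not 0 <= led_on_ms < total_ms:
        raise ValueError("led_on_ms must lie inside the session duration")
    for t in stimulus_times_ms:
        if not 0 <= t < total_ms:
            raise ValueError(f"stimulus at {t} ms outside the session duration")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * fps))
    r = roi.rect
    if r.x + r.w > width or r.y + r.h > height:
        raise ValueError("LED ROI outside the frame")
    paths = []
    for i in range(1, n_frames + 1):
        img = np.full((height, width), background_intensity, dtype=np.int16)
        if noise_amp > 0:
            img = img + rng.integers(-noise_amp, noise_amp + 1, size=img.shape, dtype=np.int16)
        rgb = np.repeat(np.clip(img, 0, 255).astype(np.uint8)[:, :, None], 3, axis=2)
        t_ms = (i - 1) * 1000.0 / fps
        if t_ms >= led_on_ms:
            rgb[r.y : r.y + r.h, r.x : r.x + r.w] = 255
        p = outdir / f"f{i:06d}.png"
        write_image(p, rgb)
        paths.append(p)
    log_path = outdir / "session.log"
    with open(log_path, "w") as fh:
        fh.write("0,session_start\n")
        for j, t in enumerate(stimulus_times_ms, start=1):
            fh.write(f"{int(t)},stimulus_play,S{j}\n")
    # first 1-based i with (i - 1) * 1000 / fps >= led_on_ms
    onset = math.ceil(led_on_ms * fps / 1000.0 - 1e-9) + 1
    truth = GroundTruth(onset_frame=onset, stimulus_times_ms=list(stimulus_times_ms))
    return paths, log_path, truth
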