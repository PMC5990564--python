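"""Per-frame session orchestration.

Replays a whole frame folder through the analysis chain in navigation
order: motion gating, the general image-processing chain, species
dispatch, manual-override replay with the mHPos/mHD flag semantics,
degTh gating, CSV output and overlay rendering.

The GUI's mouse interaction is recast as data: a deterministic list of
``ManualOverride`` rows, optionally with continuous-manual mode toggles,
replayed in frame order.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .errors import HeadDirError, SessionLayoutError
from .heading import (
    HeadingState,
    apply_deg_th,
    cluster_heading,
    color_tag_bpos,
    head_angle,
    tuft_heading,
)
from .imaging import (
    background_difference,
    binarize,
    detect_contours,
    has_motion,
    morph_open,
    motion_metric,
)
from .imgio import FRAME_EXTENSIONS, read_image, write_image
from .params import SpeciesParams

__all__ = [
    "SessionConfig",
    "ManualOverride",
    "HeadRecord",
    "SessionResult",
    "load_session",
    "run_session",
    "write_csv",
    "read_csv",
    "read_overrides",
    "render_overlay",
]

log = logging.getLogger(__name__)

CSV_HEADER = ["Frame-index", "hPosX", "hPosY", "mHPos", "bPosX", "bPosY", "hDir", "mHD"]

_FRAME_RE = re.compile(r"^f(\d{6})\.(jpg|jpeg|png|tif|tiff)$", re.IGNORECASE)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class HeadRecord:
    """One output CSV row: frame index, head/base points, heading, manual flags."""

    frame_index: int
    hpos: tuple[int, int]
    bpos: tuple[int, int]
    hdir: int
    m_hpos: bool
    m_hd: bool

    @classmethod
    def from_state(cls, frame_index: int, state: HeadingState) -> "HeadRecord":
        return cls(
            frame_index=frame_index,
            hpos=(_round_half_up(state.hpos[0]), _round_half_up(state.hpos[1])),
            bpos=(_round_half_up(state.bpos[0]), _round_half_up(state.bpos[1])),
            hdir=_round_half_up(state.hdir),
            m_hpos=state.m_hpos,
            m_hd=state.m_hd,
        )


@dataclass(frozen=True)
class ManualOverride:
    """One replayed manual intervention.

    A row with positions sets the state for its frame (mHPos and mHD
    true); ``continuous`` additionally turns continuous-manual mode on
    from this frame, ``continuous_off`` turns it off (a positionless row
    with only ``continuous_off`` simply releases the mode and the frame
    is analysed normally).
    """

    frame_index: int
    hpos: tuple[float, float] | None = None
    bpos: tuple[float, float] | None = None
    continuous: bool = False
    continuous_off: bool = False

    def __post_init__(self) -> None:
        if self.frame_index < 1:
            raise ValueError("frame_index is 1-based and must be >= 1")
        if (self.hpos is None) != (self.bpos is None):
            raise ValueError("hPos and bPos must be given together")
        if self.hpos is not None and self.hpos == self.bpos:
            raise ValueError("override hPos must differ from bPos")
        if self.continuous and self.continuous_off:
            raise ValueError("an override cannot both enable and disable continuous mode")
        if self.hpos is None and not self.continuous_off:
            raise ValueError("an override without positions must set continuous_off")


@dataclass
class SessionConfig:
    """Everything needed to replay one session batch-style."""

    frames_dir: Path
    species: str  # 'cluster' | 'tuft'
    params: SpeciesParams
    color_tag: bool = False
    initial_state: HeadingState | None = None
    overlay_dir: Path | None = None
    fps: float | None = None  # metadata only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species not in ("cluster", "tuft"):
            raise ValueError(f"species must be 'cluster' or 'tuft', got {self.species!r}")
        self.frames_dir = Path(self.frames_dir)


@dataclass
class SessionResult:
    """Records plus bookkeeping for effort estimation."""

    records: list[HeadRecord]
    fallbacks: list[tuple[int, str]] = field(default_factory=list)
    manual_frames: int = 0
    continuous_frames: int = 0

    @property
    def fallback_rate(self) -> float:
        return len(self.fallbacks) / len(self.records) if self.records else 0.0


def load_session(frames_dir: str | Path):
    """Resolve a frame folder into (background image, ordered frame list).

    Frames follow the ``f%06d.<ext>`` convention (ext jpg/png/tif); the
    background is the ``bg`` file beside them.  Indices must be
    contiguous but need not start at 1.  Returns the background array and
    a sorted list of ``(index, path)`` pairs.
    """
    frames_dir = Path(frames_dir)
    if not frames_dir.is_dir():
        raise SessionLayoutError(f"{frames_dir} is not a directory")
    bg_path = None
    for ext in FRAME_EXTENSIONS:
        cand = frames_dir / f"bg{ext}"
        if cand.exists():
            bg_path = cand
            break
    if bg_path is None:
        raise SessionLayoutError(f"no background image (bg.jpg/png/tif) in {frames_dir}")
    frames: list[tuple[int, Path]] = []
    for p in frames_dir.iterdir():
        m = _FRAME_RE.match(p.name)
        if m:
            frames.append((int(m.group(1)), p))
    if not frames:
        raise SessionLayoutError(f"no frame images matching f%06d.* in {frames_dir}")
    frames.sort()
    indices = [i for i, _ in frames]
    for a, b in zip(indices, indices[1:]):
        if b != a + 1:
            raise SessionLayoutError(f"missing frame {a + 1} (indices jump {a} -> {b})")
    return read_image(bg_path), frames


def _analyse_frame(
    frame: np.ndarray,
    background: np.ndarray,
    prev: HeadingState,
    config: SessionConfig,
) -> HeadingState:
    """Run the general chain and dispatch to the species algorithm."""
    p = config.params
    diff = background_difference(frame, background)
    opened = morph_open(diff, p.mexo_iter)
    mask = binarize(opened, p.th_param)
    contours, mbr = detect_contours(mask, p.contour_th)
    if config.species == "tuft":
        candidate = tuft_heading(contours, prev)
    else:
        if mbr is None:
            raise HeadDirError("no contours survived filtering")
        candidate = cluster_heading(mask, prev, p, mbr, seed=config.seed)
        if config.color_tag:
            bpos = color_tag_bpos(frame)
            candidate = HeadingState(candidate.hpos, bpos, head_angle(candidate.hpos, bpos))
    return apply_deg_th(prev, candidate, p.deg_th)


def run_session(
    config: SessionConfig, overrides: list[ManualOverride] = ()
) -> SessionResult:
    """Replay every frame of a session and return one record per frame.

    Per frame, in priority order: an explicit override sets the state
    (mHPos and mHD true); continuous-manual mode carries the last manual
    state (mHD true only); the motion gate holds the previous state when
    the frame barely differs from the last motion frame; otherwise the
    image chain and species algorithm run, guarded by degTh.  Algorithm
    failures fall back to the previous state and are counted.
    """
    background, frames = load_session(config.frames_dir)
    by_frame: dict[int, ManualOverride] = {}
    for ov in overrides:
        if ov.frame_index in by_frame:
            raise ValueError(f"duplicate override for frame {ov.frame_index}")
        by_frame[ov.frame_index] = ov

    first_idx = frames[0][0]
    state = config.initial_state
    if state is None and not (
        first_idx in by_frame and by_frame[first_idx].hpos is not None
    ):
        raise SessionLayoutError(
            "first frame has no defined state: supply initial_state or an "
            f"override at frame {first_idx}"
        )

    result = SessionResult(records=[])
    continuous = False
    manual_state: HeadingState | None = None
    motion_ref: np.ndarray | None = None

    for idx, path in frames:
        frame = read_image(path)
        if motion_ref is None:
            motion_ref = frame  # "last motion frame" starts at the first frame
        ov = by_frame.get(idx)

        if ov is not None and ov.continuous_off:
            continuous = False
            manual_state = None
        if ov is not None and ov.hpos is not None:
            state = HeadingState(
                ov.hpos, ov.bpos, head_angle(ov.hpos, ov.bpos), m_hpos=True, m_hd=True
            )
            result.manual_frames += 1
            log.info("frame %d: manual override applied", idx)
            if ov.continuous or continuous:
                # a fresh manual input inside continuous mode refreshes
                # the carried state
                continuous = True
                manual_state = state
        elif continuous:
            state = replace(manual_state, m_hpos=False, m_hd=True)
            result.continuous_frames += 1
        else:
            metric = motion_metric(frame, motion_ref)
            if not has_motion(metric, config.params.motion_th):
                state = replace(state, m_hpos=False, m_hd=False)
            else:
                motion_ref = frame
                try:
                    state = _analyse_frame(frame, background, state, config)
                except HeadDirError as exc:
                    result.fallbacks.append((idx, str(exc)))
                    log.warning("frame %d: %s; holding previous state", idx, exc)
                    state = replace(state, m_hpos=False, m_hd=False)

        record = HeadRecord.from_state(idx, state)
        result.records.append(record)
        if config.overlay_dir is not None:
            config.overlay_dir.mkdir(parents=True, exist_ok=True)
            overlay = render_overlay(frame, record, config.params.hd_line_len)
            write_image(config.overlay_dir / f"f{idx:06d}.png", overlay)
    return result


def write_csv(records: list[HeadRecord], path: str | Path) -> None:
    """Write records in the output schema (booleans as True/False, ints elsewhere)."""
    if not records:
        raise ValueError("no records to write")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for r in records:
            writer.writerow(
                [
                    r.frame_index,
                    r.hpos[0],
                    r.hpos[1],
                    r.m_hpos,
                    r.bpos[0],
                    r.bpos[1],
                    r.hdir,
                    r.m_hd,
                ]
            )


def read_csv(path: str | Path) -> list[HeadRecord]:
    """Inverse of :func:`write_csv`."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != CSV_HEADER:
            raise ValueError(f"unexpected CSV header: {header}")
        for row in reader:
            records.append(
                HeadRecord(
                    frame_index=int(row[0]),
                    hpos=(int(row[1]), int(row[2])),
                    m_hpos=row[3] == "True",
                    bpos=(int(row[4]), int(row[5])),
                    hdir=int(row[6]),
                    m_hd=row[7] == "True",
                )
            )
    return records


def read_overrides(path: str | Path) -> list[ManualOverride]:
    """Read an override schedule CSV.

    Columns: frame_index,hPosX,hPosY,bPosX,bPosY,continuous,continuous_off;
    position cells may be empty on a row that only releases continuous mode.
    """
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            hpos = bpos = None
            if row.get("hPosX", "").strip():
                hpos = (float(row["hPosX"]), float(row["hPosY"]))
                bpos = (float(row["bPosX"]), float(row["bPosY"]))
            out.append(
                ManualOverride(
                    frame_index=int(row["frame_index"]),
                    hpos=hpos,
                    bpos=bpos,
                    continuous=row.get("continuous", "").strip().lower()
                    in ("1", "true", "yes"),
                    continuous_off=row.get("continuous_off", "").strip().lower()
                    in ("1", "true", "yes"),
                )
            )
    return out


def render_overlay(
    frame: np.ndarray, record: HeadRecord, hd_line_len: int
) -> np.ndarray:
    """Quarter-size sanity-check frame: heading line from bPos, circle at hPos end.

    The output is half the width and half the height of the input
    (rounded up); coordinates and the line length scale by the same
    factor.  Out-of-bounds drawing is clipped by the rasteriser.
    """
    frame = np.asarray(frame)
    h, w = frame.shape[:2]
    out_size = (math.ceil(w / 2), math.ceil(h / 2))
    im = Image.fromarray(frame).resize(out_size, Image.BILINEAR)
    draw = ImageDraw.Draw(im)
    bx, by = record.bpos[0] / 2.0, record.bpos[1] / 2.0
    rad = math.radians(record.hdir)
    length = hd_line_len / 2.0
    ex = bx + math.cos(rad) * length
    ey = by - math.sin(rad) * length
    draw.line([(bx, by), (ex, ey)], fill=(255, 0, 0), width=1)
    r = 3
    draw.ellipse([ex - r, ey - r, ex + r, ey + r], outline=(255, 0, 0), width=1)
    return np.asarray(im)
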