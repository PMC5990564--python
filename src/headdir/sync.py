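"""Video/log synchronization and trial-frame extraction.

A session video starts recording some unknown time before the experiment
log's clock starts.  An infrared LED inside a fixed region of the scene
switches on at the logged session start; detecting the first frame where
the white mass inside that region departs from its baseline gives the
offset dT between video time and log time.  Trial windows (a fixed
pre/post span around each stimulus-play timestamp, shifted by dT) are
then sliced out of the frame sequence, cropped, renumbered and filed
under a group/subject/trial/stimulus folder name.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.color import rgb2hsv

from .errors import LedOnsetNotFoundError, LogFormatError, TrialWindowError
from .imaging import BoundingRect
from .imgio import read_image, write_image

__all__ = [
    "LedROI",
    "SessionLog",
    "TrialSpec",
    "white_mass",
    "find_session_start",
    "extract_trials",
    "parse_log",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LedROI:
    """Region bounding the LED bulbs, plus the HSV definition of 'white'.

    White is low saturation and high value; hue is unconstrained.  The
    defaults (S <= 40, V >= 200 on the 0-255 scale) accept pure and
    near-pure white against a dark scene.
    """

    rect: BoundingRect
    s_max: float = 40.0
    v_min: float = 200.0


@dataclass(frozen=True)
class SessionLog:
    """Ordered, timestamped experiment events: one session_start, stimuli after."""

    events: tuple[tuple[int, str, str], ...]

    def __post_init__(self) -> None:
        starts = [e for e in self.events if e[1] == "session_start"]
        if len(starts) != 1:
            raise LogFormatError(
                f"log must contain exactly one session_start, found {len(starts)}"
            )
        ts = [e[0] for e in self.events]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise LogFormatError("log timestamps must be non-decreasing")

    @property
    def session_start_ms(self) -> int:
        return next(e[0] for e in self.events if e[1] == "session_start")

    @property
    def stimuli(self) -> list[tuple[int, str]]:
        """(ms after session_start, stimulus label) per stimulus_play event."""
        t0 = self.session_start_ms
        return [(t - t0, detail) for t, lbl, detail in self.events if lbl == "stimulus_play"]


@dataclass(frozen=True)
class TrialSpec:
    """Extraction window and naming for trial slicing.

    ``pre_s``/``post_s`` default to 5 s either side of stimulus onset —
    the span in which the head-turn response is expected.
    """

    fps: float
    crop: BoundingRect
    group: str
    subject: str
    pre_s: float = 5.0
    post_s: float = 5.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.pre_s <= 0 or self.post_s <= 0:
            raise ValueError("pre_s and post_s must be positive")


def white_mass(frame: np.ndarray, roi: LedROI) -> int:
    """Count of white pixels inside the ROI (the mask's zeroth moment / 255)."""
    frame = np.asarray(frame)
    h, w = frame.shape[:2]
    r = roi.rect
    if r.x < 0 or r.y < 0 or r.x + r.w > w or r.y + r.h > h:
        raise ValueError(f"LED ROI {r} outside frame bounds {w}x{h}")
    sub = frame[r.y : r.y + r.h, r.x : r.x + r.w, :3]
    hsv = rgb2hsv(sub)
    s = hsv[..., 1] * 255.0
    v = hsv[..., 2] * 255.0
    return int(((s <= roi.s_max) & (v >= roi.v_min)).sum())


def _frame_array(frame) -> np.ndarray:
    if isinstance(frame, (str, Path)):
        return read_image(frame)
    return np.asarray(frame)


def find_session_start(
    frames, roi: LedROI, threshold: int, fps: float
) -> tuple[int, float]:
    """Locate the LED switch frame and the video-time offset dT.

    The baseline is the first frame's white mass; scanning forward, the
    first frame whose mass differs from the baseline by more than
    ``threshold`` is the session-start frame i, and
    ``dT = (i - 1) * 1000 / fps`` ms is the video time at which the log
    clock started.  The detector is change-based and sign-agnostic.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    m_init = None
    for i, frame in enumerate(frames, start=1):
        m = white_mass(_frame_array(frame), roi)
        if m_init is None:
            m_init = m
            continue
        if abs(m - m_init) > threshold:
            return i, (i - 1) * 1000.0 / fps
    raise LedOnsetNotFoundError(
        "no frame's white mass departed from the baseline by more than "
        f"{threshold}"
    )


def extract_trials(
    frames: list,
    session_log: SessionLog,
    delta_ms: float,
    spec: TrialSpec,
    outdir: str | Path,
) -> list[Path]:
    """Slice, crop and file one frame window per stimulus event.

    For a stimulus logged t ms after session start, the onset video time
    is ``t + delta_ms`` and the onset frame index
    ``floor(onset_time * fps / 1000) + 1``.  The extracted window spans
    ``pre_s`` seconds before to ``post_s`` seconds after, so the onset
    frame sits at 1-based position ``pre_s * fps`` in a window of
    ``(pre_s + post_s) * fps`` frames (position 500 of 1000 at the 5 s +
    5 s, 100 FPS defaults).  Frames are cropped to ``spec.crop``,
    renumbered from 1 and written into
    ``<group>_<subject>_t<trial#>_<stimulus>``.
    """
    outdir = Path(outdir)
    n = len(frames)
    pre_n = int(round(spec.pre_s * spec.fps))
    post_n = int(round(spec.post_s * spec.fps))
    folders: list[Path] = []
    prev_end = None
    for trial_no, (t_ms, stimulus) in enumerate(session_log.stimuli, start=1):
        onset_time = t_ms + delta_ms
        onset_idx = math.floor(onset_time * spec.fps / 1000.0) + 1
        start = onset_idx - pre_n + 1
        end = onset_idx + post_n
        if start < 1:
            raise TrialWindowError(
                f"trial {trial_no} ({stimulus}): window starts before frame 1"
            )
        if end > n:
            raise TrialWindowError(
                f"trial {trial_no} ({stimulus}): window ends past frame {n}"
            )
        if prev_end is not None and start <= prev_end:
            log.warning("trial %d window overlaps the previous trial", trial_no)
        prev_end = end
        folder = outdir / f"{spec.group}_{spec.subject}_t{trial_no}_{stimulus}"
        folder.mkdir(parents=True, exist_ok=True)
        c = spec.crop
        for out_i, src_i in enumerate(range(start, end + 1), start=1):
            arr = _frame_array(frames[src_i - 1])
            cropped = arr[c.y : c.y + c.h, c.x : c.x + c.w]
            ext = Path(frames[src_i - 1]).suffix if isinstance(frames[src_i - 1], (str, Path)) else ".png"
            write_image(folder / f"f{out_i:06d}{ext}", cropped)
        folders.append(folder)
    return folders


def parse_log(path: str | Path) -> SessionLog:
    """Parse a session log: lines of ``timestamp_ms,label[,detail]``."""
    events = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",", 2)
            if len(parts) < 2:
                raise LogFormatError(f"{path}:{lineno}: expected timestamp_ms,label")
            try:
                ts = int(parts[0])
            except ValueError as exc:
                raise LogFormatError(
                    f"{path}:{lineno}: bad timestamp {parts[0]!r}"
                ) from exc
            detail = parts[2].strip() if len(parts) > 2 else ""
            events.append((ts, parts[1].strip(), detail))
    try:
        return SessionLog(events=tuple(events))
    except LogFormatError as exc:
        raise LogFormatError(f"{path}: {exc}") from exc
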