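"""Binary look coding and per-window looking times for both channels.

Looking behaviour arrives on two channels: high-rate eye-tracker samples and
40 ms frame-by-frame annotations. Both are reduced to a :class:`LookSeries`
— a contiguous sequence of equal-duration units, each coded LOOK or NO-LOOK
— from which looking times over arbitrary windows are computed by exact
unit/window overlap.

Conventions (both channels): track loss and off-screen gaze are coded
NO-LOOK, and no fixation filtering (minimum look or gap bridging) is applied
— per-sample looking time is simply (LOOK samples) / sampling rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .session_io import LOOK, FrameAnnotation, GazeStream, SessionSchedule

EYETRACKER = "eyetracker"
FRAMES = "frames"


@dataclass(frozen=True)
class Aoi:
    """An area of interest in normalized screen coordinates (inclusive bounds).

    The default is the full screen: this paradigm measures looking *to the
    screen*, not to regions within it.
    """

    x0: float = 0.0
    y0: float = 0.0
    x1: float = 1.0
    y1: float = 1.0

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)


FULL_SCREEN = Aoi()


@dataclass
class LookSeries:
    """Per-unit binary look series covering the session span contiguously."""

    channel: str  # eyetracker | frames
    unit_ms: float
    look: np.ndarray  # bool, one entry per unit
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.unit_ms <= 0:
            raise ConfigError("unit duration must be positive")
        self.look = np.asarray(self.look, dtype=bool)

    @property
    def span_ms(self) -> tuple[float, float]:
        return self.t0_ms, self.t0_ms + len(self.look) * self.unit_ms


def code_gaze(stream: GazeStream, aoi: Aoi | None = None) -> LookSeries:
    """Code a gaze stream: a sample is LOOK iff valid and inside the AOI.

    Invalid samples (track loss) and off-screen samples are NO-LOOK — the
    conservative convention shared with frame coding.
    """
    if stream.rate_hz <= 0:
        raise ConfigError("declared sampling rate must be positive")
    if len(stream.samples) == 0:
        raise DataError("empty gaze stream")
    aoi = aoi or FULL_SCREEN
    s = stream.samples
    x = s["x"].to_numpy(float)
    y = s["y"].to_numpy(float)
    look = s["valid"].to_numpy(bool) & aoi.contains(x, y)
    unit_ms = 1000.0 / stream.rate_hz
    return LookSeries(
        channel=EYETRACKER,
        unit_ms=unit_ms,
        look=look,
        t0_ms=float(s["t_ms"].iloc[0]),
    )


def code_frames(
    annotations: Sequence[FrameAnnotation],
    session_span_ms: float,
    frame_ms: float = 40.0,
) -> LookSeries:
    """Code frame annotations over a session span; uncovered frames are NO-LOOK."""
    if frame_ms <= 0:
        raise ConfigError("frame_ms must be positive")
    n = math.ceil(session_span_ms / frame_ms - 1e-9)
    look = np.zeros(n, dtype=bool)
    for a in annotations:
        if a.end_ms > session_span_ms + 1e-6:
            raise DataError(
                f"annotation [{a.start_ms}, {a.end_ms}) extends past the "
                f"session span {session_span_ms} ms"
            )
        if a.label == LOOK:
            i0 = int(round(a.start_ms / frame_ms))
            i1 = int(round(a.end_ms / frame_ms))
            look[i0:i1] = True
    return LookSeries(channel=FRAMES, unit_ms=frame_ms, look=look, t0_ms=0.0)


def looking_time(series: LookSeries, onset_ms: float, offset_ms: float) -> float:
    """Looking time (seconds) within [onset_ms, offset_ms).

    Each LOOK unit contributes its exact overlap with the window, so units
    straddling a window boundary contribute only the overlapping part.
    """
    if offset_ms <= onset_ms:
        raise DataError(f"window [{onset_ms}, {offset_ms}) has non-positive length")
    lo, hi = series.span_ms
    if onset_ms < lo - 1e-6 or offset_ms > hi + 1e-6:
        raise DataError(
            f"window [{onset_ms}, {offset_ms}) outside series span [{lo}, {hi})"
        )
    n = len(series.look)
    starts = series.t0_ms + np.arange(n) * series.unit_ms
    overlap = np.minimum(starts + series.unit_ms, offset_ms) - np.maximum(starts, onset_ms)
    np.clip(overlap, 0.0, None, out=overlap)
    return float(overlap[series.look].sum()) / 1000.0


def window_looking_times(series: LookSeries, schedule: SessionSchedule) -> pd.DataFrame:
    """Per-event looking-time table: phase, token_index, onset/duration, lt_s."""
    rows = []
    for ev in schedule.events:
        rows.append(
            {
                "phase": ev.phase,
                "token_index": ev.token_index,
                "onset_ms": ev.onset_ms,
                "duration_ms": ev.duration_ms,
                "lt_s": looking_time(series, ev.onset_ms, ev.offset_ms),
            }
        )
    out = pd.DataFrame(rows)
    out.insert(0, "channel", series.channel)
    return out


def phase_looking_time(series: LookSeries, schedule: SessionSchedule, phase: str) -> float:
    """Total looking time (s) summed over all events of a phase."""
    return sum(
        looking_time(series, ev.onset_ms, ev.offset_ms) for ev in schedule.events_for(phase)
    )
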