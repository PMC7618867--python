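"""Readers and writers for the delimited session files the toolkit touches.

Four file shapes are handled, all plain delimited text:

* **gaze streams** — one row per eye-tracker sample (timestamp, validity,
  normalized screen coordinates), with the sampling rate carried as stream
  metadata in a ``# rate_hz:`` comment header. Column names are dialect
  driven because vendor export schemas vary.
* **frame annotations** — ELAN-style tab-delimited LOOK/NO-LOOK tiers on a
  fixed frame grid (default 40 ms frames).
* **trial logs** — the timed phase structure of a session (attention-getter,
  habituation tokens, inter-stimulus intervals, same/switch test phases).
* **participant tables** — group, age in days, per-language exposure hours
  and language-mixing item ratings.

All timestamps are milliseconds from session start; every reader validates
the invariants it can check (monotone timestamps, non-overlapping intervals,
on-grid frame bounds) and raises :class:`~gazehab.errors.DataError` rather
than silently repairing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

log = logging.getLogger(__name__)

PHASES = ("attention_getter", "habituation", "isi", "same", "switch")

LOOK = "LOOK"
NO_LOOK = "NO-LOOK"

_LABEL_ALIASES = {
    "LOOK": LOOK,
    "NOLOOK": NO_LOOK,
    "NO-LOOK": NO_LOOK,
    "NO_LOOK": NO_LOOK,
    "NO LOOK": NO_LOOK,
}


# ---------------------------------------------------------------------------
# gaze streams
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GazeDialect:
    """Column mapping for a vendor gaze export.

    ``screen_px`` — if set, coordinate columns are in pixels and are divided
    by the screen resolution at read time (e.g. ``(1920, 1080)``).
    ``rate_hz`` — overrides the ``# rate_hz:`` header when given.
    """

    t_col: str = "t_ms"
    valid_col: str = "valid"
    x_col: str = "x"
    y_col: str = "y"
    delimiter: str = ","
    screen_px: tuple[int, int] | None = None
    rate_hz: float | None = None


@dataclass
class GazeStream:
    """A validated gaze sample stream.

    ``samples`` holds columns ``t_ms`` (float, strictly increasing),
    ``x``/``y`` (normalized [0, 1] coordinates, NaN when invalid) and
    ``valid`` (bool).
    """

    samples: pd.DataFrame
    rate_hz: float

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.samples)


def _read_rate_header(path: Path) -> float | None:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "rate_hz:" in line:
                return float(line.split("rate_hz:")[1].strip())
    return None


def read_gaze_stream(path, dialect: GazeDialect = GazeDialect()) -> GazeStream:
    """Read a delimited gaze export into a :class:`GazeStream`.

    Rows whose validity flag is set but whose coordinates are unparseable or
    absent are coerced to ``valid=False`` (never dropped); the coercion count
    is reported through logging.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.delimiter, comment="#")
    needed = {dialect.t_col, dialect.valid_col, dialect.x_col, dialect.y_col}
    missing = needed - set(df.columns)
    if missing:
        raise ConfigError(
            f"{path}: missing mandatory column(s) {sorted(missing)}; "
            f"check the gaze dialect mapping"
        )

    rate = dialect.rate_hz if dialect.rate_hz is not None else _read_rate_header(path)
    if rate is None or rate <= 0:
        raise ConfigError(
            f"{path}: no sampling rate (no '# rate_hz:' header and no dialect override)"
        )

    t = pd.to_numeric(df[dialect.t_col], errors="coerce").to_numpy(float)
    if np.isnan(t).any():
        bad = int(np.flatnonzero(np.isnan(t))[0])
        raise DataError(f"{path}: unparseable timestamp at data row {bad}")
    if (t < 0).any():
        raise DataError(f"{path}: negative timestamp at data row {int(np.flatnonzero(t < 0)[0])}")
    dt = np.diff(t)
    if (dt <= 0).any():
        bad = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise DataError(f"{path}: non-monotone timestamp at data row {bad}")

    valid = df[dialect.valid_col].astype(str).str.strip().str.lower().isin(
        {"1", "true", "t", "yes"}
    ) | (pd.to_numeric(df[dialect.valid_col], errors="coerce") == 1)
    valid = valid.to_numpy(bool)
    x = pd.to_numeric(df[dialect.x_col], errors="coerce").to_numpy(float)
    y = pd.to_numeric(df[dialect.y_col], errors="coerce").to_numpy(float)
    if dialect.screen_px is not None:
        x = x / dialect.screen_px[0]
        y = y / dialect.screen_px[1]

    coerced = valid & (np.isnan(x) | np.isnan(y))
    if coerced.any():
        log.warning(
            "%s: %d sample(s) flagged valid but had unparseable coordinates; "
            "coerced to valid=False",
            path,
            int(coerced.sum()),
        )
        valid = valid & ~coerced

    out = pd.DataFrame({"t_ms": t, "x": x, "y": y, "valid": valid})
    return GazeStream(samples=out, rate_hz=float(rate))


def write_gaze_stream(stream: GazeStream, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# gazehab gaze stream\n")
        fh.write(f"# rate_hz: {stream.rate_hz}\n")
        stream.samples.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# frame annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameAnnotation:
    """A LOOK / NO-LOOK interval on the frame grid, bounds in ms."""

    start_ms: int
    end_ms: int
    label: str = LOOK


def _on_grid(v: float, frame_ms: float) -> bool:
    return abs(v / frame_ms - round(v / frame_ms)) < 1e-9


def validate_annotations(
    annotations: Sequence[FrameAnnotation], frame_ms: float = 40.0
) -> list[FrameAnnotation]:
    """Sort, grid-check and overlap-check a set of annotations."""
    if frame_ms <= 0:
        raise ConfigError("frame_ms must be positive")
    anns = sorted(annotations, key=lambda a: (a.start_ms, a.end_ms))
    prev_end = None
    for a in anns:
        if a.end_ms <= a.start_ms:
            raise DataError(f"empty or inverted interval [{a.start_ms}, {a.end_ms})")
        if not (_on_grid(a.start_ms, frame_ms) and _on_grid(a.end_ms, frame_ms)):
            raise DataError(
                f"interval [{a.start_ms}, {a.end_ms}) is off the {frame_ms} ms frame grid"
            )
        if a.label not in (LOOK, NO_LOOK):
            raise DataError(f"unknown annotation label {a.label!r}")
        if prev_end is not None and a.start_ms < prev_end:
            raise DataError(
                f"overlapping annotation intervals at {a.start_ms} ms (previous ends {prev_end} ms)"
            )
        prev_end = a.end_ms
    return anns


def read_frame_annotations(path, frame_ms: float = 40.0) -> list[FrameAnnotation]:
    """Read an ELAN-style tab-delimited export (tier, start_ms, end_ms, label).

    Intervals are validated against the frame grid; an off-grid boundary is a
    data error (no silent snapping).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    needed = {"tier", "start_ms", "end_ms", "label"}
    missing = needed - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing column(s) {sorted(missing)}")
    anns = []
    for row in df.itertuples(index=False):
        label = _LABEL_ALIASES.get(str(row.label).strip().upper())
        if label is None:
            raise DataError(f"{path}: unknown label {row.label!r}")
        anns.append(FrameAnnotation(float(row.start_ms), float(row.end_ms), label))
    return validate_annotations(anns, frame_ms=frame_ms)


def write_frame_annotations(
    annotations: Sequence[FrameAnnotation], path, tier: str = "gaze"
) -> None:
    df = pd.DataFrame(
        {
            "tier": tier,
            "start_ms": [a.start_ms for a in annotations],
            "end_ms": [a.end_ms for a in annotations],
            "label": [a.label for a in annotations],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trial logs / schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialEvent:
    phase: str
    token_index: int  # 1-based within phase
    onset_ms: float
    duration_ms: float

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.duration_ms


@dataclass
class SessionSchedule:
    """An ordered, non-overlapping sequence of timed events."""

    events: list[TrialEvent]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.events:
            raise DataError("empty schedule")
        prev_off = None
        for ev in self.events:
            if ev.phase not in PHASES:
                raise DataError(f"unknown phase label {ev.phase!r}")
            if ev.duration_ms <= 0:
                raise DataError(f"non-positive duration for {ev.phase} token {ev.token_index}")
            if prev_off is not None and ev.onset_ms < prev_off - 1e-9:
                raise DataError(
                    f"overlapping events: {ev.phase} token {ev.token_index} "
                    f"starts at {ev.onset_ms} before previous event ends at {prev_off}"
                )
            prev_off = ev.offset_ms

    def __len__(self) -> int:
        return len(self.events)

    @property
    def span_ms(self) -> float:
        return self.events[-1].offset_ms

    def events_for(self, phase: str) -> list[TrialEvent]:
        return [e for e in self.events if e.phase == phase]

    def has_phase(self, phase: str) -> bool:
        return any(e.phase == phase for e in self.events)


def read_trial_log(path) -> SessionSchedule:
    """Read a trial log CSV (phase, token_index, onset_ms, duration_ms)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty trial log") from None
    needed = {"phase", "token_index", "onset_ms", "duration_ms"}
    missing = needed - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        raise DataError(f"{path}: empty trial log")
    events = [
        TrialEvent(str(r.phase), int(r.token_index), float(r.onset_ms), float(r.duration_ms))
        for r in df.itertuples(index=False)
    ]
    return SessionSchedule(events)


def write_trial_log(schedule: SessionSchedule, path) -> None:
    df = pd.DataFrame(
        {
            "phase": [e.phase for e in schedule.events],
            "token_index": [e.token_index for e in schedule.events],
            "onset_ms": [e.onset_ms for e in schedule.events],
            "duration_ms": [e.duration_ms for e in schedule.events],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# participants
# ---------------------------------------------------------------------------

@dataclass
class ParticipantProfile:
    participant_id: str
    group: str  # monolingual | bilingual
    age_days: int
    exposure_hours: dict[str, float] = field(default_factory=dict)
    mixing_items: list[float] = field(default_factory=list)
    languages: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in ("monolingual", "bilingual"):
            raise DataError(f"{self.participant_id}: unknown group {self.group!r}")
        if self.age_days <= 0:
            raise DataError(f"{self.participant_id}: age_days must be positive")
        for h in self.exposure_hours.values():
            if h < 0:
                raise DataError(f"{self.participant_id}: negative exposure hours")
        for m in self.mixing_items:
            if not 0 <= m <= 6:
                raise DataError(f"{self.participant_id}: mixing item {m} outside [0, 6]")
        if not self.languages:
            self.languages = sorted(self.exposure_hours)


def _fmt_hours(hours: Mapping[str, float]) -> str:
    return "|".join(f"{k}:{v:g}" for k, v in hours.items())


def _parse_hours(s: str) -> dict[str, float]:
    if not s or pd.isna(s):
        return {}
    out = {}
    for part in str(s).split("|"):
        k, v = part.split(":")
        out[k] = float(v)
    return out


def read_participants(path) -> list[ParticipantProfile]:
    df = pd.read_csv(path)
    needed = {"participant_id", "group", "age_days", "exposure_hours", "mixing_items"}
    missing = needed - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing column(s) {sorted(missing)}")
    profiles = []
    for r in df.itertuples(index=False):
        items = (
            [float(v) for v in str(r.mixing_items).split(";") if v != ""]
            if not pd.isna(r.mixing_items) and str(r.mixing_items) != ""
            else []
        )
        profiles.append(
            ParticipantProfile(
                participant_id=str(r.participant_id),
                group=str(r.group),
                age_days=int(r.age_days),
                exposure_hours=_parse_hours(r.exposure_hours),
                mixing_items=items,
            )
        )
    return profiles


def write_participants(profiles: Sequence[ParticipantProfile], path) -> None:
    df = pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in profiles],
            "group": [p.group for p in profiles],
            "age_days": [p.age_days for p in profiles],
            "exposure_hours": [_fmt_hours(p.exposure_hours) for p in profiles],
            "mixing_items": [";".join(f"{m:g}" for m in p.mixing_items) for p in profiles],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# session results
# ---------------------------------------------------------------------------

def write_session_results(results: pd.DataFrame, path, config_echo: Mapping) -> None:
    """Write a results table plus a JSON sidecar echoing the run config."""
    path = Path(path)
    results.to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(dict(config_echo), fh, indent=2, sort_keys=True, default=str)
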