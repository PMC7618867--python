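"""End-to-end session analysis: code -> habituate -> exclude -> score.

Wires the modules together for whole cohorts: looking-time coding on either
channel, offline replay of the habituation criterion, the exclusion ledger,
novelty preference scores and the long-format analysis table, plus the
dual-channel reliability report. Also handles reading/writing a cohort as
the on-disk file set the CLI exchanges.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import session_io
from .errors import DataError
from .habituation_engine import HabituationConfig, recompute_habituation
from .look_coder import (
    EYETRACKER,
    FRAMES,
    LookSeries,
    code_frames,
    code_gaze,
    looking_time,
    phase_looking_time,
)
from .reliability import (
    channel_correlation,
    flag_disagreements,
    habituation_agreement,
    pair_channels,
)
from .session_io import SessionSchedule
from .test_analytics import (
    ExclusionConfig,
    SessionResult,
    apply_exclusions,
    build_analysis_table,
    classify_discriminator,
    results_frame,
)


@dataclass
class LoadedSession:
    """A session as the analyzer sees it (no ground truth attached)."""

    participant_id: str
    group: str
    age_days: int
    schedule: SessionSchedule
    gaze: session_io.GazeStream | None = None
    frames: list[session_io.FrameAnnotation] | None = None


def _as_loaded(session) -> LoadedSession:
    if isinstance(session, LoadedSession):
        return session
    # a SyntheticSession quacks closely enough
    return LoadedSession(
        participant_id=session.participant_id,
        group=session.group,
        age_days=0,
        schedule=session.schedule,
        gaze=session.gaze,
        frames=session.frames,
    )


def session_series(session, channel: str = EYETRACKER) -> LookSeries:
    s = _as_loaded(session)
    if channel == EYETRACKER:
        if s.gaze is None:
            raise DataError(f"{s.participant_id}: no gaze channel")
        return code_gaze(s.gaze)
    if channel == FRAMES:
        if s.frames is None:
            raise DataError(f"{s.participant_id}: no frame channel")
        return code_frames(s.frames, s.schedule.span_ms)
    raise DataError(f"unknown channel {channel!r}")


def habituation_token_lts(series: LookSeries, schedule: SessionSchedule) -> list[float]:
    return [
        looking_time(series, ev.onset_ms, ev.offset_ms)
        for ev in schedule.events_for("habituation")
    ]


def summarize_session(
    session,
    config: HabituationConfig = HabituationConfig(),
    channel: str = EYETRACKER,
    age_days: int | None = None,
) -> SessionResult:
    """Reduce one session to a :class:`SessionResult` on one channel.

    Completion is read off the schedule: a session missing either test
    phase did not complete the task.
    """
    s = _as_loaded(session)
    series = session_series(s, channel)
    token_lts = habituation_token_lts(series, s.schedule)
    # clip coder jitter that spills a hair past the token bound
    token_lts = [min(lt, config.token_s) for lt in token_lts]
    hab = recompute_habituation(token_lts, config)
    completed = s.schedule.has_phase("same") and s.schedule.has_phase("switch")
    lt_same = phase_looking_time(series, s.schedule, "same") if completed else float("nan")
    lt_switch = phase_looking_time(series, s.schedule, "switch") if completed else float("nan")
    return SessionResult(
        participant_id=s.participant_id,
        group=s.group,
        age_days=age_days if age_days is not None else s.age_days,
        completed=completed,
        habituation_trial=hab.trial,
        habituation_status=hab.status,
        lt_same_s=lt_same,
        lt_switch_s=lt_switch,
        channel=channel,
    )


@dataclass
class CohortAnalysis:
    results: pd.DataFrame
    ledger: pd.DataFrame
    summary: pd.DataFrame
    analysis_table: pd.DataFrame
    n_included: int
    n_discriminators: int


def analyze_sessions(
    sessions,
    config: HabituationConfig = HabituationConfig(),
    channel: str = EYETRACKER,
    ages: dict[str, int] | None = None,
) -> CohortAnalysis:
    """Run the full analysis pipeline over a collection of sessions."""
    ages = ages or {}
    results = [
        summarize_session(s, config, channel, age_days=ages.get(_as_loaded(s).participant_id))
        for s in sessions
    ]
    df = results_frame(results)
    ledger, summary = apply_exclusions(df, ExclusionConfig.from_habituation(config))
    included = df[ledger["included"].to_numpy()]
    table = (
        build_analysis_table(included)
        if len(included)
        else pd.DataFrame(
            columns=["participant_id", "group", "age_days", "trial", "lt_s"]
        )
    )
    n_disc = int(
        sum(bool(classify_discriminator(s)) for s in included["novelty_score"])
    )
    return CohortAnalysis(
        results=df,
        ledger=ledger,
        summary=summary,
        analysis_table=table,
        n_included=int(ledger["included"].sum()),
        n_discriminators=n_disc,
    )


def phase_table(sessions, config: HabituationConfig, channel: str) -> pd.DataFrame:
    """Per-(participant, test phase) looking times on one channel."""
    rows = []
    for session in sessions:
        s = _as_loaded(session)
        series = session_series(s, channel)
        for phase in ("same", "switch"):
            if s.schedule.has_phase(phase):
                rows.append(
                    {
                        "participant_id": s.participant_id,
                        "phase": phase,
                        "lt_s": phase_looking_time(series, s.schedule, phase),
                    }
                )
    return pd.DataFrame(rows)


def reliability_report(
    sessions, config: HabituationConfig = HabituationConfig(), k_sd: float = 2.0
) -> dict:
    """Dual-channel validation over a cohort.

    Pairs test-phase looking times (eye-tracker vs frames), computes their
    Pearson correlation, flags disagreements beyond ``k_sd`` SDs above the
    mean difference, and checks habituation-trial concordance of the two
    channels' offline replays.
    """
    complete = [
        s
        for s in sessions
        if _as_loaded(s).schedule.has_phase("same") and _as_loaded(s).schedule.has_phase("switch")
    ]
    a = phase_table(complete, config, EYETRACKER)
    b = phase_table(complete, config, FRAMES)
    paired = pair_channels(a, b)
    corr = channel_correlation(paired.pairs)
    flags = flag_disagreements(paired.pairs, k_sd=k_sd)

    online, offline = {}, {}
    for session in sessions:
        s = _as_loaded(session)
        et = summarize_session(s, config, EYETRACKER)
        fr = summarize_session(s, config, FRAMES)
        online[s.participant_id] = et.habituation_trial
        offline[s.participant_id] = fr.habituation_trial
    agreement, rate = habituation_agreement(online, offline, config, config)
    return {
        "pairs": paired.pairs,
        "unmatched": paired.unmatched,
        "correlation": corr,
        "flags": flags,
        "agreement": agreement,
        "agreement_rate": rate,
    }


# ---------------------------------------------------------------------------
# cohort file exchange
# ---------------------------------------------------------------------------

def write_cohort(cohort, out_dir) -> dict:
    """Write a generated cohort as the file set session_io reads.

    Returns a manifest (config echo, seed, per-file checksums) that is also
    written to ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session_io.write_participants(cohort.profiles, out / "participants.csv")
    for s in cohort.sessions:
        session_io.write_gaze_stream(s.gaze, out / f"gaze_{s.participant_id}.csv")
        session_io.write_frame_annotations(s.frames, out / f"frames_{s.participant_id}.tsv")
        session_io.write_trial_log(s.schedule, out / f"trials_{s.participant_id}.csv")
    cohort.truth.to_csv(out / "truth_oracle_only.csv", index=False)

    checksums = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.tsv"))
    }
    manifest = {
        "seed": cohort.spec.seed,
        "n_total": cohort.spec.n_total,
        "habituation_config": vars(cohort.config) if not isinstance(cohort.config, dict) else cohort.config,
        "cohort_spec": {
            k: v for k, v in vars(cohort.spec).items() if not hasattr(v, "__dict__")
        },
        "checksums": checksums,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def read_cohort(in_dir) -> list[LoadedSession]:
    """Load a written cohort directory back into analyzable sessions."""
    root = Path(in_dir)
    profiles = {p.participant_id: p for p in session_io.read_participants(root / "participants.csv")}
    sessions = []
    for pid, prof in profiles.items():
        schedule = session_io.read_trial_log(root / f"trials_{pid}.csv")
        gaze = session_io.read_gaze_stream(root / f"gaze_{pid}.csv")
        frames_path = root / f"frames_{pid}.tsv"
        frames = (
            session_io.read_frame_annotations(frames_path) if frames_path.exists() else None
        )
        sessions.append(
            LoadedSession(
                participant_id=pid,
                group=prof.group,
                age_days=prof.age_days,
                schedule=schedule,
                gaze=gaze,
                frames=frames,
            )
        )
    return sessions
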