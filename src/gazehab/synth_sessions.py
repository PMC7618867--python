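"""Synthetic infant sessions with known ground truth.

No raw infant data is distributable with this toolkit, so every downstream
module is exercised against generated sessions whose true looking behaviour
is known exactly. A session is built in three layers:

1. **Intended looking** — per-token looking time during habituation follows
   a geometrically decaying attention process, clip(lt0 * decay^(k-1) +
   noise, 0, token_s); test-phase tokens look at a base level, with an
   additive novelty increment on the switch phase for discriminators. The
   habituation criterion applied to this series fixes the number of
   habituation tokens actually presented (as the live system would).
2. **Eye-tracker channel** — gaze samples at the configured rate realise
   each token's intended looking as one contiguous look run from token
   onset; per-sample validity is dropped with probability ``track_loss_p``
   (track loss reads as NO-LOOK downstream).
3. **Frame channel** — the intended look runs quantized to the 40 ms frame
   grid, with optional integer-frame coder jitter on run ends.

A ``big_movement`` session reproduces the known failure signature of remote
eye-tracking with mobile toddlers: the child slumps or leans out of the
trackable box mid-habituation, gaze validity collapses from that point on
while the video/frame channel still captures real looking, the online
criterion fires early on the starved gaze signal, and test-phase gaze
looking drops to ~0 (so such sessions fail the 1 s test-looking rule and
disagree across channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .habituation_engine import (
    HabituationConfig,
    HabituationResult,
    recompute_habituation,
    schedule_session,
)
from .session_io import (
    LOOK,
    FrameAnnotation,
    GazeStream,
    ParticipantProfile,
    SessionSchedule,
    validate_annotations,
)

CLEAN = "clean"
NON_COMPLETER = "non_completer"
NON_HABITUATOR = "non_habituator"
LOW_LOOKER = "low_looker"

# plausible non-English languages of a diverse bilingual sample, none with
# retroflex consonants
_BILINGUAL_LANGUAGES = (
    "Spanish", "Italian", "French", "Polish", "Mandarin", "Cantonese",
    "Danish", "Dutch", "Greek", "Hebrew", "Hungarian", "Welsh", "Yoruba",
)


@dataclass(frozen=True)
class SynthParams:
    """Behavioural parameters of one synthetic session."""

    lt0_s: float = 0.95  # initial per-token looking
    decay: float = 0.88  # multiplicative per-token attention decay
    look_noise_sd_s: float = 0.01  # Gaussian noise on token looking
    novelty_effect: float = 0.0  # additive switch-phase increment, s/token
    test_lt_s: float = 0.5  # base test-phase looking, s/token
    track_loss_p: float = 0.0  # per-sample validity-loss probability
    coder_noise_frames: int = 0  # frame-channel jitter on look-run ends
    big_movement: bool = False
    big_movement_from_token: int = 7  # gaze validity lost from this token on
    rate_hz: float = 120.0
    frame_ms: float = 40.0
    ag_look_frac: float = 0.9  # fraction of AG/ISI spent looking
    frame_aligned: bool = False  # snap intended looks to the frame grid

    def __post_init__(self) -> None:
        for name in ("track_loss_p",):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not 0 < self.decay <= 1:
            raise ConfigError("decay must be in (0, 1]")
        if self.lt0_s < 0:
            raise ConfigError("lt0_s must be non-negative")
        if self.novelty_effect < 0:
            raise ConfigError("novelty_effect must be non-negative")


@dataclass
class SyntheticSession:
    participant_id: str
    group: str
    params: SynthParams
    schedule: SessionSchedule
    gaze: GazeStream
    frames: list[FrameAnnotation]
    completed: bool
    truth: dict


def _snap(v_ms: float, frame_ms: float) -> float:
    return round(v_ms / frame_ms) * frame_ms


def generate_session(
    params: SynthParams,
    config: HabituationConfig = HabituationConfig(),
    rng: np.random.Generator | int | None = None,
    participant_id: str = "p000",
    group: str = "monolingual",
    same_first: bool = True,
    truncate_after_tokens: int | None = None,
) -> SyntheticSession:
    """Generate one full session: gaze stream, frame channel, trial log, truth.

    ``truncate_after_tokens`` simulates a non-completer: the session ends
    after that many habituation tokens, before any test phase.
    """
    rng = np.random.default_rng(rng)
    token_ms = config.token_s * 1000.0

    def noisy(base: float, cap: float) -> float:
        lt = float(np.clip(base + rng.normal(0, params.look_noise_sd_s), 0, cap))
        if params.frame_aligned:
            lt = _snap(lt * 1000.0, params.frame_ms) / 1000.0
        return lt

    # intended (true) habituation-token looking
    true_token_lts = [
        noisy(params.lt0_s * params.decay ** (k - 1), config.token_s)
        for k in range(1, config.max_tokens + 1)
    ]
    truth_hab = recompute_habituation(true_token_lts, config)

    # One pool of per-sample track-loss draws covers the longest possible
    # session; the habituation phase is a timeline prefix, so the draws used
    # for the online decision below are exactly the ones the emitted stream
    # realizes — the live criterion decides on what the tracker measured,
    # not on the intended behaviour.
    dt = 1000.0 / params.rate_hz
    ag_ms = config.ag_s * 1000.0
    max_span = (
        2 * ag_ms
        + config.max_tokens * token_ms
        + 2 * config.isi_s * 1000.0
        + 2 * config.test_tokens * config.test_token_s * 1000.0
    )
    n_max = int(np.ceil(max_span / dt - 1e-9))
    loss_u = rng.random(n_max)
    t_all = np.arange(n_max) * dt

    def measured_token_lt(k: int) -> float:
        on = ag_ms + (k - 1) * token_ms
        i0 = int(np.searchsorted(t_all, on - 1e-9))
        i1 = int(np.searchsorted(t_all, on + token_ms - 1e-9))
        run_end = on + true_token_lts[k - 1] * 1000.0
        kept = (t_all[i0:i1] < run_end - 1e-9) & (loss_u[i0:i1] >= params.track_loss_p)
        return kept.sum() / params.rate_hz

    online_token_lts = [measured_token_lt(k) for k in range(1, config.max_tokens + 1)]
    if params.big_movement:
        for i in range(params.big_movement_from_token - 1, len(online_token_lts)):
            online_token_lts[i] = 0.0
    online_hab = recompute_habituation(online_token_lts, config)
    n_hab = online_hab.trial if online_hab.habituated else config.max_tokens

    if truncate_after_tokens is not None:
        n_hab = min(n_hab, max(1, truncate_after_tokens))
        completed = False
    else:
        completed = True

    schedule = schedule_session(config, n_hab, rng=rng, same_first=same_first)
    if not completed:
        events = [
            e
            for e in schedule.events
            if e.phase == "attention_getter" and e.token_index == 1
            or (e.phase == "habituation" and e.token_index <= n_hab)
        ]
        schedule = SessionSchedule(events, meta={**schedule.meta, "truncated": True})

    # per-event intended look runs (one contiguous look from event onset);
    # each run carries its event offset as a hard cap for coder jitter
    test_lts: dict[str, list[float]] = {"same": [], "switch": []}
    look_runs: list[tuple[float, float, float]] = []  # (start, end, cap), ms
    for ev in schedule.events:
        if ev.phase == "habituation":
            lt = true_token_lts[ev.token_index - 1]
        elif ev.phase in ("same", "switch"):
            base = params.test_lt_s + (
                params.novelty_effect if ev.phase == "switch" else 0.0
            )
            lt = noisy(base, config.test_token_s)
            test_lts[ev.phase].append(lt)
        else:  # attention-getter / ISI
            frac = params.ag_look_frac
            lt = (
                _snap(frac * ev.duration_ms, params.frame_ms) / 1000.0
                if params.frame_aligned
                else frac * ev.duration_ms / 1000.0
            )
        if lt > 0:
            look_runs.append((ev.onset_ms, ev.onset_ms + lt * 1000.0, ev.offset_ms))

    span_ms = schedule.span_ms

    # --- eye-tracker channel -------------------------------------------------
    n_samples = int(np.ceil(span_ms / dt - 1e-9))
    t = t_all[:n_samples]
    looking = np.zeros(n_samples, dtype=bool)
    for start, end, _cap in look_runs:
        i0 = int(np.searchsorted(t, start - 1e-9))
        i1 = i0 + int(np.count_nonzero(t[i0:] < end - 1e-9))
        looking[i0:i1] = True
    valid = looking & (loss_u[:n_samples] >= params.track_loss_p)
    if params.big_movement:
        hab_events = schedule.events_for("habituation")
        idx = min(params.big_movement_from_token, len(hab_events)) - 1
        lost_from = hab_events[idx].onset_ms
        valid &= t < lost_from
    x = np.where(valid, 0.5, np.nan)
    y = np.where(valid, 0.5, np.nan)
    gaze = GazeStream(
        samples=pd.DataFrame({"t_ms": t, "x": x, "y": y, "valid": valid}),
        rate_hz=params.rate_hz,
    )

    # --- frame channel -------------------------------------------------------
    frames: list[FrameAnnotation] = []
    fm = params.frame_ms
    for start, end, cap in look_runs:
        s = _snap(start, fm)
        e = _snap(end, fm)
        if params.coder_noise_frames:
            e += fm * rng.integers(
                -params.coder_noise_frames, params.coder_noise_frames + 1
            )
        e = min(e, np.floor(cap / fm + 1e-9) * fm, _snap(span_ms, fm))
        if e > s:
            frames.append(FrameAnnotation(s, e, LOOK))
    frames = validate_annotations(frames, frame_ms=fm)

    truth = {
        "token_lts": true_token_lts[:n_hab],
        "token_lts_full": true_token_lts,
        "habituation": truth_hab,
        "online_habituation": online_hab,
        "n_habituation_tokens": n_hab,
        "lt_same_s": float(sum(test_lts["same"])) if completed else float("nan"),
        "lt_switch_s": float(sum(test_lts["switch"])) if completed else float("nan"),
        "same_first": same_first,
    }
    return SyntheticSession(
        participant_id=participant_id,
        group=group,
        params=params,
        schedule=schedule,
        gaze=gaze,
        frames=frames,
        completed=completed,
        truth=truth,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Composition of a synthetic cohort.

    Category counts mirror the exclusion taxonomy of an infant habituation
    study: sessions that end before the test phase, sessions that never
    meet the habituation criterion, and sessions with under one second of
    test-phase looking. Remaining participants are clean. Groups alternate
    monolingual / bilingual; the switch-phase novelty increment is set per
    group so discriminator status is a designed property.
    """

    n_total: int = 95
    n_non_completers: int = 13
    n_non_habituators: int = 9
    n_low_lookers: int = 11
    n_big_movement: int = 0
    seed: int | None = None
    base_params: SynthParams = field(default_factory=lambda: SynthParams(track_loss_p=0.02))
    decay_range: tuple[float, float] = (0.87, 0.93)
    non_habituator_decay: float = 0.995
    low_looker_test_lt_s: float = 0.08
    truncate_after_tokens: int = 4
    novelty_effect_monolingual: float = 0.0
    novelty_effect_bilingual: float = 0.0
    age_days_range: tuple[int, int] = (459, 577)
    weekly_hours: float = 84.0  # waking hours of language exposure per week

    def __post_init__(self) -> None:
        designed = self.n_non_completers + self.n_non_habituators + self.n_low_lookers
        if designed + self.n_big_movement > self.n_total:
            raise ConfigError("designed category counts exceed the cohort size")


@dataclass
class Cohort:
    spec: CohortSpec
    config: HabituationConfig
    sessions: list[SyntheticSession]
    profiles: list[ParticipantProfile]
    truth: pd.DataFrame  # oracle-only ground-truth ledger


def generate_cohort(
    spec: CohortSpec, config: HabituationConfig = HabituationConfig()
) -> Cohort:
    """Generate a full cohort with a ground-truth category ledger."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_total
    categories = np.array([CLEAN] * n, dtype=object)
    order = rng.permutation(n)
    i = 0
    for cat, count in (
        (NON_COMPLETER, spec.n_non_completers),
        (NON_HABITUATOR, spec.n_non_habituators),
        (LOW_LOOKER, spec.n_low_lookers),
    ):
        categories[order[i : i + count]] = cat
        i += count
    big_movement = np.zeros(n, dtype=bool)
    big_movement[order[i : i + spec.n_big_movement]] = True

    sessions, profiles, truth_rows = [], [], []
    for idx in range(n):
        pid = f"p{idx:03d}"
        group = "monolingual" if idx % 2 == 0 else "bilingual"
        cat = categories[idx]
        novelty = (
            spec.novelty_effect_bilingual
            if group == "bilingual"
            else spec.novelty_effect_monolingual
        )
        params = replace(
            spec.base_params,
            decay=float(rng.uniform(*spec.decay_range)),
            novelty_effect=novelty,
        )
        truncate = None
        if cat == NON_HABITUATOR:
            params = replace(params, decay=spec.non_habituator_decay)
        elif cat == LOW_LOOKER:
            params = replace(params, test_lt_s=spec.low_looker_test_lt_s)
        elif cat == NON_COMPLETER:
            truncate = spec.truncate_after_tokens
        if big_movement[idx]:
            # force a mid-window true trial so the starved gaze channel
            # habituates earlier but still inside the inclusion window
            params = replace(params, big_movement=True, decay=0.93)

        session = generate_session(
            params,
            config,
            rng=rng,
            participant_id=pid,
            group=group,
            same_first=(idx % 2 == 0),
            truncate_after_tokens=truncate,
        )
        sessions.append(session)
        profiles.append(_make_profile(pid, group, spec, rng))
        th = session.truth
        truth_rows.append(
            {
                "participant_id": pid,
                "group": group,
                "category": cat,
                "big_movement": bool(big_movement[idx]),
                "true_habituation_trial": th["habituation"].trial,
                "online_habituation_trial": th["online_habituation"].trial,
                "lt_same_true_s": th["lt_same_s"],
                "lt_switch_true_s": th["lt_switch_s"],
                "novelty_effect": novelty,
            }
        )
    truth = pd.DataFrame(truth_rows)
    truth["true_habituation_trial"] = truth["true_habituation_trial"].astype("Int64")
    truth["online_habituation_trial"] = truth["online_habituation_trial"].astype("Int64")
    return Cohort(spec=spec, config=config, sessions=sessions, profiles=profiles, truth=truth)


def _make_profile(
    pid: str, group: str, spec: CohortSpec, rng: np.random.Generator
) -> ParticipantProfile:
    age = int(rng.integers(spec.age_days_range[0], spec.age_days_range[1] + 1))
    if group == "monolingual":
        return ParticipantProfile(
            participant_id=pid,
            group=group,
            age_days=age,
            exposure_hours={"English": spec.weekly_hours},
            mixing_items=[0.0] * 6,
        )
    other = str(rng.choice(_BILINGUAL_LANGUAGES))
    pct_en = float(rng.uniform(20, 80))
    hours_en = spec.weekly_hours * pct_en / 100.0
    return ParticipantProfile(
        participant_id=pid,
        group=group,
        age_days=age,
        exposure_hours={"English": hours_en, other: spec.weekly_hours - hours_en},
        mixing_items=[float(r) for r in rng.integers(0, 7, size=6)],
    )
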