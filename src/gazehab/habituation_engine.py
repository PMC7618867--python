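"""The online habituation-criterion state machine and its offline replay.

The paradigm presents 1 s habituation tokens while tracking per-token
looking time. Tokens are aggregated into non-overlapping windows of three;
starting at the sixth token and after every completed window thereafter, the
most recent window total is compared against the *peak* — the largest total
over all preceding windows. If the recent window falls to 60 % of the peak
or below, the infant is considered habituated and the session moves on to
the test phases. Sessions that reach the maximum token count (33 by default)
without meeting the criterion terminate non-habituated.

The criterion is a ratio of commensurate 3-token aggregates, so decisions
are invariant to rescaling all looking times by a positive constant, and it
is indifferent to whether totals or means are compared.

Because the online decision is irreversible in a live session, the same rule
is exposed as a pure offline replay (:func:`recompute_habituation`) so a
second measurement channel can audit it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError
from .session_io import SessionSchedule, TrialEvent

HABITUATED = "habituated"
NOT_HABITUATED = "not_habituated"  # reached max_tokens without habituating
INSUFFICIENT_DATA = "insufficient_data"  # sequence ended before first check
INCOMPLETE = "incomplete"  # sequence ended mid-run, after first check
RUNNING = "running"


@dataclass(frozen=True)
class HabituationConfig:
    """Parameters of the habituation criterion and trial schedule.

    window_tokens: tokens per aggregation window (3).
    first_check_token: earliest token at which the criterion is evaluated (6).
    criterion_ratio: habituate when recent window <= ratio * peak (0.60,
        i.e. a 40 % decrement from peak looking).
    min_habituation_trial / max_tokens: the 9-33 trial inclusion window; the
        engine enforces only max_tokens — the lower bound is an inclusion
        rule applied downstream, since the live criterion can fire at 6.
    token_s: token duration in seconds (1 s).
    sliding_peak: if True the peak is taken over every contiguous window of
        ``window_tokens`` tokens preceding the current window (sensitivity
        variant); default uses non-overlapping windows [1-3], [4-6], ...
    """

    window_tokens: int = 3
    first_check_token: int = 6
    criterion_ratio: float = 0.60
    min_habituation_trial: int = 9
    max_tokens: int = 33
    token_s: float = 1.0
    sliding_peak: bool = False
    ag_s: float = 12.0
    isi_s: float = 2.0
    test_tokens: int = 8
    test_token_s: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.criterion_ratio < 1:
            raise ConfigError("criterion_ratio must be in (0, 1)")
        if self.window_tokens < 1:
            raise ConfigError("window_tokens must be >= 1")
        if self.first_check_token < 2 * self.window_tokens:
            raise ConfigError("first_check_token must allow at least two windows")
        if self.max_tokens < self.first_check_token:
            raise ConfigError("max_tokens must be >= first_check_token")
        if self.token_s <= 0:
            raise ConfigError("token_s must be positive")


@dataclass(frozen=True)
class HabituationResult:
    habituated: bool
    trial: int | None
    status: str
    peak_window_lt_s: float
    window_totals: tuple[float, ...]


@dataclass
class HabituationState:
    """Running state of the online criterion."""

    config: HabituationConfig
    token_lts: list[float] = field(default_factory=list)
    window_totals: list[float] = field(default_factory=list)
    peak_window_lt_s: float = 0.0
    habituated: bool = False
    habituation_trial: int | None = None
    status: str = RUNNING

    @property
    def terminal(self) -> bool:
        return self.status in (HABITUATED, NOT_HABITUATED)

    def result(self) -> HabituationResult:
        status = self.status
        if status == RUNNING:
            status = (
                INSUFFICIENT_DATA
                if len(self.token_lts) < self.config.first_check_token
                else INCOMPLETE
            )
        return HabituationResult(
            habituated=self.habituated,
            trial=self.habituation_trial,
            status=status,
            peak_window_lt_s=self.peak_window_lt_s,
            window_totals=tuple(self.window_totals),
        )


def _peak_before_current(state: HabituationState) -> float:
    """Peak over windows preceding the window just completed.

    The window under test is excluded from the peak it is compared against —
    a window cannot habituate against itself when it is also the new peak.
    """
    cfg = state.config
    w = cfg.window_tokens
    n = len(state.token_lts)
    if cfg.sliding_peak:
        lts = state.token_lts
        # every contiguous w-token window ending at or before the current
        # window's start
        totals = [sum(lts[i : i + w]) for i in range(0, n - 2 * w + 1)]
        return max(totals)
    return max(state.window_totals[:-1])


def update(state: HabituationState, token_lt_s: float) -> HabituationState:
    """Feed one token's looking time into the online criterion.

    Mutates and returns ``state``. At each completed non-overlapping window
    from ``first_check_token`` onward, the criterion is evaluated; reaching
    ``max_tokens`` without habituation terminates the state non-habituated.
    """
    cfg = state.config
    if state.terminal:
        raise DataError("habituation state is terminal; no further tokens accepted")
    if not 0 <= token_lt_s <= cfg.token_s + 1e-9:
        raise DataError(
            f"token looking time {token_lt_s} s outside [0, {cfg.token_s}] s"
        )
    state.token_lts.append(float(token_lt_s))
    n = len(state.token_lts)

    if n % cfg.window_tokens == 0:
        total = float(sum(state.token_lts[-cfg.window_tokens :]))
        state.window_totals.append(total)
        if n >= cfg.first_check_token:
            peak = _peak_before_current(state)
            if total <= cfg.criterion_ratio * peak + 1e-12:
                state.habituated = True
                state.habituation_trial = n
                state.status = HABITUATED
        state.peak_window_lt_s = max(state.peak_window_lt_s, total)

    if not state.habituated and n >= cfg.max_tokens:
        state.status = NOT_HABITUATED
    return state


def recompute_habituation(
    per_token_lts, config: HabituationConfig = HabituationConfig()
) -> HabituationResult:
    """Pure-function offline replay of the online criterion.

    Applies the identical decision rule to a complete per-token looking-time
    sequence from any channel. A sequence that ends before the first check
    without habituating yields an ``insufficient_data`` marker.
    """
    state = HabituationState(config=config)
    for lt in per_token_lts:
        update(state, lt)
        if state.terminal:
            break
    return state.result()


def schedule_session(
    config: HabituationConfig,
    n_habituation_tokens: int,
    rng: np.random.Generator | int | None = None,
    same_first: bool = True,
) -> SessionSchedule:
    """Build the concrete timed schedule of a session.

    Structure: attention-getter (12 s) -> habituation tokens (1 s each) ->
    ISI (2 s) -> first test phase (8 x 1 s) -> ISI -> second test phase ->
    attention-getter. ``same_first`` controls which test phase comes first
    (counterbalanced across participants by the caller); the order of the
    eight stimulus variations within each test phase is drawn from ``rng``
    and recorded in the schedule metadata.
    """
    if not 1 <= n_habituation_tokens <= config.max_tokens:
        raise ConfigError(
            f"n_habituation_tokens must be in [1, {config.max_tokens}]"
        )
    rng = np.random.default_rng(rng)
    events: list[TrialEvent] = []
    t = 0.0

    def add(phase: str, token: int, dur_ms: float) -> None:
        nonlocal t
        events.append(TrialEvent(phase, token, t, dur_ms))
        t += dur_ms

    add("attention_getter", 1, config.ag_s * 1000)
    for k in range(1, n_habituation_tokens + 1):
        add("habituation", k, config.token_s * 1000)
    add("isi", 1, config.isi_s * 1000)
    phases = ("same", "switch") if same_first else ("switch", "same")
    variations = {}
    for phase in phases:
        variations[phase] = (rng.permutation(config.test_tokens) + 1).tolist()
        for k in range(1, config.test_tokens + 1):
            add(phase, k, config.test_token_s * 1000)
        if phase == phases[0]:
            add("isi", 2, config.isi_s * 1000)
    add("attention_getter", 2, config.ag_s * 1000)

    return SessionSchedule(
        events,
        meta={
            "same_first": same_first,
            "variation_order": variations,
        },
    )
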