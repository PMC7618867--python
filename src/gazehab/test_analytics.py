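"""Test-phase analytics: novelty preference, exclusions, analysis table.

After habituation to one token, looking time to a "same" phase (the
habituated token) and a "switch" phase (a novel contrastive token) is
compared. The novelty preference score

    (LT_switch - LT_same) / (LT_switch + LT_same)

standardises the switch/same difference for individual differences in
overall looking; a strictly positive score classifies the infant as a
potential discriminator of the contrast.

The exclusion ledger applies three rules in a fixed precedence — task
completion, habituation within the trial window (9-33 by default), and at
least one second of looking to each test phase — counting each participant
once under the first rule it fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .habituation_engine import HabituationConfig

EXCLUSION_REASONS = ("incomplete_task", "habituation_window", "low_test_looking")

RESULT_COLUMNS = [
    "participant_id",
    "group",
    "age_days",
    "completed",
    "habituation_trial",
    "habituation_status",
    "lt_same_s",
    "lt_switch_s",
    "novelty_score",
    "channel",
]


@dataclass(frozen=True)
class SessionResult:
    """Per-participant session summary on one measurement channel."""

    participant_id: str
    group: str
    age_days: int
    completed: bool
    habituation_trial: int | None
    habituation_status: str
    lt_same_s: float
    lt_switch_s: float
    channel: str = "eyetracker"

    @property
    def novelty_score(self) -> float:
        if not self.completed:
            return float("nan")
        return novelty_preference(self.lt_switch_s, self.lt_same_s)


def results_frame(results) -> pd.DataFrame:
    """Stack :class:`SessionResult` records into the canonical results table."""
    rows = []
    for r in results:
        rows.append(
            {
                "participant_id": r.participant_id,
                "group": r.group,
                "age_days": r.age_days,
                "completed": r.completed,
                "habituation_trial": r.habituation_trial,
                "habituation_status": r.habituation_status,
                "lt_same_s": r.lt_same_s,
                "lt_switch_s": r.lt_switch_s,
                "novelty_score": r.novelty_score,
                "channel": r.channel,
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df["habituation_trial"] = df["habituation_trial"].astype("Int64")
    return df


def novelty_preference(lt_switch_s: float, lt_same_s: float) -> float:
    """(switch - same) / (switch + same); NaN when both looking times are zero."""
    if lt_switch_s < 0 or lt_same_s < 0:
        raise DataError("looking times must be non-negative")
    total = lt_switch_s + lt_same_s
    if total <= 0:
        return float("nan")  # undefined; such a participant fails the 1 s rule anyway
    return (lt_switch_s - lt_same_s) / total


def classify_discriminator(score: float) -> bool | None:
    """True iff the novelty score is strictly greater than zero.

    A score of exactly zero (equal looking) is a non-discriminator; an
    undefined (NaN) score cannot be classified and returns None.
    """
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return None
    return score > 0


@dataclass(frozen=True)
class ExclusionConfig:
    min_habituation_trial: int = 9
    max_habituation_trial: int = 33
    min_test_looking_s: float = 1.0

    @classmethod
    def from_habituation(cls, cfg: HabituationConfig) -> "ExclusionConfig":
        return cls(
            min_habituation_trial=cfg.min_habituation_trial,
            max_habituation_trial=cfg.max_tokens,
        )


def apply_exclusions(
    results: pd.DataFrame, config: ExclusionConfig = ExclusionConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the inclusion ledger and per-reason summary counts.

    Returns ``(ledger, summary)``. The ledger has one row per participant
    with the three boolean flags, the overall ``included`` flag (their
    conjunction) and ``exclusion_reason`` — the first failing rule in the
    precedence completion -> habituation window -> test looking.
    """
    required = {"participant_id", "completed", "habituation_trial", "lt_same_s", "lt_switch_s"}
    missing_cols = required - set(results.columns)
    if missing_cols:
        raise DataError(f"results table missing column(s) {sorted(missing_cols)}")
    for col in ("completed",):
        bad = results[results[col].isna()]
        if len(bad):
            raise DataError(
                f"participant {bad['participant_id'].iloc[0]} missing field {col!r}"
            )

    trial = pd.to_numeric(results["habituation_trial"], errors="coerce")
    completed = results["completed"].astype(bool)
    habituated_in_window = (
        trial.notna()
        & (trial >= config.min_habituation_trial)
        & (trial <= config.max_habituation_trial)
    )
    lt_same = results["lt_same_s"].fillna(0.0)
    lt_switch = results["lt_switch_s"].fillna(0.0)
    sufficient = (lt_same >= config.min_test_looking_s) & (
        lt_switch >= config.min_test_looking_s
    )

    reason = np.select(
        [~completed, ~habituated_in_window, ~sufficient],
        list(EXCLUSION_REASONS),
        default="",
    )
    ledger = pd.DataFrame(
        {
            "participant_id": results["participant_id"],
            "completed_task": completed,
            "habituated_in_window": habituated_in_window,
            "sufficient_test_looking": sufficient,
            "included": completed & habituated_in_window & sufficient,
            "exclusion_reason": reason,
        }
    )
    if "group" in results.columns:
        ledger.insert(1, "group", results["group"])

    counts = []
    for r in EXCLUSION_REASONS:
        sub = ledger[ledger["exclusion_reason"] == r]
        row = {"reason": r, "n_excluded": len(sub)}
        if "group" in ledger.columns:
            for g, c in sub.groupby("group").size().items():
                row[f"n_{g}"] = int(c)
        counts.append(row)
    counts.append({"reason": "included", "n_excluded": int(ledger["included"].sum())})
    summary = pd.DataFrame(counts).fillna(0)
    return ledger, summary


def build_analysis_table(
    results: pd.DataFrame, profiles: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Long-format table for external mixed-model fitting.

    Two rows per (included) participant — one per test phase — with columns
    participant_id, group, age_days, trial (same|switch) and lt_s. Age stays
    in days, continuous.
    """
    df = results
    if profiles is not None:
        keep = [c for c in ("participant_id", "group", "age_days") if c in profiles.columns]
        df = df.drop(columns=[c for c in ("group", "age_days") if c in df.columns]).merge(
            profiles[keep], on="participant_id", how="left", validate="one_to_one"
        )
    missing = df[df["lt_same_s"].isna() | df["lt_switch_s"].isna()]
    if len(missing):
        raise DataError(
            f"participant {missing['participant_id'].iloc[0]} is missing a test "
            "phase; it should have been excluded before table construction"
        )
    long = df.melt(
        id_vars=["participant_id", "group", "age_days"],
        value_vars=["lt_same_s", "lt_switch_s"],
        var_name="trial",
        value_name="lt_s",
    )
    long["trial"] = long["trial"].map({"lt_same_s": "same", "lt_switch_s": "switch"})
    return long.sort_values(["participant_id", "trial"]).reset_index(drop=True)
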