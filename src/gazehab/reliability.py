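"""Dual-channel measurement agreement.

Every session yields two looking-time measurements per phase: one coded
online by the eye-tracker and one coded offline frame-by-frame from video.
This module quantifies their agreement — Pearson correlation of paired
looking times, flagging of unusually large disagreements (more than k
standard deviations above the mean difference, one-sided by default), and
concordance of the habituation-trial decision recomputed on each channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .habituation_engine import HabituationConfig


@dataclass
class PairedChannels:
    """Inner join of two channels on (participant, phase) keys.

    ``pairs`` carries ``lt_a_s``, ``lt_b_s`` and ``diff_s = lt_b_s - lt_a_s``
    (conventionally frames minus eye-tracker). Keys present in only one
    channel are reported in ``unmatched``, never silently dropped.
    """

    pairs: pd.DataFrame
    unmatched: pd.DataFrame


def pair_channels(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    keys: tuple[str, ...] = ("participant_id", "phase"),
) -> PairedChannels:
    """Pair per-phase looking times from two channels by key columns.

    Each input needs the key columns plus ``lt_s``. Duplicate keys within a
    channel are a data error.
    """
    for name, df in (("A", results_a), ("B", results_b)):
        missing = (set(keys) | {"lt_s"}) - set(df.columns)
        if missing:
            raise DataError(f"channel {name} missing column(s) {sorted(missing)}")
        if df.duplicated(subset=list(keys)).any():
            raise DataError(f"channel {name} has duplicate keys")
    a = results_a[list(keys) + ["lt_s"]].rename(columns={"lt_s": "lt_a_s"})
    b = results_b[list(keys) + ["lt_s"]].rename(columns={"lt_s": "lt_b_s"})
    merged = a.merge(b, on=list(keys), how="outer", indicator=True)
    pairs = merged[merged["_merge"] == "both"].drop(columns="_merge").reset_index(drop=True)
    unmatched = (
        merged[merged["_merge"] != "both"]
        .rename(columns={"_merge": "present_in"})
        .reset_index(drop=True)
    )
    unmatched["present_in"] = unmatched["present_in"].astype(str).map(
        {"left_only": "A", "right_only": "B"}
    )
    pairs["diff_s"] = pairs["lt_b_s"] - pairs["lt_a_s"]
    return PairedChannels(pairs=pairs, unmatched=unmatched)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.r)


def channel_correlation(pairs: pd.DataFrame) -> CorrelationResult:
    """Pearson product-moment correlation of the paired looking times."""
    if len(pairs) < 3:
        raise DataError("need at least 3 pairs for a correlation")
    a = pairs["lt_a_s"].to_numpy(float)
    b = pairs["lt_b_s"].to_numpy(float)
    # a channel constant up to floating-point noise has no defined correlation
    for v in (a, b):
        if np.std(v) <= 1e-12 * max(1.0, float(np.abs(v).max(initial=0.0))):
            return CorrelationResult(float("nan"), float("nan"), len(pairs))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        r, p = stats.pearsonr(a, b)
    return CorrelationResult(float(r), float(p), len(pairs))


def flag_disagreements(
    pairs: pd.DataFrame, k_sd: float = 2.0, two_sided: bool = False
) -> pd.DataFrame:
    """Flag pairs whose difference exceeds mean(diff) + k_sd * sd(diff).

    One-sided above the mean by default (large positive differences are the
    signature of the frame channel capturing looking the eye-tracker lost);
    ``two_sided=True`` flags on |diff - mean| instead.
    """
    if k_sd <= 0:
        raise ConfigError("k_sd must be positive")
    if len(pairs) < 2:
        raise DataError("need at least 2 pairs to estimate the difference spread")
    d = pairs["diff_s"].to_numpy(float)
    mu, sd = d.mean(), d.std(ddof=1)
    if two_sided:
        mask = np.abs(d - mu) > k_sd * sd
    else:
        mask = d - mu > k_sd * sd
    return pairs[mask].reset_index(drop=True)


def habituation_agreement(
    online_trials: pd.Series | dict,
    offline_trials: pd.Series | dict,
    config_online: HabituationConfig | None = None,
    config_offline: HabituationConfig | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-participant concordance of the habituation-trial decision.

    ``online_trials`` / ``offline_trials`` map participant id to the
    habituation trial (None/NaN for non-habituated). Both must have been
    computed with the same criterion configuration; passing two differing
    configs is a configuration error. Returns the per-participant table and
    the overall agreement proportion.
    """
    if config_online is not None and config_offline is not None:
        if config_online != config_offline:
            raise ConfigError("habituation configs differ between channels")
    on = pd.Series(online_trials, name="online_trial")
    off = pd.Series(offline_trials, name="offline_trial")
    df = pd.concat([on, off], axis=1)
    df.index.name = "participant_id"
    df = df.reset_index()
    both_missing = df["online_trial"].isna() & df["offline_trial"].isna()
    df["match"] = (df["online_trial"] == df["offline_trial"]) | both_missing
    rate = float(df["match"].mean()) if len(df) else float("nan")
    return df, rate
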