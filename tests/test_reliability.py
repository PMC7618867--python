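"""Dual-channel agreement: correlation, disagreement flags, habituation concordance."""

import numpy as np
import pandas as pd
import pytest

from gazehab.errors import ConfigError, DataError
from gazehab.habituation_engine import HabituationConfig
from gazehab.pipeline import reliability_report
from gazehab.reliability import (
    channel_correlation,
    flag_disagreements,
    habituation_agreement,
    pair_channels,
)
from gazehab.synth_sessions import CohortSpec, SynthParams, generate_cohort


def channel(pids, lts, phase="same"):
    return pd.DataFrame({"participant_id": pids, "phase": phase, "lt_s": lts})


class TestPairChannels:
    def test_identical_channels_have_zero_diffs(self):
        a = channel(["p0", "p1", "p2"], [1.0, 2.0, 3.0])
        paired = pair_channels(a, a.copy())
        assert (paired.pairs["diff_s"] == 0).all()
        assert len(paired.unmatched) == 0

    def test_missing_participant_reported_not_dropped(self):
        a = channel(["p0", "p1"], [1.0, 2.0])
        b = channel(["p0"], [1.1])
        paired = pair_channels(a, b)
        assert len(paired.pairs) == 1
        assert len(paired.unmatched) == 1
        assert paired.unmatched["participant_id"].iloc[0] == "p1"

    def test_duplicate_keys_rejected(self):
        a = channel(["p0", "p0"], [1.0, 2.0])
        with pytest.raises(DataError):
            pair_channels(a, a)

    def test_cohort_pair_count_is_size_times_phases(self, noiseless_params):
        spec = CohortSpec(
            n_total=10, n_non_completers=0, n_non_habituators=0, n_low_lookers=0,
            seed=2, base_params=noiseless_params,
        )
        cohort = generate_cohort(spec)
        rep = reliability_report(cohort.sessions, cohort.config)
        assert len(rep["pairs"]) == 20  # 10 participants x 2 test phases


class TestCorrelation:
    def test_identical_channels_give_r_one(self, rng):
        lts = rng.uniform(1, 5, 30)
        a = channel([f"p{i}" for i in range(30)], lts)
        paired = pair_channels(a, a.copy())
        assert channel_correlation(paired.pairs).r == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        lts = rng.uniform(1, 5, 30)
        pids = [f"p{i}" for i in range(30)]
        paired = pair_channels(channel(pids, lts), channel(pids, 2 * lts + 1))
        assert channel_correlation(paired.pairs).r == pytest.approx(1.0)

    def test_attenuation_matches_closed_form(self, rng):
        """Adding Gaussian noise of known sd to one channel attenuates r to
        sqrt(var_A / (var_A + sd^2)), within a Fisher-z 95 % band."""
        n, sd = 500, 0.5
        a_vals = rng.uniform(0, 4, n)  # var = 16/12
        b_vals = a_vals + rng.normal(0, sd, n)
        pids = [f"p{i}" for i in range(n)]
        paired = pair_channels(channel(pids, a_vals), channel(pids, b_vals))
        r = channel_correlation(paired.pairs).r
        var_a = np.var(a_vals)
        expected = np.sqrt(var_a / (var_a + sd**2))
        z, z0 = np.arctanh(r), np.arctanh(expected)
        assert abs(z - z0) < 1.96 / np.sqrt(n - 3)

    def test_zero_variance_is_undefined(self):
        a = channel(["p0", "p1", "p2"], [2.0, 2.0, 2.0])
        paired = pair_channels(a, a.copy())
        assert not channel_correlation(paired.pairs).defined

    def test_too_few_pairs_rejected(self):
        a = channel(["p0", "p1"], [1.0, 2.0])
        with pytest.raises(DataError):
            channel_correlation(pair_channels(a, a.copy()).pairs)


class TestFlags:
    def test_equal_diffs_flag_nothing(self):
        a = channel([f"p{i}" for i in range(5)], [1.0] * 5)
        b = channel([f"p{i}" for i in range(5)], [1.5] * 5)
        assert len(flag_disagreements(pair_channels(a, b).pairs)) == 0

    def test_single_outlier_flagged(self, rng):
        pids = [f"p{i}" for i in range(50)]
        a_vals = rng.uniform(1, 5, 50)
        b_vals = a_vals + rng.normal(0, 0.01, 50)
        b_vals[17] += 4.0
        flags = flag_disagreements(
            pair_channels(channel(pids, a_vals), channel(pids, b_vals)).pairs
        )
        assert flags["participant_id"].tolist() == ["p17"]

    def test_flag_count_non_increasing_in_k(self, rng):
        pids = [f"p{i}" for i in range(60)]
        a_vals = rng.uniform(1, 5, 60)
        b_vals = a_vals + rng.normal(0, 0.5, 60)
        pairs = pair_channels(channel(pids, a_vals), channel(pids, b_vals)).pairs
        counts = [len(flag_disagreements(pairs, k_sd=k)) for k in (0.5, 1, 2, 3)]
        assert counts == sorted(counts, reverse=True)

    def test_big_movement_sessions_flagged_exactly(self, noiseless_params):
        """Injected large-movement sessions — gaze starved mid-session while
        frame coding keeps capturing looks — are exactly the flagged ones."""
        spec = CohortSpec(
            n_total=40, n_non_completers=0, n_non_habituators=0, n_low_lookers=0,
            n_big_movement=4, seed=11, base_params=noiseless_params,
        )
        cohort = generate_cohort(spec)
        rep = reliability_report(cohort.sessions, cohort.config)
        truth_bm = set(cohort.truth[cohort.truth["big_movement"]]["participant_id"])
        assert set(rep["flags"]["participant_id"]) == truth_bm


class TestHabituationAgreement:
    def test_identical_series_agree_fully(self):
        trials = {"p0": 9, "p1": 12, "p2": None}
        _, rate = habituation_agreement(trials, dict(trials))
        assert rate == 1.0

    def test_config_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            habituation_agreement(
                {"p0": 9}, {"p0": 9},
                HabituationConfig(), HabituationConfig(criterion_ratio=0.5),
            )

    def test_big_movement_sessions_are_the_disagreements(self, noiseless_params):
        spec = CohortSpec(
            n_total=40, n_non_completers=0, n_non_habituators=0, n_low_lookers=0,
            n_big_movement=4, seed=11, base_params=noiseless_params,
        )
        cohort = generate_cohort(spec)
        rep = reliability_report(cohort.sessions, cohort.config)
        disagree = set(rep["agreement"][~rep["agreement"]["match"]]["participant_id"])
        truth_bm = set(cohort.truth[cohort.truth["big_movement"]]["participant_id"])
        assert disagree == truth_bm


class TestNoiseLimits:
    def test_vanishing_noise_drives_r_and_agreement_to_one(self, noiseless_params):
        """Across a coder-noise grid, correlation and habituation agreement
        approach 1 as the noise vanishes, and are exactly 1 without noise."""
        from dataclasses import replace

        rs, agreements = [], []
        for noise in (0, 2, 5):
            # behavioural looking noise gives across-participant variance
            # (otherwise r is undefined); frame-aligned looks keep the two
            # channels exactly equal when the coder noise is zero
            params = replace(
                noiseless_params, look_noise_sd_s=0.01, coder_noise_frames=noise
            )
            spec = CohortSpec(
                n_total=24, n_non_completers=0, n_non_habituators=0, n_low_lookers=0,
                seed=5, base_params=params,
            )
            cohort = generate_cohort(spec)
            rep = reliability_report(cohort.sessions, cohort.config)
            rs.append(rep["correlation"].r)
            agreements.append(rep["agreement_rate"])
        assert rs[0] == pytest.approx(1.0, abs=1e-12)
        assert agreements[0] == 1.0
        assert rs[0] >= rs[1] >= rs[2]
        assert agreements[0] >= agreements[2]
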