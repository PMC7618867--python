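"""Generator ground truth, determinism, and parameter recovery."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gazehab.errors import ConfigError
from gazehab.pipeline import analyze_sessions, summarize_session
from gazehab.synth_sessions import (
    CLEAN,
    LOW_LOOKER,
    NON_COMPLETER,
    NON_HABITUATOR,
    CohortSpec,
    SynthParams,
    generate_cohort,
    generate_session,
)
from gazehab.test_analytics import novelty_preference


class TestGenerateSession:
    def test_noiseless_channels_reproduce_true_token_lts(self, config, noiseless_params):
        session = generate_session(noiseless_params, config, rng=3)
        for channel in ("eyetracker", "frames"):
            res = summarize_session(session, config, channel)
            assert res.habituation_trial == session.truth["habituation"].trial

    def test_decay_near_one_never_habituates(self, config, noiseless_params):
        params = replace(noiseless_params, decay=0.999, look_noise_sd_s=0.0)
        session = generate_session(params, config, rng=0)
        assert not session.truth["habituation"].habituated
        assert session.truth["n_habituation_tokens"] == config.max_tokens

    def test_fast_decay_matches_closed_form_trial(self, config, noiseless_params):
        """With zero noise the habituation trial is computable by hand from
        the geometric series."""
        params = replace(noiseless_params, decay=0.7, look_noise_sd_s=0.0, frame_aligned=False)
        session = generate_session(params, config, rng=0)
        lts = [params.lt0_s * params.decay ** (k - 1) for k in range(1, config.max_tokens + 1)]
        # brute-force the criterion on non-overlapping 3-token windows
        trial = None
        for t in range(config.first_check_token, config.max_tokens + 1, config.window_tokens):
            cur = sum(lts[t - 3 : t])
            peak = max(
                sum(lts[s - 3 : s]) for s in range(3, t - 2, 3)
            )
            if cur <= config.criterion_ratio * peak:
                trial = t
                break
        assert session.truth["habituation"].trial == trial

    def test_truncated_session_has_no_test_phase(self, config, noiseless_params):
        session = generate_session(
            noiseless_params, config, rng=1, truncate_after_tokens=4
        )
        assert not session.completed
        assert not session.schedule.has_phase("same")
        assert len(session.schedule.events_for("habituation")) == 4

    def test_online_decision_matches_analyzer_replay_under_track_loss(self, config):
        """The live criterion fires on what the tracker measured, so the
        analyzer's offline replay on the emitted gaze stream reaches the
        same trial — even with track loss."""
        params = SynthParams(track_loss_p=0.05)
        for seed in range(10):
            session = generate_session(params, config, rng=seed)
            res = summarize_session(session, config, "eyetracker")
            assert res.habituation_trial == session.truth["online_habituation"].trial

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigError):
            SynthParams(track_loss_p=1.5)
        with pytest.raises(ConfigError):
            SynthParams(decay=0.0)


class TestGenerateCohort:
    def test_seed_gives_bit_identical_cohorts(self):
        spec = CohortSpec(n_total=12, n_non_completers=2, n_non_habituators=2,
                          n_low_lookers=2, seed=9)
        a, b = generate_cohort(spec), generate_cohort(spec)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        for sa, sb in zip(a.sessions, b.sessions):
            pd.testing.assert_frame_equal(sa.gaze.samples, sb.gaze.samples)
            assert sa.frames == sb.frames
            assert sa.schedule.events == sb.schedule.events

    def test_infeasible_mixture_rejected(self):
        with pytest.raises(ConfigError):
            CohortSpec(n_total=10, n_non_completers=5, n_non_habituators=5,
                       n_low_lookers=5)

    def test_profiles_are_well_formed(self):
        spec = CohortSpec(n_total=20, n_non_completers=0, n_non_habituators=0,
                          n_low_lookers=0, seed=4)
        cohort = generate_cohort(spec)
        for p in cohort.profiles:
            total = sum(p.exposure_hours.values())
            assert total == pytest.approx(spec.weekly_hours)
            if p.group == "bilingual":
                pcts = [100 * h / total for h in p.exposure_hours.values()]
                assert all(20 <= v <= 80 for v in pcts)
                assert 0 <= sum(p.mixing_items) <= 36
            else:
                assert list(p.exposure_hours) == ["English"]

    def test_exclusion_category_recovery(self, config, exclusion_mixture_cohort):
        """The analyzer recovers each designed category: the included set is
        exactly the clean participants, and each excluded participant falls
        under the reason matching its designed failure mode."""
        cohort = exclusion_mixture_cohort
        analysis = analyze_sessions(cohort.sessions, config)
        merged = analysis.ledger.merge(
            cohort.truth[["participant_id", "category"]], on="participant_id"
        )
        by_cat = merged.groupby("category")
        assert by_cat["included"].all()[CLEAN]
        reason = merged.set_index("participant_id")["exclusion_reason"]
        cat = merged.set_index("participant_id")["category"]
        assert (reason[cat == NON_COMPLETER] == "incomplete_task").all()
        assert (reason[cat == NON_HABITUATOR] == "habituation_window").all()
        assert (reason[cat == LOW_LOOKER] == "low_test_looking").all()


class TestParameterRecovery:
    def test_novelty_effect_separates_groups(self, config):
        """Cohorts generated with a positive bilingual novelty effect and a
        zero monolingual effect separate in mean novelty score (p < .01 over
        200 simulated participants); the null group's mean is ~0."""
        spec = CohortSpec(
            n_total=200, n_non_completers=0, n_non_habituators=0, n_low_lookers=0,
            novelty_effect_bilingual=0.15, novelty_effect_monolingual=0.0, seed=21,
        )
        cohort = generate_cohort(spec, config)
        analysis = analyze_sessions(cohort.sessions, config)
        res = analysis.results
        scores = {
            g: res[res["group"] == g].apply(
                lambda r: novelty_preference(r["lt_switch_s"], r["lt_same_s"]), axis=1
            )
            for g in ("bilingual", "monolingual")
        }
        t = stats.ttest_ind(scores["bilingual"], scores["monolingual"])
        assert t.pvalue < 0.01
        assert scores["bilingual"].mean() > scores["monolingual"].mean()
        null_se = scores["monolingual"].std() / np.sqrt(len(scores["monolingual"]))
        assert abs(scores["monolingual"].mean()) < 3 * null_se

    def test_mean_novelty_monotone_in_effect(self, config):
        means = []
        for effect in (0.0, 0.1, 0.25):
            spec = CohortSpec(
                n_total=60, n_non_completers=0, n_non_habituators=0, n_low_lookers=0,
                novelty_effect_bilingual=effect, novelty_effect_monolingual=effect,
                seed=33,
            )
            cohort = generate_cohort(spec, config)
            res = analyze_sessions(cohort.sessions, config).results
            means.append(
                res.apply(
                    lambda r: novelty_preference(r["lt_switch_s"], r["lt_same_s"]),
                    axis=1,
                ).mean()
            )
        assert means == sorted(means)
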