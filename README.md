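# gazehab

Analysis toolkit for infant visual-habituation "switch" experiments with
dual-channel looking-time measurement.

## The scientific problem

In a habituation–switch study an infant watches a repeating audiovisual
token (for example a word–object pairing) until their looking wanes, then
is tested with a *same* trial (the habituated pairing) and a *switch*
trial (a novel pairing). Longer looking to the switch trial indicates the
infant discriminates the two stimuli. Running and analyzing such a study
requires several pieces of careful machinery:

- **Gaze-contingent habituation.** The live system decides, token by
  token, whether looking has dropped to a criterion fraction of its peak
  — here, whether the most recent non-overlapping 3-token window totals
  at most 60 % of the peak window before it, checked at tokens 6, 9, 12,
  …, 33. The decision is irreversible, so the offline analysis must be
  able to replay it exactly.
- **Two measurement channels.** Looking time comes both from an eye
  tracker (per-sample gaze validity and position inside an area of
  interest) and from frame-by-frame human coding of session video (40 ms
  LOOK / NO-LOOK frames). The channels must be coded with the same rules,
  compared by correlation, and screened for large disagreements — the
  classic failure mode being a large body movement that starves the eye
  tracker while the video still shows real looking.
- **Principled exclusions.** Sessions that end early, habituate outside
  the 9–33-token window, or show under one second of looking to a test
  phase are excluded, in that order of precedence, with every decision
  recorded in a ledger.
- **Design statistics.** Effect sizes chain from a reported interaction F
  statistic (partial eta-squared, then Cohen's f), and power for the
  2 (group) × 2 (test phase) interaction is available both in closed form
  (noncentral F) and by Monte-Carlo simulation.
- **Bilingual language profiles.** Degree of bilingualism
  (min/max exposure share), parental language-mixing scores, and
  eligibility screening on exposure balance.

No infant data ships with the package. A synthetic-session generator with
exact ground truth stands in for raw data everywhere: it produces gaze
streams, frame annotations, trial logs and participant profiles whose
true habituation trials, looking times and designed failure modes are
known, so every pipeline stage can be validated oracle-style.

## The generative model

Per-token habituation looking decays geometrically,
`clip(lt0 · decay^(k−1) + ε, 0, token_s)` with Gaussian ε; test-phase
tokens look at a base level plus an additive novelty increment on switch
trials. The eye-tracker channel realizes each token's looking as a
contiguous gaze run sampled at the tracker rate, with per-sample track
loss; the frame channel is the same runs snapped to the 40 ms grid with
optional integer-frame coder jitter. Crucially, the **online habituation
decision is made on the measured gaze signal** (after sampling and track
loss), exactly as a live system would, so the analyzer's offline replay of
the emitted stream reproduces the decision by construction. Designed
failure modes — early termination, near-flat decay, low test looking, and
mid-session tracker starvation ("big movement") — generate the exclusion
and reliability signatures the pipeline must catch.

## Worked example

Command line — simulate a cohort, analyze it, check channel reliability:

```bash
$ gazehab simulate --out demo/cohort --seed 11 --n-total 24 \
    --n-non-completers 3 --n-non-habituators 2 --n-low-lookers 3
wrote 24 sessions to demo/cohort (74 files)

$ gazehab analyze --in demo/cohort --out demo/analysis
24 sessions -> 16 included, 9 potential discriminators

$ gazehab reliability --in demo/cohort --out demo/rel
r = 0.999 over 42 pairs; 1 flagged; habituation agreement 91.67%
```

`demo/analysis/ledger.csv` then holds the per-participant exclusion
ledger:

```
participant_id,group,completed_task,habituated_in_window,sufficient_test_looking,included,exclusion_reason
p000,monolingual,True,True,True,True,
p001,bilingual,True,True,True,True,
p002,monolingual,True,False,True,False,habituation_window
p003,bilingual,True,True,True,True,
p004,monolingual,False,False,False,False,incomplete_task
```

Python API — the effect-size/power chain and core metrics:

```python
>>> from gazehab import EffectSize, PowerSpec, simulate_power
>>> es = EffectSize.from_f_statistic(6.27, 1, 42)
>>> print(f"eta_p^2 = {es.eta_p_sq:.4f}, f = {es.f:.4f}")
eta_p^2 = 0.1299, f = 0.3864

>>> est = simulate_power(PowerSpec(f=0.39, n_total=37, seed=7))
>>> print(f"power = {est.power:.1%} +/- {est.mc_se:.1%} (analytic {est.analytic:.1%})")
power = 89.6% +/- 1.0% (analytic 90.3%)

>>> from gazehab import degree_of_bilingualism, recompute_habituation
>>> round(degree_of_bilingualism({"English": 30, "Spanish": 70}), 2)
0.43
>>> res = recompute_habituation([0.95, 0.90, 0.88, 0.70, 0.62, 0.55, 0.40, 0.33, 0.28])
>>> print(f"habituated={res.habituated} at trial {res.trial}")
habituated=True at trial 9
```

## Package layout

| Module | Purpose |
| --- | --- |
| `gazehab.session_io` | Readers/writers and validation for gaze streams, frame annotations, trial logs, participant profiles |
| `gazehab.look_coder` | LOOK/NO-LOOK coding of both channels; exact windowed looking times |
| `gazehab.habituation_engine` | Online habituation criterion, offline replay, session scheduling |
| `gazehab.test_analytics` | Novelty preference, discriminator classification, exclusion ledger, long-format analysis table |
| `gazehab.reliability` | Channel pairing, Pearson correlation, disagreement flags, habituation concordance |
| `gazehab.language_metrics` | Exposure percentages, degree of bilingualism, mixing score, eligibility |
| `gazehab.power_tools` | Effect-size chain, analytic and simulated power, recruitment targets |
| `gazehab.synth_sessions` | Ground-truth session and cohort generator |
| `gazehab.pipeline` | End-to-end cohort analysis and cohort file exchange |
| `gazehab.cli` | `gazehab simulate / analyze / reliability / power` |

See `docs/methods.md` for the statistical model, parameter conventions and
numerical choices.
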