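# sdtkernels

Bayes-rational observer models and reverse-correlation kernel analysis for
perceptual **detection** ("is a signal present?") and **discrimination**
("which of two channels carries the signal?"), with a synthetic-experiment
generator so the whole pipeline is testable end to end without human data.

## The scientific problem

When people discriminate between two alternatives, their confidence is
driven more by evidence *for* the chosen alternative than by evidence
*against* it — equivalently, confidence increases with the **sum** of
evidence across both channels, even though only the **difference** is
task-relevant. This *positive evidence bias* (PEB) can be probed with
psychophysical reverse correlation: split trials by accuracy or by the
median confidence rating, and ask how the random stimulus fluctuations
differ between the cells.

This package implements:

- **Four ideal observers** that watch two noisy channels *E₁, E₂* over
  *T* = 12 time steps (signal evidence ~ 𝒩(0.5, 1), noise ~ 𝒩(0, 1)),
  accumulate log-likelihoods for the elementary hypotheses
  {signal-in-1, signal-in-2, absent} under full generative knowledge,
  report the maximum-likelihood world state, and rate confidence as the
  posterior probability of being correct:
  - `vanilla` — additive Gaussian sensory noise 𝒩(0, 2) on both channels;
  - `firing_rate` — percepts are Poisson counts with rate
    λ(E) = exp(2 + E), so stronger stimuli are noisier (Weber–Fechner);
  - `random_attention` — one channel per time step, a trial-preferred
    channel attended with probability 0.95;
  - `goal_directed` — one channel per time step, P(attend right) =
    σ(5 · LLR_r) where LLR_r is the running log-likelihood ratio for
    signal-in-right vs signal-in-left.
- **Reverse-correlation kernels.** With ⟨·⟩_c a conditional cell mean of
  the (mean-centred) evidence, e.g.

  E_relative = ⟨E_s − E_n⟩_CORRECT − ⟨E_s − E_n⟩_INCORRECT
  E_conf-chosen = ⟨E_chosen⟩_HIGH − ⟨E_chosen⟩_LOW

  plus the analogous sum composites, detection kernels conditioned on
  yes/no responses (signal-present trials only), and detection confidence
  kernels computed within each response category. Per-subject values are
  tested against zero with one-sample t-tests.
- **A synthetic experiment generator** emulating luminance-flicker
  sessions (two 4-bar patches, 12 frames at 25 Hz, background 128/255,
  signal 133/255, bar SD 10/255, optional +2/255 sum-evidence boost) and
  hue-flicker sessions (angles on a CIE L\*a\*b\* hue circle of radius 49,
  nontarget mean 1.85 rad, target 2.1 rad, SD 0.35 rad), a block-wise
  3 %-step staircase, and configurable observers — including a
  `weighted_heuristic` observer with injectable evidence weights for
  validating that the pipeline recovers known weighting patterns.
- **Behavioral metrics**: response bias, confidence by response,
  response-conditional type-2 ROC AUC, evidence-boost contrasts, and
  cross-task correlations of per-subject kernel amplitudes.

## Worked example

```python
import sdtkernels as sk

for model in ("vanilla", "firing_rate"):
    cfg = sk.AgentConfig(model=model)
    table = sk.simulate_campaign(cfg, "discrimination", n_agents=100, n_trials=100, seed=11)
    kernels = sk.compute_kernels(table, "discrimination")
    print(f"-- {model}")
    for name in ("relative", "sum", "conf_chosen", "conf_unchosen", "conf_sum"):
        s = kernels[name].group_stats()
        print(f"  {name:14s} mean={s.mean:+.4f}  t({s.df})={s.t:+.2f}  p={s.p:.3g}")
```

prints (also in `examples/02_reverse_correlation.py`):

```
-- vanilla
  relative       mean=+0.3117  t(99)=+38.29  p=3.74e-61
  sum            mean=+0.0106  t(99)=+1.21  p=0.23
  conf_chosen    mean=+0.0705  t(99)=+12.45  p=5.52e-22
  conf_unchosen  mean=-0.0733  t(99)=-12.56  p=3.31e-22
  conf_sum       mean=-0.0028  t(99)=-0.35  p=0.729
-- firing_rate
  relative       mean=+0.7114  t(99)=+101.34  p=8.14e-102
  sum            mean=+0.0188  t(99)=+1.35  p=0.179
  conf_chosen    mean=+0.1754  t(99)=+33.70  p=4.73e-56
  conf_unchosen  mean=-0.1515  t(99)=-33.76  p=4.04e-56
  conf_sum       mean=+0.0239  t(99)=+3.24  p=0.00163
```

Both observers decide from relative evidence (`relative` ≫ 0, `sum` ≈ 0)
and are more confident when the chosen channel is strong and the unchosen
channel weak. The signature difference is `conf_sum`: flat for the vanilla
observer, positive for the firing-rate observer — the positive evidence
bias emerging from signal-dependent Poisson noise alone, with no
metacognitive heuristic.

The other examples cover the observer models themselves
(`examples/01_observer_models.py`), a boosted synthetic luminance
experiment (`03`), and behavioral/metacognitive summaries (`04`). A thin
CLI wraps the same functions:

```bash
sdtkernels simulate --model vanilla --task detection --agents 100 --trials 100 --seed 1 --out campaign.csv
sdtkernels analyze --table campaign.csv --task detection --out analysis/
```

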