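# Methods

## Generative world model

A trial presents two sensory channels over T = 12 time steps. In
discrimination, one channel (equiprobably left/right) carries signal; in
detection, both channels are noise on half of the trials. Signal evidence
is drawn i.i.d. 𝒩(signal_mean = 0.5, signal_sd = 1) per time step and
noise evidence 𝒩(0, 1), in dimensionless evidence units.

## Observers

All four observers know the generative model exactly, accumulate
log-likelihoods for the three elementary hypotheses H ∈ {S1, S2, absent}
over whatever samples they observe, decide by maximum posterior, and
report confidence as the posterior probability of the chosen (composite)
hypothesis. They differ only in perception:

- **vanilla** — both channels observed with additive sensory noise
  𝒩(0, sensory_noise_sd = 2). The per-sample marginal under hypothesis H
  is 𝒩(μ_H, √(1² + 2²)), giving the closed-form channel-1 log-likelihood
  ratio increment (0.5/5)(x − 0.25) for S1 vs S2.
- **firing_rate** — percepts are Poisson counts k ~ Poisson(λ(E)) with
  λ(E) = exp(intercept + gain·E), defaults intercept = 2, gain = 1
  (noise-mean rate ≈ 7.4, signal-mean ≈ 12.2). The mapping from evidence
  to rate is not pinned down by the modelling tradition this mirrors; the
  exponential link was chosen because it is strictly positive, monotone,
  needs no cutoffs for negative evidence, and preserves the defining
  property that stronger activation is more variable. Both parameters are
  exposed in `AgentConfig`. The marginal P(k | H) = ∫ Poisson(k; λ(e))
  𝒩(e; μ_H, 1) de is evaluated with *adaptive* Gauss–Hermite quadrature
  (default 61 nodes, configurable ≥ 40): nodes are centred on the mode of
  the integrand (found by Newton iteration on the strictly concave
  log-integrand) and scaled by the local curvature. Fixed-node quadrature
  centred on the prior loses many log-units of accuracy for counts whose
  likelihood peaks far from the prior mean; the adaptive rule agrees with
  dense numerical integration to < 1e-9 over the realised count range and
  the resulting pmf sums to 1 within 1e-6. Marginals are cached as
  growable lookup tables per (config, hypothesis-mean).
- **random_attention** — a preferred channel is drawn uniformly per
  trial; each time step attends it with probability 0.95, the other with
  0.05. Only the attended entry is observed (with Gaussian sensory
  noise); unobserved entries contribute zero log-likelihood to every
  hypothesis, i.e. agents know what they attended.
- **goal_directed** — attention is sequential: P(attend channel 2 at t) =
  1/(1 + exp(−slope · LLR_r)) with slope = 5 and LLR_r the accumulated
  log-likelihood ratio of signal-in-2 vs signal-in-1 from all previously
  observed samples; LLR_r(0) = 0, so the first step is a fair coin.
  Channel 2 plays the role of "right"; the labelling is arbitrary and
  fixed for reproducibility. The same policy is used in detection.

Decision rules: discrimination decides argmax(ℓ_S1, ℓ_S2), confidence
= 1/(1 + e^(−|ℓ_S1 − ℓ_S2|)). Detection forms the presence mixture
ℓ_present = logsumexp(ℓ_S1 + log π₁, ℓ_S2 + log(1 − π₁)) with channel
prior π₁ = 0.5 and compares it with ℓ_absent under prior
P(present) = 0.5 (elementary priors 0.25/0.25/0.5, matching the
simulation design). Confidence is the posterior of the chosen composite
hypothesis; an `elementary` switch reports the best elementary posterior
instead, since either reading of "probability correct" is defensible (the
elementary variant can fall below 0.5 for 'yes' responses). Exact
likelihood ties are broken by a seeded fair coin — a zero-measure event
made deterministic per seed. All accumulation is in log space with
logsumexp for the mixture.

Campaign reproducibility: one root `SeedSequence` per campaign spawns one
independent substream per agent, so tables are bitwise reproducible and
agents are statistically independent.

## Reverse correlation

Analyses use the *external* evidence only; internal noise stays hidden.
Before kernel computation the evidence is mean-centred within channel
role (signal/nonsignal, assigned by ground truth) × condition × time
point, pooled across subjects, so only random fluctuations remain;
per-subject centring is available as an option. Detection signal-absent
trials are centred in their own group by default (they never enter the
kernels); an option pools them with present-trial noise channels.
Singleton groups are left uncentred with a warning.

Kernels are conditional cell-mean differences computed per subject:
correct − incorrect (discrimination decisions, roles by ground truth —
conditioning on the subject's own decision would make positive/negative
evidence circular), high − low confidence at the subject-session median
(discrimination confidence, roles by the subject's decision), yes − no on
signal-present trials (detection decisions), and high − low within each
response category (detection confidence). Median ties go to "low": a
deterministic, scale-free rule. Relative and sum composites are built
from the same cell means, so `relative = a − b` and `sum = a + b` hold
exactly per subject and time point, and every kernel is invariant under
strictly monotone transforms of the confidence scale.

Two paths share one interface: `trial_mean=True` averages the evidence
over all time points before conditioning (used for simulated agents);
`trial_mean=False` keeps one kernel value per stimulus frame, typically
followed by `window_mean` over the first 300 ms. A frame enters the
window iff its onset lies in [start, end) — at 25 Hz the default [0, 300)
window covers frames 1–8; the half-open convention is our choice, as the
boundary is otherwise ambiguous.

Exclusions are first-class: a subject lacking any conditioning cell for a
kernel is dropped for that kernel only, with the reason recorded, and
n_included + n_excluded always equals the number of subjects. Group
inference is a two-sided one-sample t-test of per-subject window values
against zero.

A caveat established while validating the pipeline: an observer whose
confidence ignores the unchosen channel still shows a positive
unchosen-channel confidence kernel (about half the chosen one), because
the median split is conditioned on a decision driven by relative
evidence, which couples the channels. Kernel signs therefore reflect the
full decision-plus-selection process, not raw weights read off in
isolation; the test suite asserts the properties that are actually
invariant (e.g. a confidence rule using only relative evidence yields a
null sum kernel — exactly, since sum and difference of i.i.d. Gaussian
channels are independent).

## Synthetic experiments

The luminance generator emulates two-patch flicker: per-bar values
𝒩(patch mean, 10) on the 0–255 RGB scale, background 128, signal patch
133, 4 bars × 12 frames at 25 Hz; detection 'same' trials put both
patches at 128; the boost adds 2/255 to every bar of both patches. The
hue generator samples per-bar angles 𝒩(role mean, 0.35 rad) with
nontarget 1.85 and target 2.1 rad and places colours exactly on the
circle of radius 49 around (L = 54, a* = 21.5, b* = 11.5); the boost
shifts both patch means toward the target hue by (2.1 − 1.85)/5 rad by
default — the magnitude is unspecified in the tradition this emulates, so
a "slight" fifth of the separation was fixed once and made configurable.
Channel evidence is the per-patch mean over bars (per-bar analysis is
possible by passing bar-level frames); world states and boost flags are
counterbalanced by shuffled balanced lists so cell sizes are exact at
small n.

Observers: `bayes_agent` maps stimulus units to evidence units by affine
standardisation against the background/nontarget mean and the stated SD
((value − 128)/10; (θ − 1.85)/0.35) — parameter-free, and mapping the
signal-patch mean to +0.5 evidence units, the agents' assumed signal
mean. Note the *patch-mean* SD is 0.5 evidence units (4 bars), so the
agent's assumed per-sample evidence SD of 1 is a deliberate model
mismatch of the same kind human observers face. `weighted_heuristic`
decides discrimination by the sign of relative trial-mean evidence plus
Gaussian decision noise and rates confidence as a logistic of
w_pos·chosen + w_neg·unchosen + w_sum·(sum) plus clipped confidence
noise; detection thresholds the summed evidence (default threshold 0.25,
halfway between the absent and present means) and confidence follows the
distance from threshold. The staircase starts at coherence 1.0 and moves
by 0.03 when 20-trial block accuracy leaves [0.60, 0.80], clipped to
[0, 1]; coherence scales the signal offset from the background.

What the generator does *not* emulate: screen gamma and the RGB-to-
brightness nonlinearity, colour rendering, response times, sequential
dependencies, lapses, and idiosyncratic confidence-scale use. Passing
tests therefore demonstrate the correctness and calibration of the
*pipeline* and the qualitative behaviour of the *models*, not that human
data would show these effects.

## Behavioral metrics

Type-2 ROC AUC sweeps every observed confidence value as a criterion
within a response category and accumulates P(conf ≥ c | correct) vs
P(conf ≥ c | incorrect) by the trapezoid rule; tied confidences share an
operating point (no random tie-breaking), making the statistic
deterministic and rank-invariant. Subjects without both correct and
incorrect trials in a cell are excluded for that metric. Boost contrasts
are per-subject boosted-minus-standard differences of confidence (per
response category) and of P(yes), tested against zero; confidence is used
on its native 0–1 scale. Cross-task correlations are Pearson r over
subjects, paired by subject id.

## Problem sizes and numerical choices

Default campaigns are 200 agents × 100 trials (20,000 trials per task and
model). The model-signature checks in the test suite run at 100 agents ×
100 trials per model and task, the weight-recovery check at 100 replicate
datasets of 50 subjects × 56 trials per task, and the null calibration at
500 replicates of 15 subjects × 32 trials per task with 4-frame evidence
— sizes at which every targeted effect is decisively signed while the
whole suite stays lightweight. Tolerances for stochastic checks are three
standard errors of the estimator concerned; algebraic identities are
asserted exactly; likelihood oracles at 1e-9.

## Known limitations

- The firing-rate observer's rate mapping is a modelling choice; other
  monotone positive links would shift quantitative (not qualitative)
  predictions.
- Detection confidence kernels for the firing-rate model can be noisy at
  small scale because high accuracy leaves few misses — the exclusion
  accounting surfaces this rather than hiding it.
- The weighted-heuristic detection confidence rule uses
  distance-from-threshold rather than the injected channel weights;
  weight-recovery validation is therefore a discrimination-side check.
- Time-resolved kernels assume a fixed frame rate per table; mixed frame
  rates would need per-session windowing.
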