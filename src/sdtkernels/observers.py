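"""Bayes-rational observer models for perceptual detection and discrimination.

Agents watch two noisy sensory channels over ``T`` time steps. On each trial
one channel may carry a signal (evidence drawn from ``N(signal_mean,
signal_sd)``) while the other carries noise (``N(0, signal_sd)``); in
detection, on half of the trials both channels are noise. Agents only see an
internally corrupted version of the evidence, accumulate log-likelihoods for
the three elementary world hypotheses (signal-in-1, signal-in-2, absent)
under full knowledge of the generative process, report the maximum-likelihood
world state, and rate confidence as the posterior probability of being
correct.

Four model families differ only in the perception stage:

``vanilla``
    Both channels seen each step, corrupted by additive Gaussian sensory
    noise (an equal-variance signal detection model).
``firing_rate``
    Percepts are Poisson spike counts with rate ``exp(intercept + gain * E)``;
    mean and variance are coupled, so strong stimuli are perceived as
    noisier (Weber-Fechner-like).
``random_attention``
    One channel is seen per step; a trial-preferred channel is attended with
    high persistent probability.
``goal_directed``
    One channel per step; the probability of attending channel 2 ("right")
    is a steep sigmoid of the running log-likelihood ratio for
    signal-in-2 vs signal-in-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import poisson

DISCRIMINATION = "discrimination"
DETECTION = "detection"
TASKS = (DISCRIMINATION, DETECTION)

MODELS = ("vanilla", "firing_rate", "random_attention", "goal_directed")
GAUSSIAN_MODELS = ("vanilla", "random_attention", "goal_directed")
ATTENTION_MODELS = ("random_attention", "goal_directed")

HYPOTHESES = ("S1", "S2", "absent")

Task = Literal["discrimination", "detection"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WorldState:
    """Ground-truth state of a trial.

    ``signal_channel`` is 1 or 2 when a signal is present, ``None`` when both
    channels are noise (detection only).
    """

    task: Task
    signal_channel: int | None

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.task == DISCRIMINATION and self.signal_channel not in (1, 2):
            raise ValueError("discrimination requires signal_channel in {1, 2}")
        if self.task == DETECTION and self.signal_channel not in (1, 2, None):
            raise ValueError("detection requires signal_channel in {1, 2, None}")

    @property
    def present(self) -> bool:
        return self.signal_channel is not None


@dataclass
class StimulusTrial:
    """External evidence for one trial: a ``T x 2`` matrix plus ground truth."""

    evidence: np.ndarray
    world: WorldState
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.evidence = np.asarray(self.evidence, dtype=float)
        if self.evidence.ndim != 2 or self.evidence.shape[1] != 2:
            raise ValueError("evidence must be a T x 2 matrix")
        if not np.all(np.isfinite(self.evidence)):
            raise ValueError("evidence must be finite")

    @property
    def T(self) -> int:
        return self.evidence.shape[0]


@dataclass(frozen=True)
class AgentConfig:
    """Parameters of a simulated observer.

    Defaults reproduce the reference simulation setting: external evidence
    ``N(0.5, 1)`` vs ``N(0, 1)``, additive sensory noise ``N(0, 2)``,
    attention persistence 0.95, attention sigmoid slope 5, and equal priors
    over world states.
    """

    model: str = "vanilla"
    signal_mean: float = 0.5
    signal_sd: float = 1.0
    sensory_noise_sd: float = 2.0
    attention_persistence: float = 0.95
    sigmoid_slope: float = 5.0
    poisson_log_rate_intercept: float = 2.0
    poisson_log_rate_gain: float = 1.0
    prior_present: float = 0.5
    prior_channel_given_present: float = 0.5
    n_quad_nodes: int = 61
    detection_confidence: str = "composite"  # or "elementary"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        for name in ("signal_sd", "sensory_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "attention_persistence",
            "prior_present",
            "prior_channel_given_present",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_quad_nodes < 40:
            raise ValueError("n_quad_nodes must be >= 40")
        if self.detection_confidence not in ("composite", "elementary"):
            raise ValueError("detection_confidence must be 'composite' or 'elementary'")


@dataclass
class PerceptTrace:
    """Internal samples of one trial.

    ``samples`` holds reals (Gaussian models) or spike counts
    (``firing_rate``). For attention models only one entry per time step is
    observed; unobserved entries are NaN and masked out.
    """

    samples: np.ndarray
    observed_mask: np.ndarray
    attended_channel: np.ndarray | None = None
    preferred_channel: int | None = None


@dataclass
class BeliefState:
    """Accumulated log-likelihoods (nats) for the elementary hypotheses."""

    loglik_s1: float = 0.0
    loglik_s2: float = 0.0
    loglik_absent: float = 0.0

    @property
    def llr_r(self) -> float:
        """Log-likelihood ratio for signal-in-2 ("right") vs signal-in-1."""
        return self.loglik_s2 - self.loglik_s1


@dataclass
class AgentResponse:
    decision: str  # "channel1" | "channel2" | "yes" | "no"
    confidence: float
    trace: PerceptTrace
    belief: BeliefState


# ---------------------------------------------------------------------------
# World and stimulus sampling
# ---------------------------------------------------------------------------


def sample_world(task: Task, rng: np.random.Generator) -> WorldState:
    """Draw a ground-truth world state.

    Discrimination: channels 1 and 2 equiprobable. Detection: absent with
    probability 1/2; otherwise the signal side is equiprobable.
    """
    if task == DISCRIMINATION:
        return WorldState(task, int(rng.integers(1, 3)))
    if task == DETECTION:
        if rng.random() < 0.5:
            return WorldState(task, None)
        return WorldState(task, int(rng.integers(1, 3)))
    raise ValueError(f"unknown task {task!r}")


def generate_stimulus(
    world: WorldState,
    T: int = 12,
    rng: np.random.Generator | None = None,
    signal_mean: float = 0.5,
    signal_sd: float = 1.0,
) -> StimulusTrial:
    """Sample a ``T x 2`` external-evidence matrix for a given world state."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    evidence = rng.normal(0.0, signal_sd, size=(T, 2))
    if world.signal_channel is not None:
        evidence[:, world.signal_channel - 1] += signal_mean
    return StimulusTrial(evidence=evidence, world=world)


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------


def _hypothesis_mean(hypothesis: str, channel: int, config: AgentConfig) -> float:
    """Generative evidence mean in `channel` under an elementary hypothesis."""
    if hypothesis not in HYPOTHESES:
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    signal_here = (hypothesis == "S1" and channel == 1) or (
        hypothesis == "S2" and channel == 2
    )
    return config.signal_mean if signal_here else 0.0


def _gaussian_marginal_logpdf(x: float, mu: float, config: AgentConfig) -> float:
    """log N(x; mu, sqrt(signal_sd^2 + sensory_noise_sd^2))."""
    var = config.signal_sd**2 + config.sensory_noise_sd**2
    return -0.5 * (x - mu) ** 2 / var - 0.5 * math.log(2.0 * math.pi * var)


@lru_cache(maxsize=16)
def _gh_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    nodes, weights = np.polynomial.hermite.hermgauss(n)
    return nodes, weights / math.sqrt(math.pi)


def poisson_marginal_logpmf(
    counts: np.ndarray | int, mu: float, config: AgentConfig
) -> np.ndarray | float:
    """Marginal log P(k | hypothesis mean mu) for the firing-rate model.

    Integrates Poisson(k; exp(intercept + gain*E)) over E ~ N(mu, signal_sd)
    with adaptive Gauss-Hermite quadrature (config.n_quad_nodes nodes): the
    nodes are centred on the mode of the integrand and scaled by its local
    curvature, which keeps the rule accurate even for large counts whose
    likelihood peaks far from the prior mean.
    """
    from scipy.special import gammaln

    k = np.atleast_1d(np.asarray(counts, dtype=float))
    if k.ndim != 1:
        k = k.ravel()
    a = config.poisson_log_rate_intercept
    g = config.poisson_log_rate_gain
    sd = config.signal_sd
    z, w = _gh_nodes(config.n_quad_nodes)

    # Newton iteration for the mode of log[Poisson(k; lambda(e)) N(e; mu, sd)];
    # the objective is strictly concave, steps are clipped for safety.
    m = np.where(k > 0, (np.log(np.maximum(k, 1.0)) - a) / max(g, 1e-12), mu)
    for _ in range(60):
        lam = np.exp(a + g * m)
        grad = g * k - g * lam - (m - mu) / sd**2
        hess = -(g**2) * lam - 1.0 / sd**2
        step = np.clip(grad / hess, -2.0, 2.0)
        m = m - step
        if np.max(np.abs(step)) < 1e-14:
            break
    lam_m = np.exp(a + g * m)
    s = 1.0 / np.sqrt(g**2 * lam_m + 1.0 / sd**2)

    e = m[:, None] + math.sqrt(2.0) * s[:, None] * z[None, :]
    log_rate = a + g * e
    log_integrand = (
        k[:, None] * log_rate
        - np.exp(log_rate)
        - gammaln(k + 1.0)[:, None]
        - 0.5 * ((e - mu) / sd) ** 2
        - math.log(sd)
        - 0.5 * math.log(2.0 * math.pi)
    )
    # _gh_nodes holds weights divided by sqrt(pi); restore the raw GH weights
    out = logsumexp(
        np.log(w)[None, :] + z[None, :] ** 2 + log_integrand, axis=1
    ) + np.log(math.sqrt(2.0 * math.pi) * s)
    return float(out[0]) if np.ndim(counts) == 0 else out


class _FiringRateTable:
    """Growable lookup table of marginal log-pmfs for the two evidence means."""

    def __init__(self, config: AgentConfig):
        self.config = config
        self._tables: dict[float, np.ndarray] = {}

    def logpmf(self, counts: np.ndarray, mu: float) -> np.ndarray:
        counts = np.asarray(counts, dtype=int)
        kmax = int(counts.max(initial=0))
        table = self._tables.get(mu)
        if table is None or len(table) <= kmax:
            size = max(kmax + 1, 256)
            table = np.asarray(
                poisson_marginal_logpmf(np.arange(size), mu, self.config)
            )
            self._tables[mu] = table
        return table[counts]


@lru_cache(maxsize=32)
def _firing_rate_table(config: AgentConfig) -> _FiringRateTable:
    return _FiringRateTable(config)


def loglik_increment(
    sample: float | int,
    observed_channel: int,
    hypothesis: str,
    config: AgentConfig,
) -> float:
    """Log-likelihood of one internal sample under an elementary hypothesis.

    Gaussian models use the marginal Normal of evidence-plus-sensory-noise;
    the firing-rate model marginalises the Poisson rate over the evidence
    distribution by quadrature.
    """
    if not np.isfinite(sample):
        raise ValueError("sample must be finite")
    if observed_channel not in (1, 2):
        raise ValueError("observed_channel must be 1 or 2")
    mu = _hypothesis_mean(hypothesis, observed_channel, config)
    if config.model == "firing_rate":
        k = int(sample)
        if k != sample or k < 0:
            raise ValueError("firing-rate samples must be non-negative integers")
        return float(poisson_marginal_logpmf(k, mu, config))
    return _gaussian_marginal_logpdf(float(sample), mu, config)


def belief_from_samples(
    samples: np.ndarray,
    config: AgentConfig,
    observed_mask: np.ndarray | None = None,
) -> BeliefState:
    """Accumulate log-likelihoods over all observed entries of ``samples``.

    Vectorised over the trial; unobserved (masked) entries contribute zero to
    every hypothesis.
    """
    samples = np.asarray(samples)
    if observed_mask is None:
        observed_mask = np.ones(samples.shape, dtype=bool)
    m = config.signal_mean
    if config.model == "firing_rate":
        table = _firing_rate_table(config)
        k = samples.astype(int)
        lp_sig = np.where(observed_mask, table.logpmf(k, m), 0.0)
        lp_noise = np.where(observed_mask, table.logpmf(k, 0.0), 0.0)
    else:
        var = config.signal_sd**2 + config.sensory_noise_sd**2
        norm_const = 0.5 * math.log(2.0 * math.pi * var)
        lp_sig = np.where(
            observed_mask, -0.5 * (samples - m) ** 2 / var - norm_const, 0.0
        )
        lp_noise = np.where(observed_mask, -0.5 * samples**2 / var - norm_const, 0.0)
    return BeliefState(
        loglik_s1=float(lp_sig[:, 0].sum() + lp_noise[:, 1].sum()),
        loglik_s2=float(lp_noise[:, 0].sum() + lp_sig[:, 1].sum()),
        loglik_absent=float(lp_noise.sum()),
    )


# ---------------------------------------------------------------------------
# Perception
# ---------------------------------------------------------------------------


def _perceive_and_accumulate(
    stimulus: StimulusTrial, config: AgentConfig, rng: np.random.Generator
) -> tuple[PerceptTrace, BeliefState]:
    """Run the model-specific perception stage and accumulate beliefs.

    Attention models interleave sampling and belief updating because the
    goal-directed policy depends on the running LLR.
    """
    E = stimulus.evidence
    T = E.shape[0]

    if config.model == "vanilla":
        samples = E + rng.normal(0.0, config.sensory_noise_sd, size=E.shape)
        trace = PerceptTrace(samples, np.ones(E.shape, dtype=bool))
        return trace, belief_from_samples(samples, config)

    if config.model == "firing_rate":
        lam = np.exp(
            config.poisson_log_rate_intercept + config.poisson_log_rate_gain * E
        )
        samples = rng.poisson(lam).astype(float)
        trace = PerceptTrace(samples, np.ones(E.shape, dtype=bool))
        return trace, belief_from_samples(samples, config)

    if config.model == "random_attention":
        preferred = int(rng.integers(1, 3))
        stay = rng.random(T) < config.attention_persistence
        attended = np.where(stay, preferred, 3 - preferred)
        noise = rng.normal(0.0, config.sensory_noise_sd, size=T)
        samples = np.full((T, 2), np.nan)
        mask = np.zeros((T, 2), dtype=bool)
        samples[np.arange(T), attended - 1] = E[np.arange(T), attended - 1] + noise
        mask[np.arange(T), attended - 1] = True
        trace = PerceptTrace(samples, mask, attended, preferred)
        belief = belief_from_samples(np.nan_to_num(samples), config, mask)
        return trace, belief

    # goal_directed: sequential policy, one channel per step
    samples = np.full((T, 2), np.nan)
    mask = np.zeros((T, 2), dtype=bool)
    attended = np.zeros(T, dtype=int)
    belief = BeliefState()
    for t in range(T):
        p_attend_2 = 1.0 / (1.0 + math.exp(-config.sigmoid_slope * belief.llr_r))
        ch = 2 if rng.random() < p_attend_2 else 1
        x = E[t, ch - 1] + rng.normal(0.0, config.sensory_noise_sd)
        samples[t, ch - 1] = x
        mask[t, ch - 1] = True
        attended[t] = ch
        belief.loglik_s1 += loglik_increment(x, ch, "S1", config)
        belief.loglik_s2 += loglik_increment(x, ch, "S2", config)
        belief.loglik_absent += loglik_increment(x, ch, "absent", config)
    trace = PerceptTrace(samples, mask, attended)
    return trace, belief


def perceive(
    stimulus: StimulusTrial, config: AgentConfig, rng: np.random.Generator
) -> PerceptTrace:
    """Generate the internal percept of a trial (without deciding)."""
    trace, _ = _perceive_and_accumulate(stimulus, config, rng)
    return trace


# ---------------------------------------------------------------------------
# Decision and confidence
# ---------------------------------------------------------------------------


def respond_from_belief(
    belief: BeliefState,
    task: Task,
    config: AgentConfig,
    rng: np.random.Generator,
) -> tuple[str, float]:
    """Maximum-posterior decision plus confidence from accumulated beliefs.

    Discrimination: argmax over the two signal hypotheses (equal priors);
    confidence is the posterior of the chosen one. Detection: the presence
    hypothesis is the prior-weighted mixture of signal-in-1 and signal-in-2;
    confidence is the posterior of the chosen composite hypothesis
    (default), or of the best elementary hypothesis when
    ``detection_confidence='elementary'``. Exact ties are broken by a fair
    coin from ``rng``.
    """
    if task == DISCRIMINATION:
        delta = belief.loglik_s1 - belief.loglik_s2
        if delta == 0.0:
            decision = "channel1" if rng.random() < 0.5 else "channel2"
        else:
            decision = "channel1" if delta > 0 else "channel2"
        confidence = 1.0 / (1.0 + math.exp(-abs(delta)))
        return decision, confidence

    p_ch1 = config.prior_channel_given_present
    lp_present = logsumexp(
        [belief.loglik_s1, belief.loglik_s2],
        b=[max(p_ch1, 1e-300), max(1.0 - p_ch1, 1e-300)],
    ) + math.log(max(config.prior_present, 1e-300))
    lp_absent = belief.loglik_absent + math.log(max(1.0 - config.prior_present, 1e-300))
    delta = lp_present - lp_absent
    if delta == 0.0:
        decision = "yes" if rng.random() < 0.5 else "no"
    else:
        decision = "yes" if delta > 0 else "no"
    confidence = 1.0 / (1.0 + math.exp(-abs(delta)))
    if config.detection_confidence == "elementary":
        logpost = np.array(
            [
                belief.loglik_s1
                + math.log(max(config.prior_present * p_ch1, 1e-300)),
                belief.loglik_s2
                + math.log(max(config.prior_present * (1.0 - p_ch1), 1e-300)),
                lp_absent,
            ]
        )
        post = np.exp(logpost - logsumexp(logpost))
        confidence = float(max(post[0], post[1]) if decision == "yes" else post[2])
    return decision, confidence


def is_correct(world: WorldState, decision: str) -> bool:
    if world.task == DISCRIMINATION:
        return decision == f"channel{world.signal_channel}"
    return decision == ("yes" if world.present else "no")


def run_trial(
    stimulus: StimulusTrial,
    config: AgentConfig,
    task: Task,
    rng: np.random.Generator,
) -> AgentResponse:
    """Perceive a stimulus, accumulate beliefs, decide and rate confidence."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    trace, belief = _perceive_and_accumulate(stimulus, config, rng)
    decision, confidence = respond_from_belief(belief, task, config, rng)
    return AgentResponse(decision, confidence, trace, belief)


# ---------------------------------------------------------------------------
# Campaigns
# ---------------------------------------------------------------------------


def _evidence_columns(T: int) -> list[str]:
    return [f"ev_ch{c}_t{t:02d}" for c in (1, 2) for t in range(1, T + 1)]


def simulate_campaign(
    config: AgentConfig,
    task: Task,
    n_agents: int = 200,
    n_trials: int = 100,
    seed: int | None = None,
    T: int = 12,
) -> pd.DataFrame:
    """Simulate ``n_agents x n_trials`` trials and return a trial table.

    One root seed drives the campaign; each agent gets an independent
    deterministic substream, so the table is bitwise reproducible. Columns
    follow the wide trial-table schema (one row per trial, external evidence
    time points as columns).
    """
    if n_agents < 1 or n_trials < 1:
        raise ValueError("n_agents and n_trials must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_agents)
    records: list[dict] = []
    for agent_idx, stream in enumerate(streams, start=1):
        rng = np.random.default_rng(stream)
        for _ in range(n_trials):
            world = sample_world(task, rng)
            stimulus = generate_stimulus(
                world, T=T, rng=rng, signal_mean=config.signal_mean,
                signal_sd=config.signal_sd,
            )
            resp = run_trial(stimulus, config, task, rng)
            row = {
                "subject_id": agent_idx,
                "session_id": 1,
                "task": task,
                "condition_boost": 0,
                "coherence": np.nan,
                "world_signal_channel": (
                    "none" if world.signal_channel is None else str(world.signal_channel)
                ),
                "decision": resp.decision,
                "correct": int(is_correct(world, resp.decision)),
                "confidence": resp.confidence,
            }
            ev = stimulus.evidence
            for c in (1, 2):
                for t in range(T):
                    row[f"ev_ch{c}_t{t + 1:02d}"] = ev[t, c - 1]
            records.append(row)
    return pd.DataFrame.from_records(records)
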