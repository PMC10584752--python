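"""Synthetic flicker experiments: stimuli, staircases, and observers.

Emulates online luminance- and hue-flicker sessions so the whole analysis
pipeline can be exercised without human data. A trial shows two patches of
four bars flickering over 12 frames at 25 Hz. In the luminance paradigm each
bar's luminance is Gaussian around the patch mean on the 0-255 RGB scale
(background 128, signal patch 133, SD 10; an optional boost adds 2 to every
bar of both patches). In the hue paradigm each bar's hue angle is Gaussian
on a CIE L*a*b* hue circle (radius 49 around L=54, a*=21.5, b*=11.5;
nontarget mean 1.85 rad, target mean 2.1 rad, SD 0.35 rad).

Two observer families respond to these stimuli: ``bayes_agent`` delegates to
the observer models after an affine mapping of stimulus units to evidence
units, and ``weighted_heuristic`` applies explicit, injectable weights to
chosen/unchosen/sum evidence -- a ground-truth observer for validating that
the reverse-correlation pipeline recovers known evidence-weighting patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .observers import (
    DETECTION,
    DISCRIMINATION,
    AgentConfig,
    StimulusTrial,
    WorldState,
    is_correct,
    run_trial,
)

__all__ = [
    "StimulusSpec",
    "StaircaseState",
    "ObserverSpec",
    "ExperimentDesign",
    "generate_luminance_trial",
    "generate_hue_trial",
    "frames_to_channels",
    "staircase_update",
    "staircase_record",
    "synthetic_observer_respond",
    "run_synthetic_experiment",
    "run_staircase_session",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of the flicker stimulus generator."""

    paradigm: str = "luminance"
    n_frames: int = 12
    frame_rate_hz: float = 25.0
    bars_per_patch: int = 4
    background_mean: float = 128.0
    signal_mean: float = 133.0
    luminance_sd: float = 10.0
    boost_delta: float = 2.0
    hue_L: float = 54.0
    hue_a: float = 21.5
    hue_b: float = 11.5
    hue_radius: float = 49.0
    hue_nontarget_rad: float = 1.85
    hue_target_rad: float = 2.1
    hue_sd_rad: float = 0.35
    # the hue boost has no stated magnitude; one fifth of the target-nontarget
    # separation keeps it "slight" and is configurable
    hue_boost_delta: float = (2.1 - 1.85) / 5.0

    def __post_init__(self) -> None:
        if self.paradigm not in ("luminance", "hue"):
            raise ValueError("paradigm must be 'luminance' or 'hue'")
        if self.luminance_sd <= 0 or self.hue_sd_rad <= 0:
            raise ValueError("stimulus SDs must be > 0")


@dataclass(frozen=True)
class StaircaseState:
    """Block-wise 1-up/1-down staircase on stimulus coherence."""

    coherence: float = 1.0
    trial_count: int = 0
    window: tuple = ()  # accuracy buffer of the current 20-trial block

    def __post_init__(self) -> None:
        if not 0.0 <= self.coherence <= 1.0:
            raise ValueError("coherence must lie in [0, 1]")


@dataclass(frozen=True)
class ObserverSpec:
    """A synthetic respondent: Bayes agent or explicit-weights heuristic."""

    kind: str = "bayes_agent"
    w_pos: float = 1.0
    w_neg: float = -1.0
    w_sum: float = 0.0
    decision_noise_sd: float = 0.0
    confidence_noise_sd: float = 0.0
    detection_threshold: float = 0.25  # on summed evidence units
    agent_config: AgentConfig = field(default_factory=AgentConfig)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("bayes_agent", "weighted_heuristic"):
            raise ValueError("kind must be 'bayes_agent' or 'weighted_heuristic'")
        if self.decision_noise_sd < 0 or self.confidence_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class ExperimentDesign:
    n_subjects: int = 50
    trials_per_task: int = 56
    boost_fraction: float = 0.0
    seed: int | None = None


# ---------------------------------------------------------------------------
# Stimulus generation
# ---------------------------------------------------------------------------


def _patch_means_luminance(
    spec: StimulusSpec, world: WorldState, boost: bool, coherence: float
) -> np.ndarray:
    means = np.full(2, spec.background_mean)
    if world.signal_channel is not None:
        means[world.signal_channel - 1] += coherence * (
            spec.signal_mean - spec.background_mean
        )
    if boost:
        means += spec.boost_delta
    return means


def _luminance_batch(
    spec: StimulusSpec,
    worlds: list[WorldState],
    boosts: np.ndarray,
    rng: np.random.Generator,
    coherence: float = 1.0,
) -> np.ndarray:
    """Bar luminances for many trials: (n, n_frames, 2, bars_per_patch)."""
    n = len(worlds)
    means = np.stack(
        [_patch_means_luminance(spec, w, bool(b), coherence) for w, b in zip(worlds, boosts)]
    )  # (n, 2)
    shape = (n, spec.n_frames, 2, spec.bars_per_patch)
    return means[:, None, :, None] + rng.normal(0.0, spec.luminance_sd, size=shape)


def generate_luminance_trial(
    spec: StimulusSpec,
    task: str,
    world: WorldState,
    boost: bool,
    rng: np.random.Generator,
    coherence: float = 1.0,
) -> np.ndarray:
    """One luminance trial: bar values of shape (n_frames, 2, bars_per_patch).

    The signal patch is centered ``coherence * (signal - background)`` above
    the background; on detection 'same' trials both patches sit at the
    background mean. A boost raises every bar of both patches.
    """
    del task  # the world state already encodes the task
    return _luminance_batch(spec, [world], np.array([boost]), rng, coherence)[0]


def _hue_angle_batch(
    spec: StimulusSpec,
    worlds: list[WorldState],
    boosts: np.ndarray,
    rng: np.random.Generator,
    coherence: float = 1.0,
) -> np.ndarray:
    n = len(worlds)
    sep = spec.hue_target_rad - spec.hue_nontarget_rad
    means = np.full((n, 2), spec.hue_nontarget_rad)
    for i, w in enumerate(worlds):
        if w.signal_channel is not None:
            means[i, w.signal_channel - 1] += coherence * sep
    means += np.where(boosts[:, None], spec.hue_boost_delta, 0.0)
    shape = (n, spec.n_frames, 2, spec.bars_per_patch)
    return means[:, None, :, None] + rng.normal(0.0, spec.hue_sd_rad, size=shape)


def generate_hue_trial(
    spec: StimulusSpec,
    task: str,
    world: WorldState,
    boost: bool,
    rng: np.random.Generator,
    coherence: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One hue trial: per-bar angles (radians) and their L*a*b* coordinates.

    Angles are Gaussian around the patch-role mean; colors lie exactly on
    the configured hue circle: (L, a + r cos(theta), b + r sin(theta)).
    A boost shifts both patches' angle means toward the target hue.
    """
    del task
    angles = _hue_angle_batch(spec, [world], np.array([boost]), rng, coherence)[0]
    lab = np.stack(
        [
            np.full_like(angles, spec.hue_L),
            spec.hue_a + spec.hue_radius * np.cos(angles),
            spec.hue_b + spec.hue_radius * np.sin(angles),
        ],
        axis=-1,
    )
    return angles, lab


def frames_to_channels(
    frames: np.ndarray, world: WorldState | None = None, condition: dict | None = None
) -> StimulusTrial:
    """Collapse bar values to per-patch per-frame channel evidence.

    ``evidence[t, patch]`` is the mean over that patch's bars at frame t;
    units (RGB values or radians) are preserved.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[1] != 2:
        raise ValueError("frames must have shape (n_frames, 2, bars_per_patch)")
    evidence = frames.mean(axis=2)
    if world is None:
        world = WorldState(DETECTION, None)
    return StimulusTrial(evidence=evidence, world=world, condition=condition or {})


# ---------------------------------------------------------------------------
# Staircase
# ---------------------------------------------------------------------------


def staircase_update(state: StaircaseState, block_accuracy: float) -> StaircaseState:
    """Adjust coherence by 3% when block accuracy leaves the 60-80% band."""
    if not 0.0 <= block_accuracy <= 1.0:
        raise ValueError("block_accuracy must lie in [0, 1]")
    coherence = state.coherence
    if block_accuracy < 0.60:
        coherence += 0.03
    elif block_accuracy > 0.80:
        coherence -= 0.03
    coherence = min(1.0, max(0.0, coherence))
    return replace(state, coherence=coherence, window=())


def staircase_record(state: StaircaseState, correct: bool) -> StaircaseState:
    """Record one trial outcome; every 20 trials the block rule applies."""
    window = state.window + (bool(correct),)
    state = replace(state, trial_count=state.trial_count + 1, window=window)
    if len(window) >= 20:
        return staircase_update(state, float(np.mean(window)))
    return state


# ---------------------------------------------------------------------------
# Observers
# ---------------------------------------------------------------------------


def _standardize(evidence: np.ndarray, spec: StimulusSpec) -> np.ndarray:
    """Map stimulus units to the abstract evidence units of the agents.

    Luminance: (value - background) / luminance_sd; hue: (angle - nontarget
    mean) / hue SD. With the default specs the signal-patch mean maps to
    +0.5 evidence units, matching the agents' generative assumptions.
    """
    if spec.paradigm == "hue":
        return (evidence - spec.hue_nontarget_rad) / spec.hue_sd_rad
    return (evidence - spec.background_mean) / spec.luminance_sd


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _heuristic_respond_batch(
    evidence_units: np.ndarray,
    observer: ObserverSpec,
    task: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised weighted-heuristic responses for (n, T, 2) evidence."""
    m = evidence_units.mean(axis=1)  # (n, 2) trial-mean evidence per channel
    n = len(m)
    dec_noise = (
        rng.normal(0.0, observer.decision_noise_sd, size=n)
        if observer.decision_noise_sd > 0
        else np.zeros(n)
    )
    conf_noise = (
        rng.normal(0.0, observer.confidence_noise_sd, size=n)
        if observer.confidence_noise_sd > 0
        else np.zeros(n)
    )
    total = m.sum(axis=1)
    if task == DISCRIMINATION:
        stat = m[:, 0] - m[:, 1] + dec_noise
        ties = stat == 0.0
        if ties.any():
            stat = stat + np.where(ties, rng.choice([-1e-12, 1e-12], size=n), 0.0)
        first = stat > 0
        decisions = np.where(first, "channel1", "channel2")
        chosen = np.where(first, m[:, 0], m[:, 1])
        unchosen = np.where(first, m[:, 1], m[:, 0])
        drive = (
            observer.w_pos * chosen + observer.w_neg * unchosen + observer.w_sum * total
        )
        confidence = _logistic(drive) + conf_noise
    else:
        stat = total + dec_noise
        yes = stat > observer.detection_threshold
        decisions = np.where(yes, "yes", "no")
        margin = stat - observer.detection_threshold
        confidence = _logistic(np.where(yes, margin, -margin)) + conf_noise
    return decisions, np.clip(confidence, 0.0, 1.0)


def synthetic_observer_respond(
    trial: StimulusTrial,
    observer: ObserverSpec,
    task: str,
    rng: np.random.Generator,
    spec: StimulusSpec | None = None,
) -> tuple[str, float]:
    """Decision and confidence of a synthetic observer for one trial.

    ``trial.evidence`` is in stimulus units; it is standardized against the
    background (or nontarget hue) before the observer responds.
    """
    spec = spec or StimulusSpec()
    units = _standardize(trial.evidence, spec)[None, :, :]
    if observer.kind == "weighted_heuristic":
        decisions, confidences = _heuristic_respond_batch(units, observer, task, rng)
        return str(decisions[0]), float(confidences[0])
    agent_trial = StimulusTrial(units[0], trial.world, dict(trial.condition))
    resp = run_trial(agent_trial, observer.agent_config, task, rng)
    return resp.decision, resp.confidence


# ---------------------------------------------------------------------------
# Experiment runner
# ---------------------------------------------------------------------------


def _balanced_worlds(task: str, n: int, rng: np.random.Generator) -> list[WorldState]:
    """Counterbalanced world states (shuffled balanced list, not coin flips)."""
    if task == DISCRIMINATION:
        channels = [1, 2] * (n // 2) + [1] * (n % 2)
    else:
        n_absent = n // 2
        n_present = n - n_absent
        channels = [None] * n_absent + [1, 2] * (n_present // 2) + [1] * (
            n_present % 2
        )
    rng.shuffle(channels)
    return [WorldState(task, c) for c in channels]


def _balanced_flags(fraction: float, n: int, rng: np.random.Generator) -> np.ndarray:
    k = int(round(fraction * n))
    flags = np.zeros(n, dtype=bool)
    flags[:k] = True
    rng.shuffle(flags)
    return flags


def run_synthetic_experiment(
    spec: StimulusSpec,
    observer: ObserverSpec,
    design: ExperimentDesign,
) -> pd.DataFrame:
    """Simulate a full multi-subject session and return a trial table.

    Detection and discrimination blocks are interleaved per subject with
    counterbalanced world states; the boost flag marks the configured
    fraction of trials (exactly, by construction). Evidence columns hold the
    per-patch per-frame means in stimulus units.
    """
    streams = np.random.SeedSequence(design.seed).spawn(design.n_subjects)
    frames_per_trial = spec.n_frames
    records = []
    for subject, stream in enumerate(streams, start=1):
        rng = np.random.default_rng(stream)
        for task in (DETECTION, DISCRIMINATION):
            worlds = _balanced_worlds(task, design.trials_per_task, rng)
            boosts = _balanced_flags(design.boost_fraction, design.trials_per_task, rng)
            if spec.paradigm == "hue":
                bars = _hue_angle_batch(spec, worlds, boosts, rng)
            else:
                bars = _luminance_batch(spec, worlds, boosts, rng)
            evidence = bars.mean(axis=3)  # (n, T, 2) per-patch means
            units = _standardize(evidence, spec)
            if observer.kind == "weighted_heuristic":
                decisions, confidences = _heuristic_respond_batch(
                    units, observer, task, rng
                )
            else:
                decisions, confidences = [], []
                for i, world in enumerate(worlds):
                    resp = run_trial(
                        StimulusTrial(units[i], world),
                        observer.agent_config,
                        task,
                        rng,
                    )
                    decisions.append(resp.decision)
                    confidences.append(resp.confidence)
            for i, world in enumerate(worlds):
                row = {
                    "subject_id": subject,
                    "session_id": 1,
                    "task": task,
                    "condition_boost": int(boosts[i]),
                    "coherence": np.nan,
                    "world_signal_channel": (
                        "none" if world.signal_channel is None
                        else str(world.signal_channel)
                    ),
                    "decision": str(decisions[i]),
                    "correct": int(is_correct(world, str(decisions[i]))),
                    "confidence": float(confidences[i]),
                }
                for c in (1, 2):
                    for t in range(frames_per_trial):
                        row[f"ev_ch{c}_t{t + 1:02d}"] = evidence[i, t, c - 1]
                records.append(row)
    return pd.DataFrame.from_records(records)


def run_staircase_session(
    spec: StimulusSpec,
    observer: ObserverSpec,
    task: str,
    n_trials: int = 400,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run one observer through a staircased session of luminance trials.

    Coherence scales the signal-patch offset from the background; the
    block-wise staircase adjusts it from 1.0 toward the 60-80% accuracy
    band. Returns one row per trial with the prevailing coherence.
    """
    rng = np.random.default_rng(seed)
    state = StaircaseState()
    rows = []
    for i in range(n_trials):
        if task == DISCRIMINATION:
            world = WorldState(task, int(rng.integers(1, 3)))
        else:
            world = WorldState(
                task, None if rng.random() < 0.5 else int(rng.integers(1, 3))
            )
        bars = generate_luminance_trial(
            spec, task, world, False, rng, coherence=state.coherence
        )
        trial = frames_to_channels(bars, world)
        decision, confidence = synthetic_observer_respond(
            trial, observer, task, rng, spec
        )
        correct = is_correct(world, decision)
        rows.append(
            {
                "trial": i + 1,
                "coherence": state.coherence,
                "decision": decision,
                "correct": int(correct),
                "confidence": confidence,
            }
        )
        state = staircase_record(state, correct)
    return pd.DataFrame(rows)
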