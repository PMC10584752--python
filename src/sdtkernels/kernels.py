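"""Reverse-correlation decision and confidence kernels.

A kernel is the mean difference in stimulus noise between two trial classes:
correct vs incorrect (discrimination decision kernels), high vs low
confidence (confidence kernels, split at the subject-session median rating),
or yes vs no responses on signal-present detection trials (detection
kernels). Channel roles are assigned by the ground truth for decision
kernels (signal vs nonsignal channel) and by the subject's own decision for
discrimination confidence kernels (chosen vs unchosen channel).

All composite kernels (relative, sum) are built from the same conditional
cell means as the per-channel kernels, so the identities
``relative = chosen - unchosen`` and ``sum = chosen + unchosen`` hold
exactly per subject and time point.

Two analysis paths share one interface: trial-level kernels (evidence
averaged over all time points before conditioning, as used for simulated
agents) and time-resolved kernels (one value per stimulus frame, as used for
flicker-style sessions, typically followed by averaging over an early
window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupStats",
    "KernelResult",
    "group_ttest",
    "mean_center_evidence",
    "median_split",
    "discrimination_decision_kernels",
    "discrimination_confidence_kernels",
    "detection_decision_kernels",
    "detection_confidence_kernels",
    "window_mean",
    "window_frames",
    "compute_kernels",
    "evidence_column_names",
    "plot_kernel_timecourses",
]

DISCRIMINATION_KERNELS = ("relative", "sum")
CONFIDENCE_KERNELS = ("conf_chosen", "conf_unchosen", "conf_relative", "conf_sum")
DETECTION_KERNELS = (
    "detection_s",
    "detection_n",
    "detection_relative",
    "detection_sum",
)


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------


@dataclass
class GroupStats:
    """One-sample t-test of per-subject kernel values against zero."""

    mean: float
    sd: float
    t: float
    df: int
    p: float
    ci95: tuple[float, float]
    n: int


def group_ttest(per_subject_values) -> GroupStats:
    """Two-sided one-sample t-test against zero; errors on degenerate input."""
    values = np.asarray(pd.Series(per_subject_values).dropna(), dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("group t-test needs at least 2 subjects")
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        raise ValueError("zero variance across subjects; t-test undefined")
    res = stats.ttest_1samp(values, 0.0)
    ci = res.confidence_interval(0.95)
    return GroupStats(
        mean=float(values.mean()),
        sd=sd,
        t=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
        ci95=(float(ci.low), float(ci.high)),
        n=n,
    )


# ---------------------------------------------------------------------------
# Kernel container
# ---------------------------------------------------------------------------


@dataclass
class KernelResult:
    """Per-subject reverse-correlation kernel with exclusion accounting.

    ``per_subject_timecourse`` is a subjects x frames DataFrame (a single
    column for trial-level kernels). ``per_subject_window`` is the mean over
    the analysis window, initially the full trial.
    """

    kernel_id: str
    per_subject_timecourse: pd.DataFrame
    per_subject_window: pd.Series
    cell_counts: pd.DataFrame
    excluded_subjects: list[tuple] = field(default_factory=list)
    window_ms: tuple[float, float] | None = None
    frame_rate_hz: float | None = None

    @property
    def n_included(self) -> int:
        return len(self.per_subject_timecourse)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_subjects)

    def group_stats(self) -> GroupStats:
        return group_ttest(self.per_subject_window)


def evidence_column_names(table: pd.DataFrame) -> tuple[list[str], list[str]]:
    """The per-frame evidence columns for channels 1 and 2, in time order."""
    ch1 = sorted(c for c in table.columns if c.startswith("ev_ch1_t"))
    ch2 = sorted(c for c in table.columns if c.startswith("ev_ch2_t"))
    if not ch1 or len(ch1) != len(ch2):
        raise ValueError("table must hold matching ev_ch1_t*/ev_ch2_t* columns")
    return ch1, ch2


def _channel_arrays(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    ch1, ch2 = evidence_column_names(table)
    return table[ch1].to_numpy(float), table[ch2].to_numpy(float)


# ---------------------------------------------------------------------------
# Mean-centering
# ---------------------------------------------------------------------------


def mean_center_evidence(
    table: pd.DataFrame,
    grouping: tuple[str, ...] = ("task", "condition_boost"),
    per_subject: bool = False,
    include_absent: bool = False,
) -> pd.DataFrame:
    """Remove systematic signal/noise channel differences from the evidence.

    Within each group -- channel role (signal vs noise, by ground truth) x
    the listed condition columns, pooled across subjects, separately per
    time point -- the mean evidence is subtracted, so that only random
    fluctuations remain. Detection signal-absent trials are centered in
    their own group unless ``include_absent`` pools them with the
    signal-present noise channels. Groups with a single trial are left
    uncentered with a warning. The input table is not modified.
    """
    out = table.copy()
    ch1, ch2 = evidence_column_names(table)
    world = table["world_signal_channel"].astype(str)
    keys_extra = [table[k] for k in grouping if k in table.columns]
    if per_subject:
        keys_extra.append(table["subject_id"])
    for cols, channel in ((ch1, "1"), (ch2, "2")):
        role = np.where(world == channel, "signal", "noise")
        keys = [pd.Series(role, index=table.index)]
        if not include_absent:
            keys.append((world == "none").rename("absent"))
        keys.extend(keys_extra)
        grouped = out.groupby(keys, observed=True, dropna=False)
        sizes = grouped[cols[0]].transform("size")
        if (sizes < 2).any():
            warnings.warn(
                "singleton centering group left uncentered", stacklevel=2
            )
        means = grouped[cols].transform("mean")
        ok = (sizes.to_numpy() >= 2)[:, None]
        out[cols] = np.where(ok, out[cols].to_numpy() - means.to_numpy(), out[cols])
    return out


# ---------------------------------------------------------------------------
# Median split
# ---------------------------------------------------------------------------


def median_split(confidences) -> tuple[np.ndarray, bool]:
    """Split ratings at their median: strictly above -> ``"high"``.

    Ties at the median go to ``"low"``. Returns the labels and a flag that
    is True when the scope is degenerate (all ratings identical, so every
    trial is labelled low).
    """
    values = np.asarray(confidences, dtype=float)
    if len(values) < 2:
        raise ValueError("median split needs at least 2 ratings")
    med = float(np.median(values))
    labels = np.where(values > med, "high", "low")
    degenerate = bool(np.all(values == values[0]))
    return labels, degenerate


def _split_labels(table: pd.DataFrame, scope: tuple[str, ...]) -> pd.Series:
    """High/low labels per row, median taken within the given scope columns."""
    scope_cols = [c for c in scope if c in table.columns]
    med = table.groupby(scope_cols, observed=True)["confidence"].transform("median")
    return pd.Series(
        np.where(table["confidence"] > med, "high", "low"), index=table.index
    )


# ---------------------------------------------------------------------------
# Kernel machinery
# ---------------------------------------------------------------------------


def _role_arrays(
    table: pd.DataFrame, by_decision: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Evidence arrays (n_trials x T) for the two channel roles.

    ``by_decision=False``: (signal, nonsignal) by ground truth.
    ``by_decision=True``: (chosen, unchosen) by the subject's decision.
    """
    e1, e2 = _channel_arrays(table)
    if by_decision:
        first = table["decision"].astype(str).isin(["channel1", "1"]).to_numpy()
    else:
        first = (table["world_signal_channel"].astype(str) == "1").to_numpy()
    a = np.where(first[:, None], e1, e2)
    b = np.where(first[:, None], e2, e1)
    return a, b


def _cell_difference_kernels(
    table: pd.DataFrame,
    role_a: np.ndarray,
    role_b: np.ndarray,
    cell: pd.Series,
    positive_cell: str,
    negative_cell: str,
    names: tuple[str, str, str, str],
    trial_mean: bool,
) -> dict[str, KernelResult]:
    """Per-subject cell-mean differences for two channel roles + composites.

    Kernel_a = <role_a>_pos - <role_a>_neg per subject (and per frame),
    likewise kernel_b; relative = a - b and sum = a + b from the same cell
    means. Subjects missing either conditioning cell are excluded.
    """
    name_a, name_b, name_rel, name_sum = names
    if trial_mean:
        frames = ["t01"]
        a = role_a.mean(axis=1, keepdims=True)
        b = role_b.mean(axis=1, keepdims=True)
    else:
        T = role_a.shape[1]
        frames = [f"t{t:02d}" for t in range(1, T + 1)]
        a, b = role_a, role_b
    subj = table["subject_id"].to_numpy()
    df = pd.DataFrame(
        {"subject_id": subj, "cell": cell.to_numpy()},
    )
    wide_a = pd.concat([df, pd.DataFrame(a, columns=frames)], axis=1)
    wide_b = pd.concat([df, pd.DataFrame(b, columns=frames)], axis=1)
    means_a = wide_a.groupby(["subject_id", "cell"], observed=True)[frames].mean()
    means_b = wide_b.groupby(["subject_id", "cell"], observed=True)[frames].mean()
    counts = (
        df.groupby(["subject_id", "cell"], observed=True)
        .size()
        .unstack("cell", fill_value=0)
    )
    for c in (positive_cell, negative_cell):
        if c not in counts.columns:
            counts[c] = 0
    included = counts.index[
        (counts[positive_cell] > 0) & (counts[negative_cell] > 0)
    ]
    excluded = [
        (s, f"missing '{positive_cell}' or '{negative_cell}' trials")
        for s in counts.index.difference(included)
    ]

    def _diff(means: pd.DataFrame) -> pd.DataFrame:
        if len(included) == 0:
            return pd.DataFrame(columns=frames, index=included, dtype=float)
        pos = means.xs(positive_cell, level="cell").reindex(included)
        neg = means.xs(negative_cell, level="cell").reindex(included)
        return pos - neg

    kern_a = _diff(means_a)
    kern_b = _diff(means_b)
    results = {}
    for name, tc in (
        (name_a, kern_a),
        (name_b, kern_b),
        (name_rel, kern_a - kern_b),
        (name_sum, kern_a + kern_b),
    ):
        results[name] = KernelResult(
            kernel_id=name,
            per_subject_timecourse=tc,
            per_subject_window=tc.mean(axis=1),
            cell_counts=counts,
            excluded_subjects=list(excluded),
        )
    return results


# ---------------------------------------------------------------------------
# Public kernel operations
# ---------------------------------------------------------------------------


def discrimination_decision_kernels(
    table: pd.DataFrame, trial_mean: bool = True
) -> dict[str, KernelResult]:
    """Relative- and sum-evidence decision kernels, correct minus incorrect.

    Signal/nonsignal roles are assigned by the ground truth, never by the
    decision, so that evidence-weighting asymmetries cannot arise trivially
    from the conditioning itself.
    """
    disc = table[table["task"] == "discrimination"].reset_index(drop=True)
    e_s, e_n = _role_arrays(disc, by_decision=False)
    cell = disc["correct"].astype(int).map({1: "correct", 0: "incorrect"})
    all_four = _cell_difference_kernels(
        disc, e_s, e_n, cell, "correct", "incorrect",
        ("signal", "nonsignal", "relative", "sum"), trial_mean,
    )
    # E_relative = <Es-En>_C - <Es-En>_I and E_sum analogous; identical to the
    # composite of per-channel kernels, which is what _cell_difference returns.
    return {k: all_four[k] for k in DISCRIMINATION_KERNELS}


def discrimination_confidence_kernels(
    table: pd.DataFrame,
    trial_mean: bool = True,
    scope: tuple[str, ...] = ("subject_id", "session_id"),
) -> dict[str, KernelResult]:
    """Chosen/unchosen/relative/sum confidence kernels, high minus low.

    The median confidence rating within each subject-session splits trials
    into high and low; channel roles follow the subject's decision.
    """
    disc = table[table["task"] == "discrimination"].reset_index(drop=True)
    e_ch, e_un = _role_arrays(disc, by_decision=True)
    cell = _split_labels(disc, scope)
    return _cell_difference_kernels(
        disc, e_ch, e_un, cell, "high", "low",
        ("conf_chosen", "conf_unchosen", "conf_relative", "conf_sum"), trial_mean,
    )


def detection_decision_kernels(
    table: pd.DataFrame, trial_mean: bool = True
) -> dict[str, KernelResult]:
    """Signal/nonsignal/relative/sum detection kernels, yes minus no.

    Only signal-present trials enter, so the two channel roles are defined
    and their contributions can be disentangled.
    """
    det = table[
        (table["task"] == "detection")
        & (table["world_signal_channel"].astype(str) != "none")
    ].reset_index(drop=True)
    e_s, e_n = _role_arrays(det, by_decision=False)
    cell = det["decision"].astype(str)
    return _cell_difference_kernels(
        det, e_s, e_n, cell, "yes", "no",
        ("detection_s", "detection_n", "detection_relative", "detection_sum"),
        trial_mean,
    )


def detection_confidence_kernels(
    table: pd.DataFrame,
    response: str,
    trial_mean: bool = True,
    scope: tuple[str, ...] = ("subject_id", "session_id"),
) -> dict[str, KernelResult]:
    """Detection confidence kernels within one response category.

    The median split is computed within the stated response ('yes' or 'no')
    on signal-present trials; subjects with sparse cells (e.g., few misses)
    are excluded and counted.
    """
    if response not in ("yes", "no"):
        raise ValueError("response must be 'yes' or 'no'")
    present = table[
        (table["task"] == "detection")
        & (table["world_signal_channel"].astype(str) != "none")
    ]
    all_subjects = pd.unique(present["subject_id"])
    det = present[present["decision"].astype(str) == response].reset_index(drop=True)
    e_s, e_n = _role_arrays(det, by_decision=False)
    sizes = det.groupby([c for c in scope if c in det.columns], observed=True)[
        "confidence"
    ].transform("size")
    det = det[sizes >= 2].reset_index(drop=True)
    e_s, e_n = e_s[sizes.to_numpy() >= 2], e_n[sizes.to_numpy() >= 2]
    cell = _split_labels(det, scope)
    prefix = f"conf_{response}"
    results = _cell_difference_kernels(
        det, e_s, e_n, cell, "high", "low",
        (f"{prefix}_s", f"{prefix}_n", f"{prefix}_relative", f"{prefix}_sum"),
        trial_mean,
    )
    accounted = set(next(iter(results.values())).cell_counts.index)
    sparse = [
        (s, f"fewer than 2 '{response}' trials")
        for s in all_subjects
        if s not in accounted
    ]
    for kr in results.values():
        kr.excluded_subjects.extend(sparse)
    return results


# ---------------------------------------------------------------------------
# Window averaging
# ---------------------------------------------------------------------------


def window_frames(
    n_frames: int, window_ms: tuple[float, float], frame_rate_hz: float
) -> list[int]:
    """1-based frame indices whose onset lies in [start, end) milliseconds."""
    start, end = window_ms
    onsets = np.arange(n_frames) * 1000.0 / frame_rate_hz
    frames = [t + 1 for t in range(n_frames) if start <= onsets[t] < end]
    if not frames:
        raise ValueError("analysis window contains no frames")
    return frames


def window_mean(
    kernel: KernelResult,
    window_ms: tuple[float, float] = (0.0, 300.0),
    frame_rate_hz: float = 25.0,
) -> KernelResult:
    """Average the kernel time course over an early analysis window.

    The default window keeps frames whose onset falls in the first 300 ms
    (frames 1-8 at 25 Hz).
    """
    tc = kernel.per_subject_timecourse
    frames = window_frames(tc.shape[1], window_ms, frame_rate_hz)
    cols = [tc.columns[i - 1] for i in frames]
    return replace(
        kernel,
        per_subject_window=tc[cols].mean(axis=1),
        window_ms=tuple(window_ms),
        frame_rate_hz=frame_rate_hz,
    )


# ---------------------------------------------------------------------------
# Umbrella
# ---------------------------------------------------------------------------


def compute_kernels(
    table: pd.DataFrame,
    task: str,
    trial_mean: bool = True,
    center: bool = True,
    scope: tuple[str, ...] = ("subject_id", "session_id"),
) -> dict[str, KernelResult]:
    """All decision and confidence kernels for one task, on one table."""
    if center:
        table = mean_center_evidence(table)
    if task == "discrimination":
        out = discrimination_decision_kernels(table, trial_mean)
        out.update(discrimination_confidence_kernels(table, trial_mean, scope))
        return out
    if task == "detection":
        out = detection_decision_kernels(table, trial_mean)
        out.update(detection_confidence_kernels(table, "yes", trial_mean, scope))
        out.update(detection_confidence_kernels(table, "no", trial_mean, scope))
        return out
    raise ValueError(f"unknown task {task!r}")


def plot_kernel_timecourses(kernels: dict[str, KernelResult], ax=None):
    """Group-mean kernel time courses with s.e.m. bands (simple overview)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, kr in kernels.items():
        tc = kr.per_subject_timecourse
        mean = tc.mean(axis=0)
        sem = tc.std(axis=0, ddof=1) / np.sqrt(max(len(tc), 1))
        x = np.arange(1, tc.shape[1] + 1)
        ax.plot(x, mean, label=name)
        ax.fill_between(x, mean - sem, mean + sem, alpha=0.2)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("frame")
    ax.set_ylabel("kernel amplitude")
    ax.legend(fontsize="small")
    return ax
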