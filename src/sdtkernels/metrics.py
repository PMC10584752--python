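"""Response-asymmetry and metacognition summaries.

Detection responses are typically asymmetric: observers say 'yes' more often
than 'no', are more confident in 'yes' responses, and their confidence
tracks accuracy better after 'yes' than after 'no'. The functions here
quantify these asymmetries on a trial table: response proportions, mean
confidence per response, response-conditional type-2 ROC area (a
metacognitive-sensitivity index), the effect of an evidence boost on
confidence and response rates, and cross-task individual-difference
correlations of kernel amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kernels import GroupStats, group_ttest

__all__ = [
    "ResponseSummary",
    "BoostContrast",
    "response_summary",
    "type2_auc",
    "boost_contrast",
    "cross_task_correlation",
]


@dataclass
class ResponseSummary:
    """Group-level response and confidence asymmetries for one task."""

    task: str
    p_first: float  # P('yes') in detection, P('channel1') in discrimination
    mean_confidence_by_response: dict
    auc2_by_response: dict
    n_by_response: dict
    per_subject: pd.DataFrame


@dataclass
class BoostContrast:
    """Per-subject boosted-minus-standard differences with group t-tests."""

    delta_confidence: dict  # {'yes', 'no', 'discrimination'} -> per-subject Series
    delta_p_yes: pd.Series
    group: dict  # same keys plus 'p_yes' -> GroupStats


def type2_auc(correct, confidence) -> float:
    """Area under the type-2 ROC: confidence as a predictor of accuracy.

    Sweeps every observed confidence value as a criterion and plots
    P(conf >= c | correct) against P(conf >= c | incorrect); the area is
    accumulated by the trapezoid rule. Tied confidence values enter the
    curve at a single operating point. Requires at least one correct and
    one incorrect trial.
    """
    correct = np.asarray(correct, dtype=bool)
    confidence = np.asarray(confidence, dtype=float)
    n_correct = int(correct.sum())
    n_incorrect = int((~correct).sum())
    if n_correct == 0 or n_incorrect == 0:
        raise ValueError("type-2 AUC needs both correct and incorrect trials")
    thresholds = np.unique(confidence)[::-1]
    hits = [0.0]
    fas = [0.0]
    for c in thresholds:
        above = confidence >= c
        hits.append((above & correct).sum() / n_correct)
        fas.append((above & ~correct).sum() / n_incorrect)
    return float(np.trapezoid(hits, fas))


def _subject_summary(rows: pd.DataFrame, responses: tuple[str, str]) -> dict:
    out: dict = {}
    first, second = responses
    decisions = rows["decision"].astype(str)
    out["p_first"] = float((decisions == first).mean())
    for resp in responses:
        sel = rows[decisions == resp]
        out[f"n_{resp}"] = len(sel)
        out[f"conf_{resp}"] = float(sel["confidence"].mean()) if len(sel) else np.nan
        try:
            out[f"auc2_{resp}"] = type2_auc(
                sel["correct"].astype(bool), sel["confidence"]
            )
        except ValueError:
            out[f"auc2_{resp}"] = np.nan
    return out


def response_summary(table: pd.DataFrame, task: str) -> ResponseSummary:
    """Per-subject then group-aggregated response proportions, confidence
    and type-2 AUC per response category."""
    rows = table[table["task"] == task]
    if rows.empty:
        raise ValueError(f"no {task} trials in table")
    responses = ("yes", "no") if task == "detection" else ("channel1", "channel2")
    per_subject = rows.groupby("subject_id")[
        ["decision", "correct", "confidence"]
    ].apply(lambda g: pd.Series(_subject_summary(g, responses)))
    return ResponseSummary(
        task=task,
        p_first=float(per_subject["p_first"].mean()),
        mean_confidence_by_response={
            r: float(per_subject[f"conf_{r}"].mean()) for r in responses
        },
        auc2_by_response={
            r: float(per_subject[f"auc2_{r}"].mean()) for r in responses
        },
        n_by_response={r: int(per_subject[f"n_{r}"].sum()) for r in responses},
        per_subject=per_subject,
    )


def boost_contrast(table: pd.DataFrame) -> BoostContrast:
    """Effect of the evidence boost on confidence and detection responses.

    Per subject: mean confidence difference (boosted minus standard) for
    detection 'yes', detection 'no', and discrimination responses, plus the
    difference in P('yes'). Group-level paired one-sample t-tests against
    zero; subjects missing a condition cell are dropped per entry.
    """
    if "condition_boost" not in table.columns:
        raise ValueError("table has no condition_boost column")
    boost = table["condition_boost"].astype(int)
    if boost.nunique() < 2:
        raise ValueError("both boosted and standard trials are required")

    def _per_subject_delta(rows: pd.DataFrame, value: str) -> float:
        cells = rows.groupby(rows["condition_boost"].astype(int))[value].mean()
        if set(cells.index) != {0, 1}:
            return np.nan
        return float(cells[1] - cells[0])

    det = table[table["task"] == "detection"]
    disc = table[table["task"] == "discrimination"]
    delta_confidence = {}
    for key, rows in (
        ("yes", det[det["decision"].astype(str) == "yes"]),
        ("no", det[det["decision"].astype(str) == "no"]),
        ("discrimination", disc),
    ):
        delta_confidence[key] = rows.groupby("subject_id")[
            ["condition_boost", "confidence"]
        ].apply(lambda g: _per_subject_delta(g, "confidence"))
    is_yes = det.assign(is_yes=(det["decision"].astype(str) == "yes").astype(float))
    delta_p_yes = is_yes.groupby("subject_id")[["condition_boost", "is_yes"]].apply(
        lambda g: _per_subject_delta(g, "is_yes")
    )
    def _maybe_ttest(values):
        values = pd.Series(values).dropna() if len(values) else pd.Series(dtype=float)
        return group_ttest(values) if len(values) >= 2 else None

    group = {k: _maybe_ttest(v) for k, v in delta_confidence.items()}
    group["p_yes"] = _maybe_ttest(delta_p_yes)
    return BoostContrast(delta_confidence, delta_p_yes, group)


def cross_task_correlation(x, y) -> tuple[float, float]:
    """Pearson correlation of per-subject effects across two tasks.

    ``x`` and ``y`` must be paired by subject (e.g., two pd.Series indexed
    by subject id, or aligned arrays). Returns (r, two-sided p).
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        joined = pd.concat([x.rename("x"), y.rename("y")], axis=1, join="inner")
        joined = joined.dropna()
        xv, yv = joined["x"].to_numpy(), joined["y"].to_numpy()
    else:
        xv, yv = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(xv) < 3:
        raise ValueError("correlation needs at least 3 paired subjects")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(xv, yv)
    return float(r), float(p)
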