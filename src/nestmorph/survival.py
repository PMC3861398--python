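"""Evaluation layer: Kaplan-Meier/log-rank, Pearson chi-square association,
ROC for five-year recurrence, and multivariate Cox regression.

These are the standard survival-analysis stages run on the graded cohort.
Kaplan-Meier curves and Cox fits go through lifelines (Efron tie handling);
the ROC is the trapezoidal curve with a Hanley-McNeil confidence interval.
Graded/tiled variables enter the Cox model as ordinal 1/2/3 so each hazard
ratio is per one grade or tile step.  All tests are two-sided at alpha 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvRecord",
    "KMCurve",
    "RocResult",
    "CoxResult",
    "km_logrank",
    "chisq_association",
    "roc_for_recurrence",
    "cox_multivariate",
]

logger = logging.getLogger("nestmorph.survival")


@dataclass(frozen=True)
class SurvRecord:
    patient_id: str
    time: float  # months
    event: int  # 1 = recurrence/progression within follow-up
    covariates: dict | None = None

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event indicator must be 0 or 1")


@dataclass
class KMCurve:
    """Product-limit estimate: survival starts at 1 and never increases."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class RocResult:
    auc: float
    ci95: tuple[float, float]
    p_value: float  # two-sided, vs AUC = 0.5
    n_pos: int
    n_neg: int
    n_excluded: int  # censored before the horizon

    def to_dict(self) -> dict:
        return {
            "auc": float(self.auc),
            "ci95": [float(self.ci95[0]), float(self.ci95[1])],
            "p_value": float(self.p_value),
            "n_pos": int(self.n_pos),
            "n_neg": int(self.n_neg),
            "n_excluded": int(self.n_excluded),
        }


@dataclass
class CoxResult:
    summary: pd.DataFrame  # index: covariate; columns: hr, ci_low, ci_high, p
    log_likelihood: float
    n: int
    n_events: int

    def to_dict(self) -> dict:
        return {
            "covariates": {
                name: {
                    "hr": float(row["hr"]),
                    "ci_low": float(row["ci_low"]),
                    "ci_high": float(row["ci_high"]),
                    "p": float(row["p"]),
                }
                for name, row in self.summary.iterrows()
            },
            "log_likelihood": float(self.log_likelihood),
            "n": int(self.n),
            "n_events": int(self.n_events),
        }


def _as_time_event(group) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(group, pd.DataFrame):
        return group["time"].to_numpy(float), group["event"].to_numpy(int)
    if len(group) and isinstance(next(iter(group)), SurvRecord):
        recs = list(group)
        return (np.array([r.time for r in recs], float),
                np.array([r.event for r in recs], int))
    t, e = group
    return np.asarray(t, float), np.asarray(e, int)


def km_logrank(groups: Sequence) -> tuple[list[KMCurve], float, float]:
    """Kaplan-Meier curves per group plus the (k-1)-df log-rank test.

    Each group may be a DataFrame with ``time``/``event`` columns, a
    sequence of :class:`SurvRecord`, or a ``(times, events)`` pair.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    parsed = [_as_time_event(g) for g in groups]
    if any(t.size == 0 for t, _ in parsed):
        raise ValueError("every group must be non-empty")

    curves = []
    for t, e in parsed:
        kmf = KaplanMeierFitter()
        kmf.fit(t, event_observed=e)
        tl = kmf.survival_function_.index.to_numpy(float)
        sv = kmf.survival_function_.iloc[:, 0].to_numpy(float)
        ar = kmf.event_table["at_risk"].to_numpy(float)
        curves.append(KMCurve(times=tl, survival=sv, at_risk=ar))

    all_t = np.concatenate([t for t, _ in parsed])
    all_e = np.concatenate([e for _, e in parsed])
    labels = np.concatenate([np.full(t.size, i) for i, (t, _) in enumerate(parsed)])
    res = multivariate_logrank_test(all_t, labels, all_e)
    return curves, float(res.test_statistic), float(res.p_value)


def chisq_association(grade_a, grade_b) -> tuple[float, float]:
    """Pearson chi-square for independence of two categorical vectors."""
    a = pd.Categorical(np.asarray(grade_a))
    b = pd.Categorical(np.asarray(grade_b))
    if len(a.categories) < 2 or len(b.categories) < 2:
        raise ValueError("both variables need at least 2 observed levels")
    table = pd.crosstab(a, b).to_numpy()
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def roc_for_recurrence(marker_values, times, events,
                       horizon: float = 60.0) -> RocResult:
    """Trapezoidal ROC of a marker for recurrence by ``horizon`` months.

    Positives are patients with an observed event at or before the horizon;
    negatives are event-free with follow-up reaching the horizon.  Patients
    censored before the horizon carry no 5-year label and are excluded (the
    count is reported and logged).  The CI uses the Hanley-McNeil variance;
    the p-value is the two-sided normal test of AUC = 0.5.
    """
    from sklearn.metrics import roc_curve

    marker = np.asarray(marker_values, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    pos = (e == 1) & (t <= horizon)
    neg = (~pos) & (t >= horizon)
    excluded = int((~pos & ~neg).sum())
    if excluded:
        logger.info("ROC: excluded %d patients censored before the horizon",
                    excluded)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("a class is empty after horizon dichotomization")
    keep = pos | neg
    y = pos[keep].astype(int)
    x = marker[keep]
    fpr, tpr, _ = roc_curve(y, x)
    auc = float(np.trapezoid(tpr, fpr))

    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1.0 - auc) + (n_pos - 1) * (q1 - auc * auc)
           + (n_neg - 1) * (q2 - auc * auc)) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    if se > 0:
        z = (auc - 0.5) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = 1.0 if auc == 0.5 else 0.0
    return RocResult(auc=auc, ci95=(lo, hi), p_value=p,
                     n_pos=n_pos, n_neg=n_neg, n_excluded=excluded)


def cox_multivariate(df: pd.DataFrame, covariate_list: Sequence[str],
                     time_col: str = "time", event_col: str = "event") -> CoxResult:
    """Multivariate Cox proportional-hazards fit (Efron tie handling).

    Graded/tiled covariates are expected as ordinal 1/2/3 codes so the HR is
    per one grade/tile step.  Fewer than 5 events per covariate is logged as
    a warning but not fatal; degenerate (constant) covariates and
    non-convergence raise explicit errors.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    cols = list(covariate_list)
    data = df[[time_col, event_col] + cols].astype(float).copy()
    n = len(data)
    n_events = int(data[event_col].sum())
    for c in cols:
        if data[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant: degenerate design")
    if n_events < 5 * len(cols):
        logger.warning("only %d events for %d covariates (< 5 per covariate)",
                       n_events, len(cols))
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col=time_col, event_col=event_col)
    except ConvergenceError as err:
        raise RuntimeError(f"Cox model failed to converge: {err}") from err
    s = cph.summary
    summary = pd.DataFrame({
        "hr": np.exp(s["coef"]),
        "ci_low": np.exp(s["coef lower 95%"]),
        "ci_high": np.exp(s["coef upper 95%"]),
        "p": s["p"],
    })
    summary.index = s.index
    return CoxResult(summary=summary,
                     log_likelihood=float(cph.log_likelihood_),
                     n=n, n_events=n_events)
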