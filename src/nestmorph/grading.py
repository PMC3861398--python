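"""Survival-driven grading: optimal two-cutpoint search, grade assignment,
integrated scores and score tiles.

A continuous nest parameter is converted to grades I/II/III by the "best-P"
principle (the X-tile approach): exhaustively search every ordered pair of
observed distinct values (cut1 < cut2), split the cohort into

    grade I:   v <= cut1
    grade II:  cut1 < v <= cut2
    grade III: v > cut2

subject to each group holding at least ``min_frac`` of the cohort, and keep
the pair maximizing the 2-df log-rank chi-square.  Ties are broken toward
the smaller cut1, then the smaller cut2.

The uncorrected best-P p-value is anti-conservative (the maximum over many
correlated tests is compared against a fixed chi-square reference); the
result therefore also carries ``p_value_corrected``, a Bonferroni bound over
the number of candidate pairs actually evaluated, which is conservative but
honest.  Both are reported; the uncorrected value reproduces what the
best-P procedure itself reports.

Grades are mapped to scores 1/2/3 and summed into the two integrated
parameters: score1 over the negatively prognostic set {number, circularity,
total_perimeter} (range 3-9) and score2 over the positively prognostic set
{average_area, average_perimeter, ta_over_tp, avg_a_over_p} (range 4-12);
each score is re-divided into low/middle/high tiles by the same search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CutpointResult",
    "NEGATIVE_MPS",
    "POSITIVE_MPS",
    "logrank_chisq",
    "search_cutpoints",
    "assign_grades",
    "integrate",
    "tile_scores",
]

NEGATIVE_MPS = ("number", "circularity", "total_perimeter")
POSITIVE_MPS = ("average_area", "average_perimeter", "ta_over_tp", "avg_a_over_p")

GRADE_LABELS = {1: "I", 2: "II", 3: "III"}
TILE_LABELS = {1: "low", 2: "middle", 3: "high"}


@dataclass
class CutpointResult:
    parameter_name: str
    cut1: float
    cut2: float
    grade_assignment: np.ndarray  # int 1/2/3 per patient
    logrank_chisq: float  # 2 df
    p_value: float
    p_value_corrected: float  # Bonferroni over evaluated pairs
    group_sizes: tuple[int, int, int]
    n_pairs_evaluated: int = 0

    def to_dict(self) -> dict:
        return {
            "parameter_name": self.parameter_name,
            "cut1": float(self.cut1),
            "cut2": float(self.cut2),
            "logrank_chisq": float(self.logrank_chisq),
            "p_value": float(self.p_value),
            "p_value_corrected": float(self.p_value_corrected),
            "group_sizes": [int(g) for g in self.group_sizes],
            "n_pairs_evaluated": int(self.n_pairs_evaluated),
        }


# ---------------------------------------------------------------------------
# log-rank machinery
# ---------------------------------------------------------------------------

def _event_table(times: np.ndarray, events: np.ndarray):
    """Sort by time and pre-aggregate the risk/death structure.

    Returns (order, one-hot time-aggregation matrix (n, T), total deaths per
    distinct time, total at risk per distinct time).
    """
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order].astype(float)
    ut, inv = np.unique(t, return_inverse=True)
    T = ut.size
    n = t.size
    agg = np.zeros((n, T))
    agg[np.arange(n), inv] = 1.0
    d_tot = np.bincount(inv, weights=e, minlength=T)
    n_tot = np.bincount(inv, minlength=T).astype(float)
    n_risk = np.cumsum(n_tot[::-1])[::-1]
    return order, agg, d_tot, n_risk, e, inv


def _chisq_from_counts(d1, d2, r1, r2, d_tot, n_risk):
    """2-df log-rank chi-square from per-(row, time) group counts.

    d1, d2: deaths in groups 1, 2 per row and distinct time (m, T);
    r1, r2: numbers at risk (m, T); d_tot, n_risk: cohort totals (T,).
    Uses the standard hypergeometric mean/variance with the (N-d)/(N-1)
    tie factor; rows with a singular covariance get chi-square NaN.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_risk > 0, d_tot / n_risk, 0.0)
        c = np.where(n_risk > 1,
                     d_tot * (n_risk - d_tot) / np.maximum(n_risk - 1.0, 1.0),
                     0.0)
        p1 = r1 / n_risk
        p2 = r2 / n_risk
    O1 = d1.sum(axis=1)
    O2 = d2.sum(axis=1)
    E1 = (r1 * frac).sum(axis=1)
    E2 = (r2 * frac).sum(axis=1)
    v11 = (c * p1 * (1.0 - p1)).sum(axis=1)
    v22 = (c * p2 * (1.0 - p2)).sum(axis=1)
    v12 = (-c * p1 * p2).sum(axis=1)
    z1 = O1 - E1
    z2 = O2 - E2
    det = v11 * v22 - v12 * v12
    with np.errstate(divide="ignore", invalid="ignore"):
        chisq = (v22 * z1 * z1 - 2.0 * v12 * z1 * z2 + v11 * z2 * z2) / det
    chisq = np.where(det > 1e-12, chisq, np.nan)
    return chisq


def logrank_chisq(times, events, groups, n_groups: int = 3) -> float:
    """k-group log-rank chi-square ((k-1) df) for a single partition."""
    times = np.asarray(times, float)
    events = np.asarray(events)
    groups = np.asarray(groups)
    if n_groups != 3:
        # generic fallback: lifelines-equivalent computation, rarely needed
        from lifelines.statistics import multivariate_logrank_test

        return float(multivariate_logrank_test(times, groups, events).test_statistic)
    order, agg, d_tot, n_risk, e, inv = _event_table(times, events)
    g = groups[order]
    labels = np.unique(g)
    if labels.size != 3:
        raise ValueError("expected exactly 3 non-empty groups")
    m1 = (g == labels[0]).astype(float)
    m2 = (g == labels[1]).astype(float)
    d1 = (m1 * e) @ agg
    d2 = (m2 * e) @ agg
    c1 = m1 @ agg
    c2 = m2 @ agg
    r1 = np.cumsum(c1[::-1])[::-1]
    r2 = np.cumsum(c2[::-1])[::-1]
    chisq = _chisq_from_counts(d1[None, :], d2[None, :], r1[None, :], r2[None, :],
                               d_tot, n_risk)
    return float(chisq[0])


# ---------------------------------------------------------------------------
# exhaustive two-cutpoint search
# ---------------------------------------------------------------------------

def search_cutpoints(values, times, events, min_frac: float = 0.10,
                     parameter_name: str = "") -> CutpointResult:
    """Best-P two-cutpoint search over all ordered pairs of observed values.

    Evaluates the 2-df log-rank chi-square for every pair of distinct
    observed values (cut1 < cut2) whose induced three groups each hold at
    least ``min_frac`` of the cohort, and returns the maximizing pair
    (ties: smaller cut1, then smaller cut2).
    """
    values = np.asarray(values, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if not (values.shape == times.shape == events.shape):
        raise ValueError("values, times and events must have equal length")
    n = values.size
    distinct = np.unique(values)
    if distinct.size < 3:
        raise ValueError("need at least 3 distinct values to form three grades")
    if n * min_frac < 2:
        raise ValueError("cohort too small for the requested min_frac")

    # group sizes depend only on counts of values <= cut
    below = np.searchsorted(np.sort(values), distinct, side="right")
    floor = min_frac * n
    # candidate cut indices into `distinct`; cut2 takes index j > i
    i_idx, j_idx = np.triu_indices(distinct.size, k=1)
    nI = below[i_idx]
    nII = below[j_idx] - below[i_idx]
    nIII = n - below[j_idx]
    feasible = (nI >= floor) & (nII >= floor) & (nIII >= floor)
    if not feasible.any():
        raise ValueError("no feasible cutpoint pair: cohort too small or too tied")
    i_idx, j_idx = i_idx[feasible], j_idx[feasible]
    m = i_idx.size

    order, agg, d_tot, n_risk, e, inv = _event_table(times, events)
    v_sorted = values[order]
    best_chisq = -np.inf
    best_k = -1
    # evaluate in lexicographic (cut1, cut2) order so np.argmax tie-breaks
    # toward the smaller pair; chunk to bound memory
    chunk = max(1, int(2_000_000 // max(1, agg.shape[1])))
    for s in range(0, m, chunk):
        ii = i_idx[s:s + chunk]
        jj = j_idx[s:s + chunk]
        cut1 = distinct[ii][:, None]
        cut2 = distinct[jj][:, None]
        v = v_sorted[None, :]
        m1 = (v <= cut1).astype(float)
        m2 = ((v > cut1) & (v <= cut2)).astype(float)
        d1 = (m1 * e[None, :]) @ agg
        d2 = (m2 * e[None, :]) @ agg
        c1 = m1 @ agg
        c2 = m2 @ agg
        r1 = np.cumsum(c1[:, ::-1], axis=1)[:, ::-1]
        r2 = np.cumsum(c2[:, ::-1], axis=1)[:, ::-1]
        chisq = _chisq_from_counts(d1, d2, r1, r2, d_tot, n_risk)
        chisq = np.where(np.isnan(chisq), -np.inf, chisq)
        k = int(np.argmax(chisq))
        if chisq[k] > best_chisq:
            best_chisq = float(chisq[k])
            best_k = s + k
    if not np.isfinite(best_chisq):
        raise ValueError("log-rank statistic undefined for every candidate pair")

    cut1 = float(distinct[i_idx[best_k]])
    cut2 = float(distinct[j_idx[best_k]])
    grades = assign_grades(values, (cut1, cut2))
    sizes = (int((grades == 1).sum()), int((grades == 2).sum()),
             int((grades == 3).sum()))
    p = float(stats.chi2.sf(best_chisq, df=2))
    return CutpointResult(
        parameter_name=parameter_name,
        cut1=cut1,
        cut2=cut2,
        grade_assignment=grades,
        logrank_chisq=best_chisq,
        p_value=p,
        p_value_corrected=float(min(1.0, p * m)),
        group_sizes=sizes,
        n_pairs_evaluated=m,
    )


def assign_grades(values, cutpoints: tuple[float, float]) -> np.ndarray:
    """Map values to grades 1/2/3; the boundary belongs to the lower grade."""
    cut1, cut2 = cutpoints
    if not cut1 < cut2:
        raise ValueError("cut1 must be strictly below cut2")
    values = np.asarray(values, float)
    return (1 + (values > cut1).astype(int) + (values > cut2).astype(int))


def integrate(grades_by_parameter: Mapping[str, Sequence[int]],
              parameter_set: Sequence[str]) -> np.ndarray:
    """Sum grade scores (1/2/3) over a parameter set; no imputation."""
    total = None
    for name in parameter_set:
        if name not in grades_by_parameter:
            raise KeyError(f"missing grades for parameter {name!r}")
        g = np.asarray(grades_by_parameter[name])
        if np.any(~np.isin(g, (1, 2, 3))):
            raise ValueError(f"grades for {name!r} must all be in {{1, 2, 3}}")
        total = g.copy() if total is None else total + g
    if total is None:
        raise ValueError("parameter_set is empty")
    return total


def tile_scores(scores, times, events, min_frac: float = 0.10,
                parameter_name: str = "integrated") -> tuple[np.ndarray, CutpointResult]:
    """Divide integer scores into low/middle/high tiles by the same search."""
    res = search_cutpoints(scores, times, events, min_frac=min_frac,
                           parameter_name=parameter_name)
    return res.grade_assignment, res
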