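"""Statistical primitives for the methylation pipeline.

Two-group testing (Welch's t), Bonferroni adjustment, Fisher's exact test,
Pearson correlation, empirical ROC curves with Youden-index cut-offs, and
Kaplan-Meier / log-rank survival comparison.

Conventions used throughout the package
---------------------------------------
* All p-values are two-sided.
* ROC threshold candidates are the midpoints between consecutive distinct
  pooled values, with ``-inf`` / ``+inf`` sentinels, so that calls are stable
  under small measurement jitter.
* Youden ties are broken by higher sensitivity, then by the more permissive
  threshold (the one admitting more positive calls).
* A value exactly at a cut-off is *not* called positive (strict inequality).
* The Kaplan-Meier median is the first time at which S(t) <= 0.5.
* Fisher's two-sided p is the probability-mass rule: the sum of
  hypergeometric probabilities of all tables with the same margins whose
  probability does not exceed that of the observed table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank_test
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "ContingencyTable2x2",
    "RocCurve",
    "SurvivalSample",
    "ConfusionCounts",
    "KaplanMeierCurve",
    "POSITIVE_IF_LOW",
    "POSITIVE_IF_HIGH",
    "welch_t_test",
    "bonferroni_adjust",
    "fisher_exact_2x2",
    "pearson_correlation",
    "roc_curve",
    "youden_cutoff",
    "km_estimate",
    "log_rank_test",
    "confusion_metrics",
]

POSITIVE_IF_LOW = "positive-if-low"
POSITIVE_IF_HIGH = "positive-if-high"
_DIRECTIONS = (POSITIVE_IF_LOW, POSITIVE_IF_HIGH)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``df`` is the Welch-Satterthwaite value for t tests (may be fractional),
    1 for the log-rank chi-square, and ``None`` where no degrees of freedom
    apply (Fisher's exact test).
    """

    statistic: float
    p_raw: float
    df: Optional[float] = None
    p_adjusted: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0):
            raise ValueError(f"p_raw outside [0, 1]: {self.p_raw}")
        if self.p_adjusted is not None and self.p_adjusted < self.p_raw - 1e-12:
            raise ValueError("p_adjusted must be >= p_raw")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table; rows = levels of factor 1, columns = factor 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in counts):
            raise ValueError("counts must be non-negative")
        if sum(counts) == 0:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def sensitivity(self) -> float:
        """tp / (tp + fn), as a fraction."""
        if self.tp + self.fn == 0:
            raise ZeroDivisionError("no positive-class samples (tp + fn = 0)")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        """tn / (tn + fp), as a fraction."""
        if self.tn + self.fp == 0:
            raise ZeroDivisionError("no negative-class samples (tn + fp = 0)")
        return self.tn / (self.tn + self.fp)


@dataclass(frozen=True)
class SurvivalSample:
    """One follow-up record: time in days, event=True if observed (not censored)."""

    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("survival time must be non-negative")


@dataclass
class RocCurve:
    """Empirical ROC curve over midpoint threshold candidates.

    ``direction`` states which side of a threshold is called positive:
    ``positive-if-low`` calls values strictly below the threshold.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    direction: str
    n_pos: int = 0
    n_neg: int = 0


@dataclass
class KaplanMeierCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray
    survival: np.ndarray
    median: Optional[float]
    n: int

    def survival_at(self, t: float) -> float:
        """S(t); S(0) = 1 and S is constant between event times."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Welch's unequal-variance t test (two-sided).

    Degenerate case: if both groups have zero variance and equal means the
    result is statistic 0, p = 1 (no evidence, not an error).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        df = float(x.size + y.size - 2)
        if x.mean() == y.mean():
            return TestResult(statistic=0.0, p_raw=1.0, df=df)
        sign = 1.0 if x.mean() > y.mean() else -1.0
        return TestResult(statistic=sign * math.inf, p_raw=0.0, df=df)
    res = _sps.ttest_ind(x, y, equal_var=False)
    return TestResult(statistic=float(res.statistic), p_raw=float(res.pvalue), df=float(res.df))


def bonferroni_adjust(p_raw: float, m: int) -> float:
    """min(1, m * p_raw)."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if not (0.0 <= p_raw <= 1.0):
        raise ValueError(f"p_raw outside [0, 1]: {p_raw}")
    return min(1.0, m * p_raw)


def fisher_exact_2x2(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher's exact test (probability-mass rule).

    A zero row or column margin makes the table degenerate: p = 1.
    The statistic reported is the sample odds ratio (inf when b*c = 0).
    """
    arr = table.as_array()
    if 0 in arr.sum(axis=0) or 0 in arr.sum(axis=1):
        odds = math.nan
        return TestResult(statistic=odds, p_raw=1.0)
    odds, p = _sps.fisher_exact(arr, alternative="two-sided")
    return TestResult(statistic=float(odds), p_raw=float(min(p, 1.0)))


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if x.var() == 0.0 or y.var() == 0.0:
        raise ValueError("correlation undefined: zero variance")
    r = _sps.pearsonr(x, y).statistic
    return float(min(1.0, max(-1.0, r)))


def _threshold_candidates(values: np.ndarray) -> np.ndarray:
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def roc_curve(pos: Sequence[float], neg: Sequence[float], direction: str = POSITIVE_IF_LOW) -> RocCurve:
    """Empirical ROC curve for discriminating ``pos`` from ``neg``.

    AUC is computed by the trapezoid rule over the curve points, which for
    midpoint thresholds equals the tie-corrected rank statistic
    P(pos on the positive side of neg) + 0.5 * P(tie).
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    thresholds = _threshold_candidates(np.concatenate([pos, neg]))
    if direction == POSITIVE_IF_LOW:
        called_pos = pos[:, None] < thresholds[None, :]
        called_neg = neg[:, None] < thresholds[None, :]
    else:
        called_pos = pos[:, None] > thresholds[None, :]
        called_neg = neg[:, None] > thresholds[None, :]
    sens = called_pos.mean(axis=0)
    fpr = called_neg.mean(axis=0)
    order = np.lexsort((sens, fpr))  # walk the curve from (0,0) to (1,1)
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=1.0 - fpr,
        auc=auc,
        direction=direction,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


def youden_cutoff(curve: RocCurve) -> tuple[float, float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties: higher J, then higher sensitivity, then the more permissive
    threshold (larger for positive-if-low, smaller for positive-if-high).
    Returns (cutoff, sensitivity, specificity) at the chosen threshold.
    """
    j = curve.sensitivity + curve.specificity - 1.0
    permissive = curve.thresholds if curve.direction == POSITIVE_IF_LOW else -curve.thresholds
    best = max(
        range(len(curve.thresholds)),
        key=lambda i: (j[i], curve.sensitivity[i], permissive[i]),
    )
    return (
        float(curve.thresholds[best]),
        float(curve.sensitivity[best]),
        float(curve.specificity[best]),
    )


def km_estimate(samples: Sequence[SurvivalSample]) -> KaplanMeierCurve:
    """Kaplan-Meier product-limit estimate; median = first t with S(t) <= 0.5."""
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    times = np.array([s.time for s in samples], dtype=float)
    events = np.array([s.event for s in samples], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    below = np.nonzero(s <= 0.5)[0]
    median = float(t[below[0]]) if below.size else None
    return KaplanMeierCurve(times=t, survival=s, median=median, n=len(samples))


def log_rank_test(
    group_a: Sequence[SurvivalSample], group_b: Sequence[SurvivalSample]
) -> TestResult:
    """Two-group log-rank test (chi-square on 1 df); symmetric in its arguments."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    if not any(s.event for s in list(group_a) + list(group_b)):
        raise ValueError("log-rank test undefined: no events in either group")
    # canonical input order => results bit-identical under sample permutation
    a_sorted = sorted(group_a, key=lambda s: (s.time, s.event))
    b_sorted = sorted(group_b, key=lambda s: (s.time, s.event))
    ta = np.array([s.time for s in a_sorted], dtype=float)
    ea = np.array([s.event for s in a_sorted], dtype=bool)
    tb = np.array([s.time for s in b_sorted], dtype=float)
    eb = np.array([s.event for s in b_sorted], dtype=bool)
    res = _ll_logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return TestResult(statistic=float(res.test_statistic), p_raw=float(res.p_value), df=1.0)


def confusion_metrics(counts: ConfusionCounts) -> tuple[float, float]:
    """(sensitivity, specificity) in percent, rounded to 1 decimal."""
    try:
        sens = counts.sensitivity
    except ZeroDivisionError as exc:
        raise ValueError("sensitivity undefined: no ER-class samples") from exc
    try:
        spec = counts.specificity
    except ZeroDivisionError as exc:
        raise ValueError("specificity undefined: no non-ER-class samples") from exc
    return round(100.0 * sens, 1), round(100.0 * spec, 1)
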