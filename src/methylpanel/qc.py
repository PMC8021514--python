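"""Probe quality filtering and two-group differential-methylation screens.

QC removes, in order of precedence, (1) probes whose detection call
proportion across all samples falls below 90% (a sign of polymorphism at
the probe CpG) and (2) probes on chromosomes X and Y (to avoid sex-specific
methylation bias). A probe failing both criteria is counted once, under
low_call. The differential screen is a per-probe Welch t test combined with
a group-mean difference (delta-beta) filter; the Bonferroni factor is the
number of probes actually tested in that screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .data import BetaMatrix, ProbeAnnotation

__all__ = [
    "MissingDetectionError",
    "QcReport",
    "DifferentialScreenResult",
    "compute_call_proportions",
    "filter_probes",
    "differential_screen",
]

logger = logging.getLogger(__name__)


class MissingDetectionError(ValueError):
    """Detection p-values were required but not supplied."""


@dataclass
class QcReport:
    """Per-probe call proportions and exclusion bookkeeping."""

    call_proportion: Optional[pd.Series]
    excluded_by: pd.Series  # index = probe id; values in {none, low_call, sex_chromosome}
    totals: dict = field(default_factory=dict)

    @property
    def retained_probe_ids(self) -> list[str]:
        return list(self.excluded_by.index[self.excluded_by == "none"])


def compute_call_proportions(beta: BetaMatrix, detection_alpha: float = 0.01) -> pd.Series:
    """Share of samples per probe with detection p < ``detection_alpha``."""
    if beta.detection_p is None:
        raise MissingDetectionError(
            "no detection p-value matrix; supply one or skip detection QC "
            "(call_prop_min=0)"
        )
    return (beta.detection_p < detection_alpha).mean(axis=1)


def filter_probes(
    beta: BetaMatrix,
    annotation: ProbeAnnotation,
    call_prop_min: float = 0.90,
    drop_sex: bool = True,
    detection_alpha: float = 0.01,
) -> tuple[BetaMatrix, QcReport]:
    """Remove low-call probes, then X/Y probes; keep sample order intact."""
    missing = set(beta.probe_ids) - set(annotation.probe_ids)
    if missing:
        raise ValueError(f"annotation does not cover probes: {sorted(missing)[:5]}")
    probe_index = beta.beta.index
    excluded = pd.Series("none", index=probe_index, dtype=object)

    call_prop: Optional[pd.Series] = None
    if call_prop_min > 0:
        call_prop = compute_call_proportions(beta, detection_alpha)
        excluded[call_prop < call_prop_min] = "low_call"

    if drop_sex:
        sex = probe_index.isin(annotation.sex_probe_ids())
        excluded[sex & (excluded == "none").to_numpy()] = "sex_chromosome"

    retained = list(probe_index[excluded == "none"])
    if not retained:
        raise ValueError("QC removed every probe; nothing to analyze")
    totals = {
        "input": len(probe_index),
        "low_call": int((excluded == "low_call").sum()),
        "sex_chromosome": int((excluded == "sex_chromosome").sum()),
        "retained": len(retained),
    }
    logger.info("QC: %s", totals)
    if logger.isEnabledFor(logging.DEBUG):
        for probe, reason in excluded[excluded != "none"].items():
            logger.debug("excluded %s: %s", probe, reason)
    report = QcReport(call_proportion=call_prop, excluded_by=excluded, totals=totals)
    return beta.subset_probes(retained), report


@dataclass
class DifferentialScreenResult:
    """Per-probe screen table plus the screen's settings and counts.

    ``table`` columns: mean_a, mean_b, delta_beta (mean_a - mean_b),
    statistic, df, p_raw, p_adjusted, selected, direction; indexed by probe
    id. Probes with fewer than two non-missing values in either group are
    skipped (listed in ``skipped_probe_ids``) and do not enter the
    Bonferroni factor.
    """

    table: pd.DataFrame
    n_tested: int
    skipped_probe_ids: list[str]
    alpha: float
    bonferroni: bool
    delta_threshold: float

    @property
    def selected_probe_ids(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    @property
    def selected_count(self) -> int:
        return int(self.table["selected"].sum())

    @property
    def hyper_count(self) -> int:
        return int((self.table["selected"] & (self.table["direction"] == "hyper")).sum())

    @property
    def hypo_count(self) -> int:
        return int((self.table["selected"] & (self.table["direction"] == "hypo")).sum())


def differential_screen(
    beta: BetaMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    bonferroni: bool = True,
    delta_threshold: float = 0.10,
) -> DifferentialScreenResult:
    """Welch-t + delta-beta screen of every probe, group A vs group B.

    A probe is selected iff (adjusted if ``bonferroni`` else raw) p < alpha
    and |delta_beta| > delta_threshold; direction is hyper when group A's
    mean exceeds group B's. Missing betas are dropped per probe per group.
    """
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    missing = (set(group_a) | set(group_b)) - set(beta.sample_ids)
    if missing:
        raise ValueError(f"samples absent from beta matrix: {sorted(missing)[:5]}")

    a = beta.beta[group_a].to_numpy()
    b = beta.beta[group_b].to_numpy()
    n_a = (~np.isnan(a)).sum(axis=1)
    n_b = (~np.isnan(b)).sum(axis=1)
    testable = (n_a >= 2) & (n_b >= 2)
    skipped = list(beta.beta.index[~testable])
    if skipped:
        logger.info("differential_screen: skipped %d probes with <2 values per group", len(skipped))

    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # skipped (<2 values) probes legitimately yield NaN here; they are
        # dropped below, so the small-sample/empty-slice warnings are noise
        warnings.simplefilter("ignore")
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)
        res = _sps.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
    stat = np.asarray(res.statistic, dtype=float)
    p_raw = np.asarray(res.pvalue, dtype=float)
    df = np.asarray(res.df, dtype=float)
    # zero-variance-in-both degenerate probes: no evidence, p = 1
    degenerate = np.isnan(p_raw) & testable & np.isclose(mean_a, mean_b)
    stat[degenerate] = 0.0
    p_raw[degenerate] = 1.0

    m = int(testable.sum())
    if m == 0:
        raise ValueError("no probe testable: every probe has <2 values in a group")
    p_adj = np.minimum(1.0, p_raw * m)
    delta = mean_a - mean_b
    p_crit = p_adj if bonferroni else p_raw
    selected = testable & (p_crit < alpha) & (np.abs(delta) > delta_threshold)
    direction = np.where(~selected, "none", np.where(delta > 0, "hyper", "hypo"))

    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "delta_beta": delta,
            "statistic": stat,
            "df": df,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "selected": selected,
            "direction": direction,
        },
        index=beta.beta.index,
    )
    table = table[testable]
    return DifferentialScreenResult(
        table=table,
        n_tested=m,
        skipped_probe_ids=skipped,
        alpha=alpha,
        bonferroni=bonferroni,
        delta_threshold=delta_threshold,
    )
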