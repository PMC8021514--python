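"""Early-recurrence (ER) marker discovery, cut-offs, and k-of-n voting panels.

ER is defined as relapse within a window (default 183 days ~ 6 months)
after surgery. Candidate marker CpGs are screened by a raw-p Welch test
plus a delta-beta filter, then ranked by ROC AUC for discriminating ER
from non-ER patients; per-CpG cut-offs are fixed at the Youden-index
threshold with a direction derived from the sign of the group difference
(ER mean below non-ER mean => a value *below* the cut-off calls ER). A
panel is an ordered set of per-CpG criteria with a minimum positive count
k: the sample is panel-positive when at least k markers individually call
ER. Cut-offs are frozen at discovery and transferred unchanged to
validation cohorts. Pyrosequencing replicates are merged by the
duplicate-mean rule with a 10-point discordance threshold triggering a
triplicate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import BetaMatrix, ClinicalRecord, convert_scale
from .qc import differential_screen
from .stats import (
    POSITIVE_IF_HIGH,
    POSITIVE_IF_LOW,
    ConfusionCounts,
    KaplanMeierCurve,
    RocCurve,
    SurvivalSample,
    TestResult,
    confusion_metrics,
    km_estimate,
    log_rank_test,
    pearson_correlation,
    roc_curve,
    youden_cutoff,
)

__all__ = [
    "ER_BELOW",
    "ER_ABOVE",
    "NEEDS_THIRD",
    "ErLabel",
    "MarkerCriterion",
    "PanelRule",
    "PanelEvaluation",
    "CandidateMarker",
    "ConcordanceResult",
    "CalibrationResult",
    "MissingMarkerError",
    "assign_er_labels",
    "er_sample_status",
    "screen_candidates",
    "build_criterion",
    "select_top_panel",
    "call_marker",
    "call_panel",
    "evaluate_panel",
    "transfer_panel",
    "merge_replicates",
    "merge_replicate_table",
    "concordance_check",
    "calibration_linearity",
    "compare_survival",
]

logger = logging.getLogger(__name__)

ER_BELOW = "ER_below"  # call ER when value < cutoff ("ER < non-ER")
ER_ABOVE = "ER_above"  # call ER when value > cutoff ("ER > non-ER")


class MissingMarkerError(KeyError):
    """A panel criterion's probe has no measured value for this sample."""


class _NeedsThird:
    """Sentinel: duplicate measurements are discordant, a third is required."""

    def __repr__(self) -> str:  # pragma: no cover
        return "NEEDS_THIRD"


NEEDS_THIRD = _NeedsThird()


@dataclass(frozen=True)
class ErLabel:
    patient_id: str
    er: bool
    basis: str  # recurrence_within_window / recurrence_after_window / no_recurrence


@dataclass(frozen=True)
class MarkerCriterion:
    """One CpG's diagnostic rule: direction + cut-off on the percent scale."""

    probe_id: str
    cutoff: float  # percent
    direction: str  # ER_BELOW or ER_ABOVE
    auc: float
    source_position: int = 1  # Infinium site = 1; neighboring pyro CpGs numbered 2+

    def __post_init__(self) -> None:
        if self.direction not in (ER_BELOW, ER_ABOVE):
            raise ValueError(f"direction must be {ER_BELOW} or {ER_ABOVE}")
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("auc must lie in [0, 1]")
        if not (0.0 <= self.cutoff <= 100.0) and math.isfinite(self.cutoff):
            raise ValueError("cutoff must lie in [0, 100] percent")

    @property
    def key(self) -> str:
        """Identifier distinguishing neighboring CpG positions of one amplicon."""
        return f"{self.probe_id}:{self.source_position}"


@dataclass(frozen=True)
class PanelRule:
    """An ordered marker set with a minimum positive count k."""

    criteria: tuple[MarkerCriterion, ...]
    min_positive: int

    def __post_init__(self) -> None:
        if not (1 <= self.min_positive <= len(self.criteria)):
            raise ValueError("min_positive must lie in 1..len(criteria)")


@dataclass
class PanelEvaluation:
    """Confusion counts and percent metrics for every k in 1..n."""

    per_k: dict[int, ConfusionCounts]
    cohort: str = "discovery"

    def metrics(self, k: int) -> tuple[float, float]:
        """(sensitivity, specificity) in percent at the given k."""
        return confusion_metrics(self.per_k[k])

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for k in sorted(self.per_k):
            sens, spec = self.metrics(k)
            c = self.per_k[k]
            rows.append(
                {
                    "min_positive": k,
                    "tp": c.tp,
                    "fp": c.fp,
                    "tn": c.tn,
                    "fn": c.fn,
                    "sensitivity_pct": sens,
                    "specificity_pct": spec,
                    "cohort": self.cohort,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class CandidateMarker:
    probe_id: str
    delta_beta: float
    p_raw: float
    auc: float
    direction: str  # ER_BELOW / ER_ABOVE
    curve: RocCurve


@dataclass(frozen=True)
class ConcordanceResult:
    probe_id: str
    pearson_r: float
    n: int


@dataclass(frozen=True)
class CalibrationResult:
    slope: float
    intercept: float
    max_abs_residual: float
    passed: bool


def assign_er_labels(
    clinical: Iterable[ClinicalRecord], er_window_days: float = 183
) -> list[ErLabel]:
    """Label each tumor patient ER / non-ER by recurrence within the window.

    Patients without recurrence are non-ER; those whose follow-up (OS) is
    shorter than the window without recurrence are still counted non-ER but
    logged as indeterminate.
    """
    labels: dict[str, ErLabel] = {}
    for record in clinical:
        if record.tissue_group != "T":
            continue
        if record.recurrence is None:
            raise ValueError(f"{record.sample_id}: recurrence field missing")
        if record.recurrence:
            er = record.rfs_days <= er_window_days
            basis = "recurrence_within_window" if er else "recurrence_after_window"
        else:
            er = False
            basis = "no_recurrence"
            if record.os_days is not None and record.os_days < er_window_days:
                logger.warning(
                    "patient %s: follow-up %.0f d < window %.0f d without recurrence; "
                    "counted non-ER (indeterminate)",
                    record.patient_id,
                    record.os_days,
                    er_window_days,
                )
        labels[record.patient_id] = ErLabel(record.patient_id, bool(er), basis)
    return list(labels.values())


def er_sample_status(
    er_labels: Iterable[ErLabel], clinical: Iterable[ClinicalRecord]
) -> dict[str, bool]:
    """Map tumor *sample* ids to their patient's ER flag."""
    by_patient = {lab.patient_id: lab.er for lab in er_labels}
    return {
        r.sample_id: by_patient[r.patient_id]
        for r in clinical
        if r.tissue_group == "T" and r.patient_id in by_patient
    }


def screen_candidates(
    beta: BetaMatrix,
    er_status: Mapping[str, bool],
    alpha: float = 0.05,
    delta_threshold: float = 0.10,
    auc_min: float = 0.70,
) -> list[CandidateMarker]:
    """Two-stage ER marker screen on tumor samples.

    Stage 1: per-probe Welch test (raw p, no multiple-testing correction —
    this screen is deliberately uncorrected, unlike the genome-wide
    tissue-contrast screens) with |delta-beta| > ``delta_threshold``.
    Stage 2: ROC per surviving probe, direction from the sign of the group
    difference; keep AUC > ``auc_min``. Candidates are returned sorted by
    AUC (descending), ties by probe id.
    """
    er_samples = [s for s, flag in er_status.items() if flag]
    non_er_samples = [s for s, flag in er_status.items() if not flag]
    if len(er_samples) < 2 or len(non_er_samples) < 2:
        raise ValueError("need at least 2 samples in each of the ER / non-ER classes")
    screen = differential_screen(
        beta, er_samples, non_er_samples,
        alpha=alpha, bonferroni=False, delta_threshold=delta_threshold,
    )
    candidates: list[CandidateMarker] = []
    for probe_id in screen.selected_probe_ids:
        row = screen.table.loc[probe_id]
        values = beta.beta.loc[probe_id]
        pos = values[er_samples].dropna().to_numpy()
        neg = values[non_er_samples].dropna().to_numpy()
        direction = ER_BELOW if row["delta_beta"] < 0 else ER_ABOVE
        roc_dir = POSITIVE_IF_LOW if direction == ER_BELOW else POSITIVE_IF_HIGH
        curve = roc_curve(pos, neg, roc_dir)
        if curve.auc > auc_min:
            candidates.append(
                CandidateMarker(
                    probe_id=probe_id,
                    delta_beta=float(row["delta_beta"]),
                    p_raw=float(row["p_raw"]),
                    auc=curve.auc,
                    direction=direction,
                    curve=curve,
                )
            )
    candidates.sort(key=lambda c: (-c.auc, c.probe_id))
    return candidates


def build_criterion(
    curve: RocCurve,
    probe_id: str,
    direction: str,
    source_position: int = 1,
    value_scale: str = "fraction",
) -> MarkerCriterion:
    """Fix the Youden cut-off of a ROC curve as a percent-scale criterion."""
    cutoff, _, _ = youden_cutoff(curve)
    cutoff_pct = convert_scale(cutoff, to="percent", current=value_scale) if math.isfinite(cutoff) else cutoff
    return MarkerCriterion(
        probe_id=probe_id,
        cutoff=float(cutoff_pct),
        direction=direction,
        auc=curve.auc,
        source_position=source_position,
    )


def select_top_panel(
    candidates: Sequence[CandidateMarker],
    n_markers: int = 3,
    min_positive: int = 2,
    value_scale: str = "fraction",
) -> PanelRule:
    """Assemble a k-of-n panel from the top-AUC candidates."""
    if len(candidates) < n_markers:
        raise ValueError(f"only {len(candidates)} candidates for a {n_markers}-marker panel")
    chosen = sorted(candidates, key=lambda c: (-c.auc, c.probe_id))[:n_markers]
    criteria = tuple(
        build_criterion(c.curve, c.probe_id, c.direction, value_scale=value_scale)
        for c in chosen
    )
    return PanelRule(criteria=criteria, min_positive=min_positive)


def call_marker(value: float, criterion: MarkerCriterion) -> bool:
    """Single-CpG ER call on the percent scale; strict at the cut-off."""
    if not (0.0 <= value <= 100.0):
        raise ValueError(f"value {value} outside the percent scale [0, 100]")
    if criterion.direction == ER_BELOW:
        return value < criterion.cutoff
    return value > criterion.cutoff


def call_panel(values: Mapping[str, float], rule: PanelRule) -> bool:
    """k-of-n vote; requires a value for every criterion's probe."""
    positive = 0
    for criterion in rule.criteria:
        key = criterion.key if criterion.key in values else criterion.probe_id
        if key not in values:
            raise MissingMarkerError(
                f"no value for marker {criterion.probe_id} "
                f"(position {criterion.source_position})"
            )
        if call_marker(values[key], criterion):
            positive += 1
    return positive >= rule.min_positive


def evaluate_panel(
    values_per_patient: Mapping[str, Mapping[str, float]],
    er_status: Mapping[str, bool],
    rule: PanelRule,
    cohort: str = "discovery",
) -> PanelEvaluation:
    """Confusion counts and percent metrics for every k in 1..n.

    As k grows the panel gets stricter, so sensitivity is non-increasing
    and specificity non-decreasing in k; this is verified as a post-check.
    """
    missing = set(er_status) - set(values_per_patient)
    if missing:
        raise ValueError(f"patients without marker values: {sorted(missing)[:5]}")
    if not any(er_status.values()) or all(er_status.values()):
        raise ValueError("both an ER and a non-ER class are required")
    n = len(rule.criteria)
    per_k: dict[int, ConfusionCounts] = {}
    votes: dict[str, int] = {}
    for patient, flag in er_status.items():
        count = 0
        for criterion in rule.criteria:
            values = values_per_patient[patient]
            key = criterion.key if criterion.key in values else criterion.probe_id
            if key not in values:
                raise MissingMarkerError(
                    f"patient {patient}: no value for marker {criterion.probe_id}"
                )
            if call_marker(values[key], criterion):
                count += 1
        votes[patient] = count
    for k in range(1, n + 1):
        tp = sum(1 for p, f in er_status.items() if f and votes[p] >= k)
        fn = sum(1 for p, f in er_status.items() if f and votes[p] < k)
        fp = sum(1 for p, f in er_status.items() if not f and votes[p] >= k)
        tn = sum(1 for p, f in er_status.items() if not f and votes[p] < k)
        per_k[k] = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    for k in range(2, n + 1):
        assert per_k[k].tp <= per_k[k - 1].tp, "sensitivity must be non-increasing in k"
        assert per_k[k].tn >= per_k[k - 1].tn, "specificity must be non-decreasing in k"
    return PanelEvaluation(per_k=per_k, cohort=cohort)


def transfer_panel(
    rule: PanelRule,
    values_per_patient: Mapping[str, Mapping[str, float]],
    er_status: Mapping[str, bool],
) -> PanelEvaluation:
    """Apply a frozen discovery panel to a validation cohort without refitting."""
    return evaluate_panel(values_per_patient, er_status, rule, cohort="validation")


def merge_replicates(
    measurements: Sequence[float], discordance_threshold: float = 10.0
):
    """Merge duplicate/triplicate pyrosequencing measurements (percent scale).

    Two concordant values (absolute difference <= threshold points) -> their
    mean. Two discordant values -> ``NEEDS_THIRD`` sentinel. Three values ->
    their mean. The result always lies within [min, max] of the inputs.
    """
    values = [float(v) for v in measurements]
    if any(not (0.0 <= v <= 100.0) for v in values):
        raise ValueError("measurements must be on the percent scale [0, 100]")
    if len(values) == 2:
        if abs(values[0] - values[1]) > discordance_threshold:
            return NEEDS_THIRD
        return (values[0] + values[1]) / 2.0
    if len(values) == 3:
        return sum(values) / 3.0
    raise ValueError(f"need 2 or 3 measurements, got {len(values)}")


def merge_replicate_table(
    table: pd.DataFrame, discordance_threshold: float = 10.0
) -> pd.Series:
    """Merge a long replicate table (columns site, replicate, percent).

    Pairs left discordant without a third replicate raise; tables produced
    by the simulator always carry the third measurement.
    """
    merged = {}
    for site, group in table.groupby("site"):
        values = group.sort_values("replicate")["percent"].tolist()
        result = merge_replicates(values, discordance_threshold)
        if result is NEEDS_THIRD:
            raise ValueError(f"site {site}: discordant duplicates without a third replicate")
        merged[site] = result
    return pd.Series(merged, name="percent")


def concordance_check(
    pyro_percent: Mapping[str, float],
    infinium_beta: Mapping[str, float],
    probe_id: str,
) -> ConcordanceResult:
    """Pearson r between pyrosequencing percents and percent-scaled betas."""
    shared = sorted(set(pyro_percent) & set(infinium_beta))
    if len(shared) < 3:
        raise ValueError("need at least 3 paired samples")
    pyro = [pyro_percent[s] for s in shared]
    array = [convert_scale(infinium_beta[s], to="percent", current="fraction") for s in shared]
    r = pearson_correlation(pyro, array)
    return ConcordanceResult(probe_id=probe_id, pearson_r=r, n=len(shared))


def calibration_linearity(
    measured: Sequence[float], inputs: Sequence[float] = (0.0, 50.0, 100.0)
) -> CalibrationResult:
    """Least-squares line through control measurements at known input levels.

    The protocol passes when the slope lies in [0.9, 1.1] and no residual
    exceeds 5 percentage points.
    """
    x = np.asarray(inputs, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need measurements at (at least) the three control levels")
    slope, intercept = np.polyfit(x, y, 1)
    residuals = y - (slope * x + intercept)
    max_dev = float(np.max(np.abs(residuals)))
    passed = bool(0.9 <= slope <= 1.1 and max_dev <= 5.0)
    return CalibrationResult(float(slope), float(intercept), max_dev, passed)


def compare_survival(
    er_labels: Iterable[ErLabel], clinical: Iterable[ClinicalRecord]
) -> tuple[KaplanMeierCurve, KaplanMeierCurve, TestResult]:
    """Overall-survival comparison of the ER vs non-ER groups.

    Returns (KM for ER, KM for non-ER, log-rank result). Requires OS time
    and death status for every labeled patient.
    """
    er_by_patient = {lab.patient_id: lab.er for lab in er_labels}
    seen: set[str] = set()
    groups: dict[bool, list[SurvivalSample]] = {True: [], False: []}
    for record in clinical:
        if record.tissue_group != "T" or record.patient_id not in er_by_patient:
            continue
        if record.patient_id in seen:
            continue
        seen.add(record.patient_id)
        if record.os_days is None or record.dead is None:
            raise ValueError(f"patient {record.patient_id}: OS time or death status missing")
        groups[er_by_patient[record.patient_id]].append(
            SurvivalSample(time=record.os_days, event=record.dead)
        )
    km_er = km_estimate(groups[True])
    km_non_er = km_estimate(groups[False])
    result = log_rank_test(groups[True], groups[False])
    return km_er, km_non_er, result
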