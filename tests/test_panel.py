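"""ER labeling, marker cut-offs, voting panels, replicate merging, concordance."""

import numpy as np
import pytest

from methylpanel import (
    ER_ABOVE,
    ER_BELOW,
    NEEDS_THIRD,
    ClinicalRecord,
    MarkerCriterion,
    PanelRule,
    assign_er_labels,
    build_criterion,
    calibration_linearity,
    call_marker,
    call_panel,
    compare_survival,
    concordance_check,
    er_sample_status,
    evaluate_panel,
    merge_replicates,
    roc_curve,
    screen_candidates,
    select_top_panel,
    simulate_cohort,
    transfer_panel,
    SimulationConfig,
)
from methylpanel.panel import MissingMarkerError


def _tumor(patient, rfs, os_days, recurrence=True, dead=True):
    return ClinicalRecord(
        f"S{patient}", patient, "T", recurrence,
        rfs if recurrence else None, os_days, dead,
    )


class TestErLabels:
    def test_window_rule(self):
        records = [
            _tumor("P1", 120, 400),          # relapse inside the window -> ER
            _tumor("P2", 400, 700),          # relapse after the window -> non-ER
            _tumor("P3", None, 800, recurrence=False, dead=False),  # never relapsed
        ]
        labels = {l.patient_id: l for l in assign_er_labels(records)}
        assert labels["P1"].er and labels["P1"].basis == "recurrence_within_window"
        assert not labels["P2"].er and labels["P2"].basis == "recurrence_after_window"
        assert not labels["P3"].er and labels["P3"].basis == "no_recurrence"

    def test_boundary_day_is_er(self):
        labels = assign_er_labels([_tumor("P1", 183, 300)])
        assert labels[0].er

    def test_short_followup_counted_non_er_with_warning(self, caplog):
        records = [_tumor("P1", None, 100, recurrence=False, dead=False)]
        with caplog.at_level("WARNING"):
            labels = assign_er_labels(records)
        assert not labels[0].er
        assert "indeterminate" in caplog.text

    def test_non_tumor_records_ignored(self):
        records = [ClinicalRecord("C1", "PC1", "C", False), _tumor("P1", 100, 300)]
        labels = assign_er_labels(records)
        assert [l.patient_id for l in labels] == ["P1"]


class TestMarkerCalls:
    def test_table_style_below_rule(self):
        criterion = MarkerCriterion("cg17206555", 23.5, ER_BELOW, auc=0.811)
        assert call_marker(20.0, criterion)
        assert not call_marker(23.5, criterion)  # strict at the cut-off
        assert not call_marker(30.0, criterion)

    def test_table_style_above_rule(self):
        criterion = MarkerCriterion("cg02192855", 13.1, ER_ABOVE, auc=0.720)
        assert call_marker(15.0, criterion)
        assert not call_marker(13.1, criterion)

    def test_monotone_in_value(self):
        criterion = MarkerCriterion("cg1", 50.0, ER_BELOW, auc=0.8)
        calls = [call_marker(v, criterion) for v in (10, 30, 49.9, 50, 70)]
        assert calls == [True, True, True, False, False]

    def test_out_of_scale_value_rejected(self):
        with pytest.raises(ValueError):
            call_marker(120.0, MarkerCriterion("cg1", 50.0, ER_BELOW, auc=0.8))

    def test_build_criterion_converts_to_percent(self):
        curve = roc_curve([0.10, 0.20], [0.15, 0.25, 0.30], "positive-if-low")
        criterion = build_criterion(curve, "cgX", ER_BELOW)
        assert criterion.cutoff == pytest.approx(22.5)
        assert criterion.auc == pytest.approx(5 / 6)


class TestPanelVoting:
    RULE = PanelRule(
        criteria=(
            MarkerCriterion("cgA", 23.5, ER_BELOW, auc=0.81),
            MarkerCriterion("cgB", 79.0, ER_BELOW, auc=0.78),
            MarkerCriterion("cgC", 70.2, ER_BELOW, auc=0.72),
        ),
        min_positive=2,
    )

    def test_two_of_three_positive(self):
        assert call_panel({"cgA": 10.0, "cgB": 50.0, "cgC": 90.0}, self.RULE)

    def test_all_negative(self):
        values = {"cgA": 90.0, "cgB": 90.0, "cgC": 90.0}
        for k in (1, 2, 3):
            rule = PanelRule(self.RULE.criteria, k)
            assert not call_panel(values, rule)

    def test_voting_monotone_in_k(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            values = {p: float(v) for p, v in zip("ABC", rng.uniform(0, 100, 3))}
            values = {f"cg{p}": v for p, v in values.items()}
            calls = [
                call_panel(values, PanelRule(self.RULE.criteria, k)) for k in (1, 2, 3)
            ]
            # k=1 positive whenever k=2 positive, etc.
            assert all(a or not b for a, b in zip(calls, calls[1:]))

    def test_missing_marker_is_explicit(self):
        with pytest.raises(MissingMarkerError):
            call_panel({"cgA": 10.0, "cgB": 50.0}, self.RULE)


class TestEvaluatePanel:
    def test_table_counts_reproduced(self):
        # 22 ER / 60 non-ER with vote counts chosen to yield tp=18, fp=17
        # at k=2: sensitivity 81.8%, specificity 71.7%
        rule = PanelRule((MarkerCriterion("cg", 50.0, ER_BELOW, auc=0.8),) * 3, 2)
        votes_er = [3] * 12 + [2] * 6 + [1] * 3 + [0] * 1
        votes_non = [3] * 5 + [2] * 12 + [1] * 11 + [0] * 32
        values, er = {}, {}
        for i, v in enumerate(votes_er + votes_non):
            # v of the 3 identical criteria positive: v values below 50
            values[f"P{i}"] = {
                "cg": 10.0 if v > 0 else 90.0  # placeholder, replaced below
            }
        # identical probes cannot vote differently; use distinct probes per slot
        criteria = tuple(
            MarkerCriterion(f"cg{j}", 50.0, ER_BELOW, auc=0.8) for j in range(3)
        )
        rule = PanelRule(criteria, 2)
        for i, v in enumerate(votes_er + votes_non):
            values[f"P{i}"] = {f"cg{j}": (10.0 if j < v else 90.0) for j in range(3)}
        er = {f"P{i}": i < 22 for i in range(82)}
        evaluation = evaluate_panel(values, er, rule)
        assert evaluation.metrics(2) == (81.8, 71.7)
        assert evaluation.metrics(1) == (95.5, round(100 * 32 / 60, 1))
        sens = [evaluation.metrics(k)[0] for k in (1, 2, 3)]
        spec = [evaluation.metrics(k)[1] for k in (1, 2, 3)]
        assert sens == sorted(sens, reverse=True)
        assert spec == sorted(spec)

    def test_always_positive_panel(self):
        criteria = (MarkerCriterion("cg0", 100.0, ER_BELOW, auc=0.5),)
        rule = PanelRule(criteria, 1)
        values = {p: {"cg0": 10.0} for p in ("P1", "P2", "P3")}
        er = {"P1": True, "P2": False, "P3": False}
        evaluation = evaluate_panel(values, er, rule)
        assert evaluation.metrics(1) == (100.0, 0.0)

    def test_single_class_rejected(self):
        criteria = (MarkerCriterion("cg0", 50.0, ER_BELOW, auc=0.5),)
        with pytest.raises(ValueError):
            evaluate_panel({"P1": {"cg0": 1.0}}, {"P1": True}, PanelRule(criteria, 1))


class TestScreenAndTransfer:
    def _run(self, seed, null=False, layout_seed=None):
        config = SimulationConfig(
            seed=seed, n_probes=2000, n_planted_TvsC=0, n_planted_TvsN=0,
            n_planted_ER=0 if null else 3, layout_seed=layout_seed,
        )
        dataset, truth = simulate_cohort(config)
        labels = assign_er_labels(dataset.clinical)
        status = er_sample_status(labels, dataset.clinical)
        sub = dataset.beta.subset_samples(sorted(status))
        return dataset, truth, sub, status

    def test_planted_markers_retained(self):
        kept = []
        for seed in range(5):
            _, truth, sub, status = self._run(seed)
            candidates = screen_candidates(sub, status)
            found = {c.probe_id for c in candidates}
            kept.append(len(found & set(truth.er_probe_ids)))
        assert np.mean([k == 3 for k in kept]) >= 0.8

    def test_null_cohort_yields_few_survivors(self):
        counts = []
        for seed in range(5):
            _, _, sub, status = self._run(seed, null=True)
            counts.append(len(screen_candidates(sub, status)))
        assert np.mean(counts) < 5

    def test_auc_floor_zero_is_reduction(self):
        _, _, sub, status = self._run(0)
        loose = screen_candidates(sub, status, auc_min=0.0)
        strict = screen_candidates(sub, status)
        assert {c.probe_id for c in strict} <= {c.probe_id for c in loose}

    def test_frozen_panel_transfers(self):
        ok = 0
        for seed in range(5):
            _, truth, sub, status = self._run(seed)
            candidates = screen_candidates(sub, status)
            if len(candidates) < 3:
                continue
            rule = select_top_panel(candidates)
            # validation cohort: same generative layout, independent samples
            val_ds, val_truth, val_sub, val_status = self._run(seed + 1000, layout_seed=seed)
            values = {
                s: {c.probe_id: float(val_sub.beta.loc[c.probe_id, s]) * 100 for c in rule.criteria}
                for s in val_status
            }
            evaluation = transfer_panel(rule, values, val_status)
            sens, spec = evaluation.metrics(2)
            ok += sens > 60 and spec > 60
        assert ok >= 4

    def test_transfer_to_null_cohort_is_chance(self):
        _, truth, sub, status = self._run(0)
        rule = select_top_panel(screen_candidates(sub, status))
        _, _, null_sub, null_status = self._run(500, null=True)
        values = {
            s: {c.probe_id: float(null_sub.beta.loc[c.probe_id, s]) * 100 for c in rule.criteria}
            for s in null_status
        }
        evaluation = transfer_panel(rule, values, null_status)
        sens, spec = evaluation.metrics(2)
        # near-chance behavior: the panel cannot keep both rates high
        assert sens < 80 or spec < 80

    def test_missing_probe_in_validation_errors(self):
        _, _, sub, status = self._run(0)
        rule = select_top_panel(screen_candidates(sub, status))
        values = {s: {} for s in status}
        with pytest.raises(MissingMarkerError):
            transfer_panel(rule, values, status)


class TestMergeReplicates:
    def test_concordant_duplicate_mean(self):
        assert merge_replicates([30.0, 32.0]) == pytest.approx(31.0)
        assert merge_replicates([50.0, 50.0]) == 50.0

    def test_discordant_needs_third_then_triplicate_mean(self):
        assert merge_replicates([30.0, 45.0]) is NEEDS_THIRD
        assert merge_replicates([30.0, 45.0, 33.0]) == pytest.approx(36.0)

    def test_result_within_input_range(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            values = rng.uniform(0, 100, size=int(rng.integers(2, 4)))
            merged = merge_replicates(values)
            if merged is not NEEDS_THIRD:
                assert values.min() <= merged <= values.max()

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            merge_replicates([50.0])


class TestConcordanceAndCalibration:
    def test_perfect_scaling_gives_unit_correlation(self):
        betas = {f"s{i}": v for i, v in enumerate([0.1, 0.4, 0.8, 0.3])}
        pyro = {s: 100 * v for s, v in betas.items()}
        result = concordance_check(pyro, betas, "cgX")
        assert result.pearson_r == pytest.approx(1.0)
        assert result.n == 4

    def test_noisy_identity_still_strongly_correlated(self):
        rng = np.random.default_rng(21)
        betas = {f"s{i}": float(v) for i, v in enumerate(rng.uniform(0.05, 0.95, 50))}
        pyro = {
            s: float(np.clip(100 * v + rng.normal(0, 2.0), 0, 100))
            for s, v in betas.items()
        }
        assert concordance_check(pyro, betas, "cgX").pearson_r > 0.95

    def test_anticorrelated_toy(self):
        betas = {"s1": 0.1, "s2": 0.5, "s3": 0.9}
        pyro = {"s1": 90.0, "s2": 50.0, "s3": 10.0}
        assert concordance_check(pyro, betas, "cgX").pearson_r == pytest.approx(-1.0)

    def test_calibration_identity_line(self):
        result = calibration_linearity([0.0, 50.0, 100.0])
        assert result.slope == pytest.approx(1.0)
        assert result.intercept == pytest.approx(0.0)
        assert result.max_abs_residual == pytest.approx(0.0)
        assert result.passed

    def test_calibration_closed_form_least_squares(self):
        # x=(0,50,100), y=(2,51,97): slope 0.95, intercept 2.5, max |res| 1.0
        result = calibration_linearity([2.0, 51.0, 97.0])
        assert result.slope == pytest.approx(0.95)
        assert result.intercept == pytest.approx(2.5)
        assert result.max_abs_residual == pytest.approx(1.0)
        assert result.passed

    def test_flat_response_fails_linearity(self):
        result = calibration_linearity([0.0, 0.0, 0.0])
        assert result.slope == 0.0
        assert not result.passed


class TestCompareSurvival:
    def test_er_group_worse_outcome(self, small_cohort):
        dataset, _ = small_cohort
        labels = assign_er_labels(dataset.clinical)
        km_er, km_non, result = compare_survival(labels, dataset.clinical)
        assert km_er.n == 22 and km_non.n == 60
        assert km_er.median < km_non.median
        assert result.p_raw < 0.001

    def test_missing_os_rejected(self):
        records = [
            _tumor("P1", 100, None, dead=None),
            _tumor("P2", 400, 700),
        ]
        labels = assign_er_labels(records)
        with pytest.raises(ValueError, match="OS"):
            compare_survival(labels, records)
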