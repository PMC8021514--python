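"""Synthetic methylation cohorts with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: three tissue groups (C = normal control pancreas, N = non-cancerous
tissue from tumor patients, T = tumor), probe-level beta values drawn from a
two-component Beta mixture (hypo-methylated Beta(2, 8) and hyper-methylated
Beta(8, 2), matching the bimodality of array betas), planted differentially
methylated probes for the T-vs-C and T-vs-N screens, an early-recurrence
(ER) split within the T group with planted ER-marker probes, per-probe
detection p-values including planted QC failures, X/Y-annotated probes, and
noisy duplicate pyrosequencing measurements.

Planted effects shift the group mean by re-parameterizing the Beta shapes:
the shifted group draws from Beta(c1 * m1, c1 * (1 - m1)), whose mean is
exactly the target m1, with the concentration c1 chosen so that the planted
group's variance never exceeds the background component's variance
(c1 = max(c0, m1 (1 - m1) / v0 - 1), v0 the background component variance).
This moves mass smoothly inside (0, 1) — no additive offset, no clipping
bias — and keeps the within-group spread of planted probes at or below the
background spread instead of inflating it. Planted T-vs-C / T-vs-N probes are
assigned to the mixture component that leaves room for the shift
(hyper-shifts start from the low component and vice versa). ER-marker
probes are shifted *toward* the nearest boundary (er_low: low component
pushed lower in ER tumors; er_high: high component pushed higher),
mimicking the near-complete methylation loss/gain typical of usable
clinical marker CpGs; the Beta density pinches near 0 and 1, so planted
marker groups are also tighter than background, as real marker
scattergrams are.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .data import (
    BetaMatrix,
    ClinicalRecord,
    CohortDataset,
    ProbeAnnotation,
    _write_float_tsv,
    read_beta_matrix,
    read_probe_annotation,
    read_sample_sheet,
    write_beta_matrix,
    write_probe_annotation,
    write_sample_sheet,
    CPG_TYPES,
    GENE_REGIONS,
)

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "simulate_cohort",
    "simulate_pyro_replicates",
    "write_fixture_bundle",
    "read_fixture_bundle",
]

# probe truth labels
NULL = "null"
HYPER_TVC = "hyper_TvsC"
HYPO_TVC = "hypo_TvsC"
HYPER_TVN = "hyper_TvsN"
HYPO_TVN = "hypo_TvsN"
ER_LOW = "er_low"
ER_HIGH = "er_high"
QC_FAIL = "qc_fail"
SEX_CHROMOSOME = "sex_chromosome"


@dataclass
class SimulationConfig:
    """Cohort-generator settings; defaults mirror the study conditions
    (17 C / 34 N / 82 T samples, 22 of 82 tumors with early recurrence)."""

    n_C: int = 17
    n_N: int = 34
    n_T: int = 82
    n_probes: int = 5000
    n_planted_TvsC: int = 50
    n_planted_TvsN: int = 50
    n_planted_ER: int = 3
    delta_planted: float = 0.30
    delta_ER: float = 0.15
    er_fraction: float = 22 / 82
    beta_shape_low: float = 2.0
    beta_shape_high: float = 8.0
    qc_fail_fraction: float = 0.01
    sex_probe_fraction: float = 0.02
    seed: int = 0
    # probe roles / annotation are drawn from layout_seed (defaults to seed):
    # give two cohorts the same layout_seed and different seeds to simulate a
    # validation cohort from the same generative model (same planted probes,
    # independent samples)
    layout_seed: Optional[int] = None

    def validate(self) -> None:
        if min(self.n_C, self.n_N, self.n_T, self.n_probes) < 1:
            raise ValueError("sample and probe counts must be positive")
        planted = (
            self.n_planted_TvsC
            + self.n_planted_TvsN
            + self.n_planted_ER
            + round(self.qc_fail_fraction * self.n_probes)
            + round(self.sex_probe_fraction * self.n_probes)
        )
        if planted > self.n_probes:
            raise ValueError(
                f"infeasible config: {planted} special probes > {self.n_probes} probes"
            )
        for name in ("delta_planted", "delta_ER", "er_fraction", "qc_fail_fraction", "sex_probe_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.beta_shape_low <= 0 or self.beta_shape_high <= 0:
            raise ValueError("Beta shapes must be positive")
        mean_lo = self.beta_shape_low / (self.beta_shape_low + self.beta_shape_high)
        if self.n_planted_ER and self.delta_ER >= mean_lo:
            raise ValueError(
                f"delta_ER {self.delta_ER} leaves no room below the low-component mean {mean_lo}"
            )


@dataclass
class PlantedTruth:
    """Ground truth of a simulated cohort: per-probe label and per-sample ER flag."""

    probe_labels: dict[str, str]
    er_by_sample: dict[str, bool]

    def probes_with(self, label: str) -> list[str]:
        return [p for p, lab in self.probe_labels.items() if lab == label]

    @property
    def er_probe_ids(self) -> list[str]:
        return [p for p, lab in self.probe_labels.items() if lab in (ER_LOW, ER_HIGH)]

    @property
    def tvsc_probe_ids(self) -> list[str]:
        return [p for p, lab in self.probe_labels.items() if lab in (HYPER_TVC, HYPO_TVC)]

    @property
    def tvsn_probe_ids(self) -> list[str]:
        return [p for p, lab in self.probe_labels.items() if lab in (HYPER_TVN, HYPO_TVN)]


def _planted_shapes(
    target_mean: float, base_concentration: float, base_variance: float
) -> tuple[float, float]:
    """Beta shapes with the requested mean, spread capped at the background's.

    Concentration c1 = max(c0, m1 (1 - m1) / v0 - 1) gives variance
    min(v0, m1 (1 - m1) / (c0 + 1)) at mean exactly m1.
    """
    c1 = max(base_concentration, target_mean * (1.0 - target_mean) / base_variance - 1.0)
    return c1 * target_mean, c1 * (1.0 - target_mean)


def simulate_cohort(config: SimulationConfig) -> tuple[CohortDataset, PlantedTruth]:
    """Draw a full cohort plus its planted ground truth; byte-reproducible per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    rng_layout = np.random.default_rng(
        config.seed if config.layout_seed is None else config.layout_seed
    )
    n_samples = config.n_C + config.n_N + config.n_T
    sample_ids = (
        [f"C{i + 1:03d}" for i in range(config.n_C)]
        + [f"N{i + 1:03d}" for i in range(config.n_N)]
        + [f"T{i + 1:03d}" for i in range(config.n_T)]
    )
    probe_ids = [f"cg{i:08d}" for i in range(1, config.n_probes + 1)]
    t_slice = slice(config.n_C + config.n_N, n_samples)

    # --- probe roles -------------------------------------------------------
    n_qc = round(config.qc_fail_fraction * config.n_probes)
    n_sex = round(config.sex_probe_fraction * config.n_probes)
    order = rng_layout.permutation(config.n_probes)
    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        out = order[cursor : cursor + n]
        cursor += n
        return out

    idx_qc = take(n_qc)
    idx_sex = take(n_sex)
    idx_hyper_tvc = take(config.n_planted_TvsC // 2 + config.n_planted_TvsC % 2)
    idx_hypo_tvc = take(config.n_planted_TvsC // 2)
    idx_hyper_tvn = take(config.n_planted_TvsN // 2 + config.n_planted_TvsN % 2)
    idx_hypo_tvn = take(config.n_planted_TvsN // 2)
    idx_er = take(config.n_planted_ER)
    idx_er_low = idx_er[::2]  # alternate: low, high, low, ...
    idx_er_high = idx_er[1::2]

    labels = np.full(config.n_probes, NULL, dtype=object)
    labels[idx_qc] = QC_FAIL
    labels[idx_sex] = SEX_CHROMOSOME
    labels[idx_hyper_tvc] = HYPER_TVC
    labels[idx_hypo_tvc] = HYPO_TVC
    labels[idx_hyper_tvn] = HYPER_TVN
    labels[idx_hypo_tvn] = HYPO_TVN
    labels[idx_er_low] = ER_LOW
    labels[idx_er_high] = ER_HIGH

    # --- ER assignment within T -------------------------------------------
    n_er = round(config.er_fraction * config.n_T)
    er_t = np.zeros(config.n_T, dtype=bool)
    er_t[rng.choice(config.n_T, size=n_er, replace=False)] = True
    er_mask = np.zeros(n_samples, dtype=bool)
    er_mask[t_slice] = er_t

    # --- beta values --------------------------------------------------------
    a_lo, a_hi = config.beta_shape_low, config.beta_shape_high
    mean_lo = a_lo / (a_lo + a_hi)  # hypo-methylated component mean
    mean_hi = a_hi / (a_lo + a_hi)
    component_high = rng_layout.random(config.n_probes) < 0.5
    # planted probes are pinned to the component that leaves room for the shift
    component_high[idx_hyper_tvc] = False
    component_high[idx_hyper_tvn] = False
    component_high[idx_er_high] = True
    component_high[idx_hypo_tvc] = True
    component_high[idx_hypo_tvn] = True
    component_high[idx_er_low] = False

    shape_a = np.where(component_high, a_hi, a_lo).astype(float)
    shape_b = np.where(component_high, a_lo, a_hi).astype(float)
    beta = rng.beta(shape_a[:, None], shape_b[:, None], size=(config.n_probes, n_samples))

    concentration = a_lo + a_hi
    base_variance = mean_lo * mean_hi / (concentration + 1.0)  # same for both components

    def replant(idx: np.ndarray, target_mean: float, sample_mask: np.ndarray) -> None:
        if idx.size == 0 or not sample_mask.any():
            return
        a_new, b_new = _planted_shapes(target_mean, concentration, base_variance)
        draw = rng.beta(a_new, b_new, size=(idx.size, int(sample_mask.sum())))
        beta[np.ix_(idx, np.nonzero(sample_mask)[0])] = draw

    t_mask = np.zeros(n_samples, dtype=bool)
    t_mask[t_slice] = True
    # T-vs-C and T-vs-N planted probes: shift all T samples
    replant(idx_hyper_tvc, mean_lo + config.delta_planted, t_mask)
    replant(idx_hyper_tvn, mean_lo + config.delta_planted, t_mask)
    replant(idx_hypo_tvc, mean_hi - config.delta_planted, t_mask)
    replant(idx_hypo_tvn, mean_hi - config.delta_planted, t_mask)
    # ER probes: shift ER tumors only, toward the nearest boundary
    replant(idx_er_low, mean_lo - config.delta_ER, er_mask)
    replant(idx_er_high, mean_hi + config.delta_ER, er_mask)

    # --- detection p-values -------------------------------------------------
    detection = rng.uniform(0.0, 0.005, size=(config.n_probes, n_samples))
    n_fail = max(int(0.1 * n_samples) + 1, round(0.2 * n_samples))
    n_fail = min(n_fail, n_samples)
    for i in idx_qc:
        cols = rng.choice(n_samples, size=n_fail, replace=False)
        detection[i, cols] = rng.uniform(0.02, 0.5, size=n_fail)

    # --- annotation ---------------------------------------------------------
    autosomes = [str(c) for c in range(1, 23)]
    chromosome = np.array([autosomes[i % 22] for i in range(config.n_probes)], dtype=object)
    chromosome[idx_sex] = [("X" if k % 2 == 0 else "Y") for k in range(idx_sex.size)]
    gene = np.array(
        [None if rng_layout.random() < 0.2 else f"GENE{i + 1:04d}" for i in range(config.n_probes)],
        dtype=object,
    )
    annotation = ProbeAnnotation(
        pd.DataFrame(
            {
                "chromosome": chromosome,
                "position": rng_layout.integers(10_000, 100_000_000, size=config.n_probes),
                "gene_symbol": gene,
                "cpg_type": rng_layout.choice(CPG_TYPES, size=config.n_probes),
                "gene_region": rng_layout.choice(GENE_REGIONS, size=config.n_probes),
            },
            index=pd.Index(probe_ids, name="probe_id"),
        )
    )

    # --- clinical records ---------------------------------------------------
    clinical: list[ClinicalRecord] = []
    for i in range(config.n_C):
        clinical.append(
            ClinicalRecord(f"C{i + 1:03d}", f"CTRL{i + 1:03d}", "C", recurrence=False)
        )
    # Tumor patients: ER patients relapse at 60-180 d and die early; the rest
    # relapse at 200-1500 d (the study cohort had near-complete recurrence).
    rfs = np.where(
        er_t,
        rng.uniform(60.0, 180.0, size=config.n_T),
        rng.uniform(200.0, 1500.0, size=config.n_T),
    )
    os_days = rfs + np.where(
        er_t,
        rng.uniform(30.0, 240.0, size=config.n_T),
        rng.uniform(200.0, 800.0, size=config.n_T),
    )
    dead = np.where(er_t, True, rng.random(config.n_T) < 0.6)
    patient_records = [
        dict(
            patient_id=f"P{i + 1:03d}",
            recurrence=True,
            rfs_days=round(float(rfs[i]), 1),
            os_days=round(float(os_days[i]), 1),
            dead=bool(dead[i]),
        )
        for i in range(config.n_T)
    ]
    for i in range(config.n_N):  # paired non-cancerous tissue from the first n_N patients
        p = patient_records[i % config.n_T]
        clinical.append(ClinicalRecord(f"N{i + 1:03d}", p["patient_id"], "N", p["recurrence"],
                                       p["rfs_days"], p["os_days"], p["dead"]))
    for i in range(config.n_T):
        p = patient_records[i]
        clinical.append(ClinicalRecord(f"T{i + 1:03d}", p["patient_id"], "T", p["recurrence"],
                                       p["rfs_days"], p["os_days"], p["dead"]))

    matrix = BetaMatrix(
        pd.DataFrame(beta, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids),
        pd.DataFrame(detection, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids),
    )
    dataset = CohortDataset(matrix, annotation, clinical, methylation_scale="fraction")
    truth = PlantedTruth(
        probe_labels=dict(zip(probe_ids, labels)),
        er_by_sample={sid: bool(er_mask[k]) for k, sid in enumerate(sample_ids)},
    )
    return dataset, truth


def simulate_pyro_replicates(
    true_levels: Sequence[float],
    noise_sd: float = 2.0,
    discordance_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Duplicate pyrosequencing measurements (percent scale) with optional
    forced-discordant pairs that receive a third replicate.

    Returns a long table with columns site, replicate, percent; discordant
    pairs (|r1 - r2| > 10 points) carry three rows.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not (0.0 <= discordance_rate <= 1.0):
        raise ValueError("discordance_rate must be in [0, 1]")
    levels = np.asarray(true_levels, dtype=float)
    if levels.size and (levels.min() < 0 or levels.max() > 100):
        raise ValueError("true levels must be on the percent scale [0, 100]")
    rng = np.random.default_rng(seed)
    rows = []
    for site, truth in enumerate(levels):
        r1 = float(np.clip(truth + rng.normal(0.0, noise_sd), 0.0, 100.0))
        r2 = float(np.clip(truth + rng.normal(0.0, noise_sd), 0.0, 100.0))
        if rng.random() < discordance_rate:
            offset = 10.0 + abs(rng.normal(0.0, noise_sd)) + 1.0
            sign = 1.0 if (truth + offset <= 100.0) else -1.0
            r2 = float(np.clip(r1 + sign * offset, 0.0, 100.0))
        rows.append((site, 1, r1))
        rows.append((site, 2, r2))
        if abs(r1 - r2) > 10.0:
            r3 = float(np.clip(truth + rng.normal(0.0, noise_sd), 0.0, 100.0))
            rows.append((site, 3, r3))
    return pd.DataFrame(rows, columns=["site", "replicate", "percent"])


def write_fixture_bundle(
    dataset: CohortDataset, truth: PlantedTruth, directory: Union[str, Path]
) -> dict[str, Path]:
    """Write beta.tsv, detection_p.tsv, manifest.csv, samples.csv, truth.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": directory / "beta.tsv",
        "detection_p": directory / "detection_p.tsv",
        "manifest": directory / "manifest.csv",
        "samples": directory / "samples.csv",
        "truth": directory / "truth.json",
    }
    write_beta_matrix(dataset.beta, paths["beta"])
    if dataset.beta.detection_p is not None:
        _write_float_tsv(dataset.beta.detection_p, paths["detection_p"])
    else:
        paths.pop("detection_p")
    write_probe_annotation(dataset.annotation, paths["manifest"])
    write_sample_sheet(dataset.clinical, paths["samples"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {"probe_labels": truth.probe_labels, "er_by_sample": truth.er_by_sample},
            fh,
            indent=0,
            sort_keys=True,
        )
    return paths


def read_fixture_bundle(directory: Union[str, Path]) -> tuple[CohortDataset, PlantedTruth]:
    """Read back a bundle written by :func:`write_fixture_bundle`."""
    directory = Path(directory)
    detection = directory / "detection_p.tsv"
    matrix = read_beta_matrix(
        directory / "beta.tsv",
        dialect="plain-tsv",
        detection_p_path=detection if detection.exists() else None,
    )
    annotation = read_probe_annotation(directory / "manifest.csv")
    clinical = read_sample_sheet(directory / "samples.csv")
    with open(directory / "truth.json") as fh:
        raw = json.load(fh)
    truth = PlantedTruth(
        probe_labels=raw["probe_labels"],
        er_by_sample={k: bool(v) for k, v in raw["er_by_sample"].items()},
    )
    return CohortDataset(matrix, annotation, clinical), truth
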