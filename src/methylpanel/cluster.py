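"""Unsupervised cohort structure: PCA, Ward clustering, cluster-factor tests.

PCA is run on mean-centered (per probe, no variance scaling) beta values
via SVD, with the sign of each component fixed so that its
largest-magnitude probe loading is positive.

Hierarchical clustering uses the classical Ward objective on Euclidean
distances (the Ward.D2-on-Euclidean convention), implemented directly with
the Lance-Williams recurrence so that ties are broken deterministically by
the smallest member sample index — making the partition invariant to the
order samples arrive in. Merge heights are Ward distances (non-decreasing;
Ward linkage is reducible and produces no inversions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data import BetaMatrix
from .stats import ContingencyTable2x2, TestResult, fisher_exact_2x2

__all__ = [
    "PcaProjection",
    "ClusterAssignment",
    "pca_project",
    "ward_cluster",
    "associate_clusters",
]


@dataclass
class PcaProjection:
    """Sample scores and explained-variance fractions."""

    scores: pd.DataFrame  # samples x components, columns PC1..PCn
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # probes x components

    def __post_init__(self) -> None:
        evr = self.explained_variance_ratio
        if np.any(np.diff(evr) > 1e-12) or evr.sum() > 1.0 + 1e-9:
            raise ValueError("explained-variance fractions must be non-increasing, sum <= 1")


@dataclass
class ClusterAssignment:
    """Flat cut of a Ward dendrogram into k clusters.

    ``labels`` maps sample id -> 1..k; ``merge_history`` lists
    (left_members, right_members, height) in merge order, members given as
    tuples of sample ids. ``method`` records the Ward variant used.
    """

    labels: dict[str, int]
    merge_history: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    k: int
    method: str = "ward.D2-euclidean"

    def members(self, label: int) -> list[str]:
        return [s for s, lab in self.labels.items() if lab == label]

    def merge_groups(self, mapping: Mapping[int, str]) -> dict[str, str]:
        """Collapse cluster labels into named super-groups (post-hoc merge)."""
        return {s: mapping[lab] for s, lab in self.labels.items()}


def pca_project(
    beta: BetaMatrix,
    probe_subset: Optional[Sequence[str]] = None,
    n_components: int = 2,
) -> PcaProjection:
    """Project samples onto principal components of the probe space."""
    probes = list(probe_subset) if probe_subset is not None else beta.probe_ids
    if not probes:
        raise ValueError("probe subset is empty")
    X = beta.beta.loc[probes].to_numpy().T  # samples x probes
    n_samples, n_probes = X.shape
    if n_components > min(n_samples, n_probes):
        raise ValueError(
            f"n_components {n_components} exceeds min(samples, probes) = "
            f"{min(n_samples, n_probes)}"
        )
    col_means = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_means, X) - col_means
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    total_var = (S**2).sum()
    evr = (S**2) / total_var if total_var > 0 else np.zeros_like(S)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(
        (U[:, :n_components] * S[:n_components]), index=beta.sample_ids, columns=cols
    )
    loadings = pd.DataFrame(Vt[:n_components].T, index=probes, columns=cols)
    return PcaProjection(scores=scores, explained_variance_ratio=evr[:n_components], loadings=loadings)


def _ward_merge_sequence(
    points: np.ndarray,
) -> list[tuple[frozenset, frozenset, float]]:
    """Agglomerate by the Ward objective; ties broken by smallest member index.

    Returns the merge sequence with Ward (D2) heights. O(n^3); the cohorts
    this package targets have at most a few hundred samples.
    """
    n = points.shape[0]
    # squared Euclidean distances, updated by the Lance-Williams Ward rule
    diff = points[:, None, :] - points[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    clusters: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    active = sorted(clusters)
    merges: list[tuple[frozenset, frozenset, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                cost = d2[i, j]
                lo_i, lo_j = min(clusters[i]), min(clusters[j])
                key = (cost, min(lo_i, lo_j), max(lo_i, lo_j))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (_, _, _), i, j = best  # type: ignore[misc]
        left, right = clusters[i], clusters[j]
        if min(right) < min(left):
            left, right = right, left
        height = float(np.sqrt(d2[i, j]))
        merges.append((left, right, height))
        # Lance-Williams update for Ward on squared distances
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        clusters[new] = left | right
        sizes[new] = ni + nj
        d2 = np.pad(d2, ((0, 1), (0, 1)), constant_values=0.0)
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            d2[new, k] = d2[k, new] = (
                (ni + nk) * d2[i, k] + (nj + nk) * d2[j, k] - nk * d2[i, j]
            ) / (ni + nj + nk)
        active = [k for k in active if k not in (i, j)] + [new]
        active.sort()
    return merges


def ward_cluster(
    beta: BetaMatrix,
    probe_subset: Optional[Sequence[str]] = None,
    k: int = 4,
) -> ClusterAssignment:
    """Ward/Euclidean hierarchical clustering of samples, cut into k clusters."""
    probes = list(probe_subset) if probe_subset is not None else beta.probe_ids
    if not probes:
        raise ValueError("probe subset is empty")
    samples = beta.sample_ids
    if k < 1 or k > len(samples):
        raise ValueError(f"k must be in 1..{len(samples)}, got {k}")
    X = beta.beta.loc[probes].to_numpy().T
    col_means = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_means, X)
    merges = _ward_merge_sequence(X)

    # cut after n - k merges
    parts: list[frozenset] = [frozenset([i]) for i in range(len(samples))]
    for left, right, _ in merges[: len(samples) - k]:
        parts = [p for p in parts if p != left and p != right] + [left | right]
    parts.sort(key=min)
    labels: dict[str, int] = {}
    for lab, part in enumerate(parts, start=1):
        for i in part:
            labels[samples[i]] = lab
    history = [
        (
            tuple(samples[i] for i in sorted(left)),
            tuple(samples[i] for i in sorted(right)),
            height,
        )
        for left, right, height in merges
    ]
    return ClusterAssignment(labels=labels, merge_history=history, k=k)


def associate_clusters(
    grouping: Mapping[str, str],
    factor: Mapping[str, bool],
) -> tuple[ContingencyTable2x2, TestResult, dict[str, float]]:
    """Fisher test of a binary sample grouping against a binary clinical factor.

    ``grouping`` maps sample -> one of exactly two group names;
    ``factor`` maps sample -> bool. Returns the 2x2 table (rows = groups in
    sorted name order, columns = factor True/False), the Fisher result and
    per-group factor incidence in percent (1 decimal).
    """
    missing = set(grouping) - set(factor)
    if missing:
        raise ValueError(f"samples lack the clinical factor: {sorted(missing)[:5]}")
    groups = sorted(set(grouping.values()))
    if len(groups) != 2:
        raise ValueError(f"grouping must have exactly 2 levels, got {groups}")
    counts = {g: [0, 0] for g in groups}
    for sample, g in grouping.items():
        counts[g][0 if factor[sample] else 1] += 1
    (a, b), (c, d) = counts[groups[0]], counts[groups[1]]
    table = ContingencyTable2x2(a, b, c, d)
    result = fisher_exact_2x2(table)
    incidence = {
        g: round(100.0 * counts[g][0] / (counts[g][0] + counts[g][1]), 1)
        if (counts[g][0] + counts[g][1])
        else float("nan")
        for g in groups
    }
    return table, result, incidence
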