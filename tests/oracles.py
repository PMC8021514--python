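"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (enumeration, pairwise counting,
hand-transcribed formulas) and shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def fisher_enumeration_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration of tables with fixed margins."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x: int) -> float:
        # hypergeometric probability of table [[x, row1-x], [col1-x, ...]]
        return (
            math.comb(row1, x)
            * math.comb(row2, col1 - x)
            / math.comb(n, col1)
        )

    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    p_obs = prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def auc_rank_oracle(pos, neg, direction: str) -> float:
    """AUC as the pairwise rank statistic with half-credit for ties."""
    wins = ties = 0
    for p in pos:
        for q in neg:
            on_positive_side = p < q if direction == "positive-if-low" else p > q
            if on_positive_side:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def best_threshold_scan(pos, neg, direction: str):
    """Exhaustive Youden scan over a dense threshold grid (midpoints)."""
    values = sorted(set(list(pos) + list(neg)))
    mids = [(-math.inf)] + [(u + v) / 2 for u, v in zip(values, values[1:])] + [math.inf]
    best = None
    for t in mids:
        if direction == "positive-if-low":
            sens = sum(1 for p in pos if p < t) / len(pos)
            fpr = sum(1 for q in neg if q < t) / len(neg)
        else:
            sens = sum(1 for p in pos if p > t) / len(pos)
            fpr = sum(1 for q in neg if q > t) / len(neg)
        j = sens - fpr
        permissive = t if direction == "positive-if-low" else -t
        key = (j, sens, permissive)
        if best is None or key > best[0]:
            best = (key, t, sens, 1 - fpr)
    return best[1], best[2], best[3]


def km_product_limit(times, events):
    """Hand-transcribed product-limit estimator: S over distinct event times."""
    order = np.argsort(times)
    times = np.asarray(times, dtype=float)[order]
    events = np.asarray(events, dtype=bool)[order]
    s = 1.0
    out_t, out_s = [0.0], [1.0]
    for t in np.unique(times[events]):
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & events))
        s *= 1 - d / at_risk
        out_t.append(float(t))
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def logrank_chi2(times_a, events_a, times_b, events_b) -> float:
    """Standard O-E/V log-rank chi-square over pooled event times."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, bool)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, bool)
    pooled = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o_minus_e = 0.0
    var = 0.0
    for t in pooled:
        n_a = int(np.sum(ta >= t))
        n_b = int(np.sum(tb >= t))
        n = n_a + n_b
        d = int(np.sum((ta == t) & ea)) + int(np.sum((tb == t) & eb))
        d_a = int(np.sum((ta == t) & ea))
        if n == 0 or d == 0:
            continue
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def partitions_into_k(items, k):
    """All set partitions of ``items`` into exactly k non-empty blocks."""
    items = list(items)

    def rec(remaining, blocks):
        if not remaining:
            if len(blocks) == k:
                yield [tuple(b) for b in blocks]
            return
        if len(blocks) > k:
            return
        head, rest = remaining[0], remaining[1:]
        for i in range(len(blocks)):
            yield from rec(rest, blocks[:i] + [blocks[i] + [head]] + blocks[i + 1 :])
        yield from rec(rest, blocks + [[head]])

    yield from rec(items, [])


def ward_objective(points: np.ndarray, partition) -> float:
    """Total within-cluster sum of squared distances to the centroid."""
    total = 0.0
    for block in partition:
        sub = points[list(block)]
        total += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total


def best_partition(points: np.ndarray, k: int):
    """Exhaustive minimizer of the Ward objective (use only for <= ~8 points)."""
    best = None
    for partition in partitions_into_k(range(points.shape[0]), k):
        obj = ward_objective(points, partition)
        if best is None or obj < best[0]:
            best = (obj, {frozenset(b) for b in partition})
    return best[1]
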