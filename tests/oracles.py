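"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the linkage oracle
recomputes every inter-cluster distance from the original matrix by
definition at each step (no Lance-Williams recurrence), the pair-count
oracle is a plain Python loop, and KR-20 is coded from its textbook form.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def loop_pair_counts(x, y):
    """Brute-force 2x2 counts with pairwise deletion."""
    a = b = c = d = 0
    for xi, yi in zip(x, y):
        if math.isnan(xi) or math.isnan(yi):
            continue
        if xi == 1 and yi == 1:
            a += 1
        elif xi == 1 and yi == 0:
            b += 1
        elif xi == 0 and yi == 1:
            c += 1
        else:
            d += 1
    return a, b, c, d


def naive_agglomerate(mat: np.ndarray, method: str):
    """From-definition greedy agglomeration (no Lance-Williams updates).

    complete: max over cross pairs of the working matrix.
    average: mean over cross pairs.
    mcquitty (WPGMA): cross-pair mean weighted by the leaf weights implied by
        the merge history (each merge halves its side's leaf weights).
    ward_d / ward_d2: twice the increase in the dispersion functional
        E(C) = (1/|C|) * sum_{x<y in C} w(x, y), computed on raw (ward_d) or
        squared (ward_d2) dissimilarities; ward_d2 heights are square-rooted.

    Ties break by (distance, min leaf, max leaf), matching the contract of
    the implementation under test.
    """
    n = mat.shape[0]
    work = mat**2 if method == "ward_d2" else mat
    clusters = {i: [i] for i in range(n)}
    weights = {i: {i: 1.0} for i in range(n)}

    def dispersion(members):
        return sum(work[x, y] for x, y in itertools.combinations(members, 2)) / len(members)

    def dist(a, b):
        mem_a, mem_b = clusters[a], clusters[b]
        if method == "complete":
            return max(work[x, y] for x in mem_a for y in mem_b)
        if method == "average":
            return sum(work[x, y] for x in mem_a for y in mem_b) / (len(mem_a) * len(mem_b))
        if method == "mcquitty":
            return sum(
                weights[a][x] * weights[b][y] * work[x, y] for x in mem_a for y in mem_b
            )
        return 2.0 * (dispersion(mem_a + mem_b) - dispersion(mem_a) - dispersion(mem_b))

    merges = []
    active = list(range(n))
    rep = {i: i for i in range(n)}
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                u, v = active[ai], active[aj]
                dd = dist(u, v)
                lo, hi = sorted((rep[u], rep[v]))
                key = (dd, lo, hi)
                if best is None or key < best[:3]:
                    best = (dd, lo, hi, u, v)
        dd, _, _, u, v = best
        new = n + step
        left, right = (u, v) if rep[u] <= rep[v] else (v, u)
        height = math.sqrt(max(dd, 0.0)) if method == "ward_d2" else dd
        merges.append((left, right, height))
        clusters[new] = clusters[u] + clusters[v]
        weights[new] = {
            **{x: w * 0.5 for x, w in weights[u].items()},
            **{x: w * 0.5 for x, w in weights[v].items()},
        }
        rep[new] = min(rep[u], rep[v])
        active.remove(u)
        active.remove(v)
        active.append(new)
    return merges


def kr20(data: np.ndarray) -> float:
    """Kuder-Richardson formula 20 on complete binary data (rows=subjects)."""
    k = data.shape[1]
    p = data.mean(axis=0)
    item_var = p * (1.0 - p) * data.shape[0] / (data.shape[0] - 1)
    total = data.sum(axis=1)
    score_var = total.var(ddof=1)
    return k / (k - 1) * (1.0 - item_var.sum() / score_var)


def random_symmetric(rng: np.random.Generator, n: int) -> np.ndarray:
    mat = rng.random((n, n))
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 0.0)
    return mat
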