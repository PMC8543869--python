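"""Variable-mode hierarchical, divisive and fuzzy clustering.

All routines cluster the *items* of a dataset from a precomputed
dissimilarity matrix.  Agglomerative linkages (complete, average,
McQuitty/WPGMA, and both Ward variants) are implemented via the
Lance-Williams recurrence with a deterministic tie-break; DIANA follows the
Kaufman-Rousseeuw splinter algorithm; FANNY minimizes the membership-weighted
dissimilarity objective.

Trees use the scipy node convention: leaves are ``0..n-1``; the ``i``-th merge
creates node ``n + i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from itemclust.association import DissimilarityMatrix

__all__ = [
    "MergeTree",
    "Partition",
    "FuzzyMembership",
    "LINKAGE_METHODS",
    "agglomerate",
    "diana",
    "fanny",
    "cut",
    "export_newick",
]

LINKAGE_METHODS = ("ward_d", "ward_d2", "complete", "average", "mcquitty")


@dataclass
class MergeTree:
    """Dendrogram over items: an ordered list of ``n - 1`` merges."""

    labels: list[str]
    merges: list[tuple[int, int, float]]
    method: str

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != n - 1:
            raise ValueError(f"{len(self.merges)} merges for {n} leaves")
        seen: set[int] = set()
        for step, (left, right, h) in enumerate(self.merges):
            for node in (left, right):
                if node < 0 or node >= n + step:
                    raise ValueError(f"merge {step}: node {node} out of range")
                if node in seen:
                    raise ValueError(f"merge {step}: node {node} used twice")
                seen.add(node)
            if h < 0:
                raise ValueError(f"merge {step}: negative height {h}")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    def leaves_under(self, node: int) -> list[int]:
        """Leaf indices below ``node`` (a leaf is below itself)."""
        n = self.n_leaves
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                left, right, _ = self.merges[v - n]
                stack.extend((left, right))
        return sorted(out)


@dataclass
class Partition:
    """Flat assignment of items to clusters ``1..k``."""

    labels: list[str]
    assignment: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.shape != (len(self.labels),):
            raise ValueError("assignment length must match labels")
        present = set(self.assignment.tolist())
        if present != set(range(1, self.k + 1)):
            raise ValueError(f"expected clusters 1..{self.k}, found {sorted(present)}")

    def members(self, cluster: int) -> list[str]:
        return [lbl for lbl, a in zip(self.labels, self.assignment) if a == cluster]

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.labels, self.assignment.tolist()))


@dataclass
class FuzzyMembership:
    """Row-stochastic item x cluster membership from FANNY."""

    labels: list[str]
    u: np.ndarray
    objective: float
    dunn: float
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if not np.allclose(self.u.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")

    def harden(self) -> Partition:
        """Argmax assignment relabelled by first appearance."""
        raw = np.argmax(self.u, axis=1)
        return _relabel_first_appearance(self.labels, raw)


def _as_matrix(d: DissimilarityMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(d, DissimilarityMatrix):
        return d.d.copy(), list(d.labels)
    arr = np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"dissimilarity must be square, got {arr.shape}")
    if not np.allclose(arr, arr.T):
        raise ValueError("dissimilarity must be symmetric")
    if np.any(arr < 0):
        raise ValueError("dissimilarity must be non-negative")
    return arr.copy(), [f"item_{i + 1}" for i in range(arr.shape[0])]


def _relabel_first_appearance(labels: Sequence[str], raw: np.ndarray) -> Partition:
    mapping: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping) + 1
        out[i] = mapping[r]
    return Partition(labels=list(labels), assignment=out, k=len(mapping))


# --------------------------------------------------------------------------
# agglomerative linkage


def _lance_williams_update(
    method: str, d_ki: float, d_kj: float, d_ij: float, n_i: int, n_j: int, n_k: int
) -> float:
    if method == "complete":
        return max(d_ki, d_kj)
    if method == "average":
        return (n_i * d_ki + n_j * d_kj) / (n_i + n_j)
    if method == "mcquitty":
        return 0.5 * (d_ki + d_kj)
    if method in ("ward_d", "ward_d2"):
        tot = n_i + n_j + n_k
        return ((n_i + n_k) * d_ki + (n_j + n_k) * d_kj - n_k * d_ij) / tot
    raise ValueError(f"unknown linkage method {method!r}")


def agglomerate(d: DissimilarityMatrix | np.ndarray, method: str = "ward_d2") -> MergeTree:
    """Greedy agglomeration under a Lance-Williams linkage.

    ``ward_d2`` squares the dissimilarities before agglomeration and reports
    square-rooted heights (the base-R ``ward.D2`` convention); ``ward_d``
    applies the Ward coefficients to the raw dissimilarities (``ward.D``).

    Ties on the minimal distance are broken by the lexicographically smallest
    (min leaf, max leaf) representative pair, so results are reproducible
    across platforms.
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"method must be one of {LINKAGE_METHODS}, got {method!r}")
    mat, labels = _as_matrix(d)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items")

    work = mat**2 if method == "ward_d2" else mat

    size = 2 * n - 1
    dist = np.full((size, size), np.inf)
    dist[:n, :n] = work
    active: list[int] = list(range(n))
    sizes = np.ones(size, dtype=int)
    rep = np.arange(size)  # smallest leaf under each node

    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        best = None  # (distance, rep_lo, rep_hi, node_i, node_j)
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                u, v = active[ai], active[aj]
                dd = dist[u, v]
                lo, hi = sorted((rep[u], rep[v]))
                key = (dd, lo, hi)
                if best is None or key < best[:3]:
                    best = (dd, lo, hi, u, v)
        assert best is not None
        dd, _, _, u, v = best
        new = n + step
        left, right = (u, v) if rep[u] <= rep[v] else (v, u)
        height = float(np.sqrt(max(dd, 0.0))) if method == "ward_d2" else float(dd)
        merges.append((left, right, height))

        for w in active:
            if w in (u, v):
                continue
            dist[new, w] = dist[w, new] = _lance_williams_update(
                method, dist[w, u], dist[w, v], dist[u, v], sizes[u], sizes[v], sizes[w]
            )
        sizes[new] = sizes[u] + sizes[v]
        rep[new] = min(rep[u], rep[v])
        active.remove(u)
        active.remove(v)
        active.append(new)

    return MergeTree(labels=labels, merges=merges, method=method)


# --------------------------------------------------------------------------
# DIANA (divisive analysis)


def _diameter(mat: np.ndarray, members: Sequence[int]) -> float:
    if len(members) < 2:
        return 0.0
    sub = mat[np.ix_(members, members)]
    return float(sub.max())


def _splinter_split(mat: np.ndarray, members: list[int]) -> tuple[list[int], list[int]]:
    """One Kaufman-Rousseeuw split of ``members`` into (remainder, splinter)."""
    if len(members) == 2:
        return [members[0]], [members[1]]
    sub = mat[np.ix_(members, members)]
    m = len(members)
    avg_to_rest = sub.sum(axis=1) / (m - 1)
    start = int(np.argmax(avg_to_rest))  # ties: argmax takes the first (smallest index)
    splinter = [members[start]]
    remainder = [x for x in members if x != members[start]]
    while len(remainder) > 1:
        best_gain, best_obj = 0.0, None
        for obj in remainder:
            rest = [x for x in remainder if x != obj]
            d_rest = mat[obj, rest].mean()
            d_spl = mat[obj, splinter].mean()
            gain = d_rest - d_spl
            if gain > best_gain + 1e-15:
                best_gain, best_obj = gain, obj
        if best_obj is None:
            break
        remainder.remove(best_obj)
        splinter.append(best_obj)
    return remainder, splinter


def diana(d: DissimilarityMatrix | np.ndarray) -> MergeTree:
    """Divisive hierarchical clustering (DIANA).

    Starting from one all-item cluster, repeatedly splits the cluster with
    the largest diameter by seeding a splinter group with the object of
    maximal average dissimilarity and moving objects that sit closer (on
    average) to the splinter than to the remainder.  Split heights are the
    diameters of the clusters being split; read bottom-up they form the
    returned merge tree.
    """
    mat, labels = _as_matrix(d)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items")

    clusters: list[list[int]] = [sorted(range(n))]
    splits: list[tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...], float]] = []
    while any(len(c) > 1 for c in clusters):
        # split the cluster with the largest diameter; ties by smallest leaf
        cand = [(c, _diameter(mat, c)) for c in clusters if len(c) > 1]
        cand.sort(key=lambda t: (-t[1], t[0][0]))
        target, diam = cand[0]
        part_a, part_b = _splinter_split(mat, target)
        part_a, part_b = sorted(part_a), sorted(part_b)
        if part_a[0] > part_b[0]:
            part_a, part_b = part_b, part_a
        splits.append((tuple(sorted(target)), tuple(part_a), tuple(part_b), diam))
        clusters.remove(target)
        clusters.extend([part_a, part_b])

    # reverse the split history into merges (heights non-increasing downward
    # because the largest-diameter cluster is split first)
    node_of: dict[tuple[int, ...], int] = {(i,): i for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    for whole, part_a, part_b, diam in reversed(splits):
        left, right = node_of[part_a], node_of[part_b]
        if left > right and min(part_a) > min(part_b):
            left, right = right, left
        merges.append((left, right, float(diam)))
        node_of[whole] = n + len(merges) - 1
    return MergeTree(labels=labels, merges=merges, method="diana")


# --------------------------------------------------------------------------
# FANNY (fuzzy clustering)


def _fanny_objective(u: np.ndarray, mat: np.ndarray, r: float) -> float:
    ur = u**r
    obj = 0.0
    for v in range(u.shape[1]):
        den = 2.0 * ur[:, v].sum()
        if den > 0:
            obj += float(ur[:, v] @ mat @ ur[:, v]) / den
    return obj


def fanny(
    d: DissimilarityMatrix | np.ndarray,
    k: int,
    *,
    r: float = 2.0,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> FuzzyMembership:
    """Fuzzy clustering of items from a dissimilarity matrix.

    Minimizes ``sum_v [sum_ij u_iv^r u_jv^r d_ij] / [2 sum_j u_jv^r]`` by
    iterative membership updates with a monotonicity safeguard (step halving
    toward the previous memberships whenever a raw update would increase the
    objective).  Initialization is deterministic: cluster seeds are picked by
    farthest-point traversal and memberships start inversely proportional to
    seed distance.
    """
    mat, labels = _as_matrix(d)
    n = mat.shape[0]
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must be in [2, {n - 1}], got {k}")
    if r <= 1.0:
        raise ValueError("membership exponent r must exceed 1")

    if np.all(mat == 0.0):
        u = np.full((n, k), 1.0 / k)
        return FuzzyMembership(labels=labels, u=u, objective=0.0,
                               dunn=_dunn_coefficient(u), converged=True, n_iter=0)

    # deterministic farthest-point seeding
    seeds = [0]
    while len(seeds) < k:
        dist_to_seeds = mat[:, seeds].min(axis=1)
        dist_to_seeds[seeds] = -1.0
        seeds.append(int(np.argmax(dist_to_seeds)))
    eps = 1e-6 * (mat.max() or 1.0)
    u = 1.0 / (mat[:, seeds] + eps)
    u /= u.sum(axis=1, keepdims=True)

    obj = _fanny_objective(u, mat, r)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ur = u**r
        s = ur.sum(axis=0)  # per-cluster membership mass
        new = np.empty_like(u)
        for v in range(k):
            if s[v] <= 0:
                new[:, v] = 1.0 / n
                continue
            num_v = float(ur[:, v] @ mat @ ur[:, v])
            a_v = (mat @ ur[:, v]) / s[v] - num_v / (2.0 * s[v] ** 2)
            new[:, v] = a_v
        # A_iv <= 0 means item i sits inside cluster v's core: hard-assign
        for i in range(n):
            nonpos = new[i] <= 1e-14
            if nonpos.any():
                row = np.zeros(k)
                row[int(np.argmin(new[i]))] = 1.0
                new[i] = row
            else:
                w = new[i] ** (-1.0 / (r - 1.0))
                new[i] = w / w.sum()

        cand, cand_obj = new, _fanny_objective(new, mat, r)
        halvings = 0
        while cand_obj > obj + 1e-15 and halvings < 30:
            cand = 0.5 * (cand + u)
            cand_obj = _fanny_objective(cand, mat, r)
            halvings += 1
        if cand_obj > obj:  # no improving point found
            converged = True
            break
        delta = obj - cand_obj
        u, obj = cand, cand_obj
        if delta < tol:
            converged = True
            break

    return FuzzyMembership(
        labels=labels, u=u, objective=obj, dunn=_dunn_coefficient(u),
        converged=converged, n_iter=it,
    )


def _dunn_coefficient(u: np.ndarray) -> float:
    """Normalized Dunn partition coefficient in [0, 1]."""
    n, k = u.shape
    f = float((u**2).sum()) / n
    if k == 1:
        return 1.0
    return (f - 1.0 / k) / (1.0 - 1.0 / k)


# --------------------------------------------------------------------------
# tree cutting and export


def cut(tree: MergeTree, k: int) -> Partition:
    """Flat ``k``-cluster partition by undoing the last ``k - 1`` merges.

    Cluster indices are assigned by order of first-appearing leaf, so the
    labelling is deterministic and comparable across runs.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        left, right, _ = tree.merges[step]
        new = n + step
        parent[find(left)] = new
        parent[find(right)] = new

    roots = np.array([find(i) for i in range(n)])
    return _relabel_first_appearance(tree.labels, roots)


def _newick_name(label: str) -> str:
    if any(ch in label for ch in "(),:;'\" \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def export_newick(tree: MergeTree) -> str:
    """Rooted Newick string with ultrametric branch lengths.

    A node at merge height ``h`` sits at depth ``h / 2`` above the leaves, so
    a two-leaf tree at height ``h`` renders as ``(A:h/2,B:h/2);``.
    """
    n = tree.n_leaves

    def depth(node: int) -> float:
        return 0.0 if node < n else tree.merges[node - n][2] / 2.0

    def render(node: int, parent_depth: float) -> str:
        blen = max(parent_depth - depth(node), 0.0)
        if node < n:
            return f"{_newick_name(tree.labels[node])}:{blen:.10g}"
        left, right, _ = tree.merges[node - n]
        inner = f"({render(left, depth(node))},{render(right, depth(node))})"
        return f"{inner}:{blen:.10g}"

    root = 2 * n - 2
    left, right, _ = tree.merges[root - n]
    d_root = depth(root)
    return f"({render(left, d_root)},{render(right, d_root)});"
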