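"""Bootstrap co-clustering stability at fixed ``k``.

Each replicate resamples *subjects* with replacement (sample size = original
``n``), recomputes the phi-squared association matrix with pairwise deletion,
re-clusters the items and cuts at the fixed ``k``.  The co-membership matrix
records, for every item pair, the proportion of valid replicates in which the
pair shared a cluster.

Replicates where some item pair has zero complete observations are dropped
(the association is undefined there); a run with more than 5% dropped
replicates fails with diagnostics.  Constant-item degeneracies inside an
otherwise valid replicate are absorbed by the phi2 = 0 rule instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from itemclust.association import association_matrix, to_dissimilarity
from itemclust.cluster import Partition, agglomerate, cut
from itemclust.datasets import ChecklistDataset

__all__ = ["CoMembershipMatrix", "bootstrap_comembership", "within_cluster_summary"]

MAX_DROP_FRACTION = 0.05


@dataclass
class CoMembershipMatrix:
    """Pairwise co-clustering proportions over bootstrap replicates."""

    labels: list[str]
    p: np.ndarray = field(repr=False)
    B: int
    B_effective: int
    n_dropped: int
    k: int
    method: str
    seed: int

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        m = len(self.labels)
        if self.p.shape != (m, m):
            raise ValueError(f"p shape {self.p.shape} != ({m}, {m})")
        if not np.allclose(self.p, self.p.T):
            raise ValueError("co-membership matrix must be symmetric")
        if not np.allclose(np.diag(self.p), 1.0):
            raise ValueError("co-membership diagonal must be 1")
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValueError("co-membership proportions must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=self.labels, columns=self.labels)


def _replicate_comembership(
    ds: ChecklistDataset, idx: np.ndarray, method: str, k: int, dissimilarity_form: str
) -> np.ndarray | None:
    """Same-cluster indicator for one replicate; None if undefined."""
    boot = ChecklistDataset(
        subject_ids=[f"b{i}" for i in range(len(idx))],
        items=ds.items,
        responses=ds.responses[idx],
    )
    try:
        assoc = association_matrix(boot, min_pairs=1, warn_degenerate=False)
    except ValueError:
        return None  # some pair had zero complete observations
    part = cut(agglomerate(to_dissimilarity(assoc, form=dissimilarity_form), method), k)
    a = part.assignment
    return (a[:, None] == a[None, :]).astype(float)


def bootstrap_comembership(
    ds: ChecklistDataset,
    method: str = "ward_d2",
    k: int = 7,
    B: int = 1000,
    seed: int = 0,
    *,
    dissimilarity_form: str = "one_minus",
) -> CoMembershipMatrix:
    """Pairwise co-clustering proportions over ``B`` subject resamples.

    Reproducible given ``seed``: each replicate draws its resampling indices
    from an independent substream, so the run parallelizes without changing
    results.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if B < 1:
        raise ValueError("B must be >= 1")
    n = ds.n_subjects
    m = ds.n_items

    streams = np.random.SeedSequence(seed).spawn(B)
    counts = np.zeros((m, m))
    dropped = 0
    for b in range(B):
        idx = np.random.default_rng(streams[b]).integers(0, n, size=n)
        co = _replicate_comembership(ds, idx, method, k, dissimilarity_form)
        if co is None:
            dropped += 1
            continue
        counts += co

    b_eff = B - dropped
    if dropped > MAX_DROP_FRACTION * B or b_eff == 0:
        raise RuntimeError(
            f"bootstrap failed: {dropped}/{B} replicates dropped "
            f"(item pairs with zero complete observations); "
            f"n={n}, items={m}, k={k}, method={method}"
        )
    p = counts / b_eff
    np.fill_diagonal(p, 1.0)
    return CoMembershipMatrix(
        labels=ds.item_ids, p=p, B=B, B_effective=b_eff, n_dropped=dropped,
        k=k, method=method, seed=seed,
    )


def within_cluster_summary(p: CoMembershipMatrix, part: Partition) -> pd.DataFrame:
    """Per-item mean co-membership inside vs. outside its own cluster.

    Returns one row per item with the mean co-membership to its co-cluster
    members (``nan`` for singleton clusters), the other cluster maximizing the
    mean co-membership, and that mean.
    """
    if list(p.labels) != list(part.labels):
        raise ValueError("co-membership matrix and partition cover different items")
    a = part.assignment
    rows = []
    for i, label in enumerate(p.labels):
        own = a[i]
        mates = np.where((a == own) & (np.arange(len(a)) != i))[0]
        within = float(p.p[i, mates].mean()) if mates.size else np.nan
        best_other, best_mean = None, np.nan
        for c in range(1, part.k + 1):
            if c == own:
                continue
            members = np.where(a == c)[0]
            mean_c = float(p.p[i, members].mean())
            if np.isnan(best_mean) or mean_c > best_mean:
                best_other, best_mean = c, mean_c
        rows.append(
            {
                "item_id": label,
                "cluster": int(own),
                "within_mean": within,
                "best_other_cluster": best_other,
                "best_other_mean": best_mean,
            }
        )
    return pd.DataFrame(rows).set_index("item_id")
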