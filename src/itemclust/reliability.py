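"""Internal-consistency reliability and rule-based cluster integration.

Cronbach's alpha is computed from the item covariance matrix; for binary
items this is KR-20.  With missing data the covariance matrix uses
pairwise-complete observations by default (mirroring the pairwise-deletion
philosophy of the association stage); listwise deletion is available.

The integration step encodes the final review rule: an item flagged by the
bootstrap evidence is *moved* only when its strongest factor loading (mapped
through the Procrustes alignment) and its strongest cross-cluster
co-membership point at the same cluster; conflicting evidence is surfaced in
the log for expert review, never auto-resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from itemclust.bootstrap import CoMembershipMatrix, within_cluster_summary
from itemclust.cluster import Partition
from itemclust.congruence import CongruenceResult
from itemclust.datasets import ChecklistDataset
from itemclust.efa import LoadingMatrix

__all__ = [
    "DEFAULT_CLUSTER_NAMES_K7",
    "FinalClusterTable",
    "OutlierFlag",
    "alpha_from_cov",
    "cronbach_alpha",
    "reliability_report",
    "flag_outliers",
    "integrate",
]

#: Default display names used when k = 7 and no name map is supplied.
DEFAULT_CLUSTER_NAMES_K7 = (
    "Scholastic",
    "Neuropsychological",
    "ASD-like",
    "Dysregulated behaviour",
    "Overactive/Impulsive",
    "Mood/Anxiety",
    "Eat/Sleep",
)


@dataclass(frozen=True)
class OutlierFlag:
    """Bootstrap-flagged item with the evidence used by the integration rule."""

    item_id: str
    cluster: int
    within_mean: float
    best_other_cluster: int
    best_other_mean: float
    top_factor: int | None = None  # 0-based column of the loading matrix
    loading_cluster: int | None = None  # cluster aligned with that factor


@dataclass
class FinalClusterTable:
    """Ordered named clusters with alphas plus the reassignment log."""

    clusters: list[dict]
    log: pd.DataFrame = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cluster": c["index"],
                    "name": c["name"],
                    "n_items": len(c["items"]),
                    "items": ";".join(c["items"]),
                    "alpha": c["alpha"],
                }
                for c in self.clusters
            ]
        )

    def as_partition(self, labels: Sequence[str]) -> Partition:
        assign = {}
        for c in self.clusters:
            for item in c["items"]:
                assign[item] = c["index"]
        return Partition(
            labels=list(labels),
            assignment=np.array([assign[l] for l in labels]),
            k=len(self.clusters),
        )


def alpha_from_cov(cov: np.ndarray) -> float:
    """Cronbach's alpha from an item covariance matrix.

    ``alpha = k/(k-1) * (1 - sum(var_i) / var(total score))`` where the total
    score variance is the grand sum of the covariance matrix.  Returns nan
    when the total variance is not positive.
    """
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    if k < 2:
        raise ValueError("alpha requires at least 2 items")
    total = float(cov.sum())
    if total <= 0:
        return float("nan")
    return k / (k - 1) * (1.0 - float(np.trace(cov)) / total)


def cronbach_alpha(
    ds: ChecklistDataset,
    items: Sequence[str] | None = None,
    *,
    method: str = "pairwise",
) -> tuple[float, int]:
    """Cronbach's alpha (KR-20 for binary items) for an item subset.

    Returns ``(alpha, n_used)``.  ``method='pairwise'`` builds the covariance
    matrix from pairwise-complete observations and reports the smallest
    pairwise count; ``'listwise'`` drops incomplete subjects first.
    """
    frame = ds.to_frame()
    if items is not None:
        missing = [i for i in items if i not in frame.columns]
        if missing:
            raise ValueError(f"unknown items: {missing}")
        frame = frame[list(items)]
    if frame.shape[1] < 2:
        raise ValueError("alpha requires at least 2 items")

    if method == "listwise":
        frame = frame.dropna()
        n_used = len(frame)
        if n_used < 2:
            return float("nan"), n_used
        cov = frame.cov(ddof=1).to_numpy()
    elif method == "pairwise":
        cov = frame.cov(ddof=1, min_periods=2).to_numpy()
        if np.isnan(cov).any():
            return float("nan"), 0
        obs = frame.notna().to_numpy().astype(float)
        n_used = int((obs.T @ obs).min())
    else:
        raise ValueError(f"method must be 'pairwise' or 'listwise', got {method!r}")
    return alpha_from_cov(cov), n_used


def reliability_report(
    ds: ChecklistDataset, part: Partition, *, method: str = "pairwise"
) -> pd.DataFrame:
    """Per-cluster alpha table (alpha is nan for singleton clusters)."""
    rows = []
    for c in range(1, part.k + 1):
        members = part.members(c)
        if len(members) >= 2:
            alpha, n_used = cronbach_alpha(ds, members, method=method)
        else:
            alpha, n_used = float("nan"), 0
        rows.append(
            {"cluster": c, "n_items": len(members), "items": ";".join(members),
             "alpha": alpha, "n_subjects_used": n_used}
        )
    return pd.DataFrame(rows)


def flag_outliers(
    p: CoMembershipMatrix,
    part: Partition,
    L: LoadingMatrix | None = None,
    alignment: CongruenceResult | None = None,
    *,
    t_within: float = 0.10,
    r_ratio: float = 2.0,
) -> list[OutlierFlag]:
    """Flag items whose bootstrap evidence contradicts their cluster.

    An item is flagged when its mean within-cluster co-membership falls below
    ``t_within`` AND some other cluster's mean co-membership is at least
    ``r_ratio`` times the within mean.  When a loading matrix (and its
    Procrustes alignment) is supplied, the evidence records the item's
    maximal-|loading| factor and that factor's aligned cluster.
    """
    summary = within_cluster_summary(p, part)
    f2c = alignment.factor_to_cluster() if alignment is not None else None
    flags: list[OutlierFlag] = []
    for i, label in enumerate(part.labels):
        row = summary.loc[label]
        within = row["within_mean"]
        best_mean = row["best_other_mean"]
        if np.isnan(within) or np.isnan(best_mean):
            continue
        if within < t_within and best_mean >= r_ratio * within:
            top_factor = loading_cluster = None
            if L is not None:
                top_factor = int(np.argmax(np.abs(L.L[i])))
                if f2c is not None:
                    loading_cluster = f2c.get(top_factor)
            flags.append(
                OutlierFlag(
                    item_id=label,
                    cluster=int(row["cluster"]),
                    within_mean=float(within),
                    best_other_cluster=int(row["best_other_cluster"]),
                    best_other_mean=float(best_mean),
                    top_factor=top_factor,
                    loading_cluster=loading_cluster,
                )
            )
    return flags


def _cluster_names(k: int, names: Mapping[int, str] | Sequence[str] | None) -> dict[int, str]:
    if names is None:
        if k == 7:
            return {i + 1: n for i, n in enumerate(DEFAULT_CLUSTER_NAMES_K7)}
        return {i: f"cluster_{i}" for i in range(1, k + 1)}
    if not isinstance(names, Mapping):
        names = {i + 1: n for i, n in enumerate(names)}
    missing = [c for c in range(1, k + 1) if c not in names]
    if missing:
        raise ValueError(f"name map missing clusters {missing}")
    return {c: str(names[c]) for c in range(1, k + 1)}


def integrate(
    ds: ChecklistDataset,
    part: Partition,
    flags: Sequence[OutlierFlag],
    L: LoadingMatrix | None = None,
    alignment: CongruenceResult | None = None,
    *,
    names: Mapping[int, str] | Sequence[str] | None = None,
    alpha_method: str = "pairwise",
) -> FinalClusterTable:
    """Apply the two-condition reassignment rule and build the final table.

    A flagged item moves to the cluster aligned with its maximal-|loading|
    factor only when that same cluster also carries its strongest
    cross-cluster co-membership; otherwise it stays put and the conflict is
    logged.  Alphas are recomputed on the final clusters.
    """
    name_map = _cluster_names(part.k, names)
    assignment = part.assignment.copy()
    idx_of = {label: i for i, label in enumerate(part.labels)}

    log_rows = []
    for flag in flags:
        i = idx_of[flag.item_id]
        loading_cluster = flag.loading_cluster
        if loading_cluster is None and L is not None and alignment is not None:
            top = int(np.argmax(np.abs(L.L[i])))
            loading_cluster = alignment.factor_to_cluster().get(top)
        evidence = (
            f"within_p={flag.within_mean:.3f}; "
            f"best_other=cluster {flag.best_other_cluster} (p={flag.best_other_mean:.3f}); "
            f"loading->cluster {loading_cluster}"
        )
        if loading_cluster is not None and loading_cluster == flag.best_other_cluster:
            assignment[i] = loading_cluster
            log_rows.append(
                {"item_id": flag.item_id, "from": flag.cluster, "to": loading_cluster,
                 "action": "moved", "evidence": evidence}
            )
        else:
            log_rows.append(
                {"item_id": flag.item_id, "from": flag.cluster, "to": flag.cluster,
                 "action": "conflict: expert review required", "evidence": evidence}
            )

    clusters = []
    for c in range(1, part.k + 1):
        members = [part.labels[i] for i in range(len(part.labels)) if assignment[i] == c]
        if len(members) >= 2:
            alpha, _ = cronbach_alpha(ds, members, method=alpha_method)
        else:
            alpha = float("nan")
        clusters.append({"index": c, "name": name_map[c], "items": members, "alpha": alpha})

    if sorted(x for c in clusters for x in c["items"]) != sorted(part.labels):
        raise AssertionError("integration lost or duplicated items")  # invariant guard

    log = pd.DataFrame(log_rows, columns=["item_id", "from", "to", "action", "evidence"])
    return FinalClusterTable(clusters=clusters, log=log)
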