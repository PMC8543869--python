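"""Matching factor solutions to cluster solutions.

The congruence between a loading matrix and a flat item partition is scored
in three stages: (1) Tucker congruence coefficients between every factor
column and every column-normalized cluster indicator column; (2) zero-padding
of the factor x cluster congruence matrix to square whenever the number of
factors differs from the number of clusters; (3) Orthogonal Procrustes
alignment of the padded matrix, whose aligned diagonal sum (equal to the sum
of the singular values) summarizes the overall match.  A grid search ranks
extraction x rotation x factor-count combinations by that diagonal sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from itemclust.association import AssociationMatrix
from itemclust.cluster import Partition

if TYPE_CHECKING:  # pragma: no cover
    from itemclust.efa import LoadingMatrix

__all__ = [
    "CongruenceResult",
    "tucker",
    "procrustes_rotation",
    "procrustes_align",
    "indicator_matrix",
    "match_score",
    "grid_search",
]


@dataclass
class CongruenceResult:
    """Procrustes-aligned Tucker congruence of factors against clusters."""

    C_raw: np.ndarray = field(repr=False)
    T: np.ndarray = field(repr=False)
    C_aligned: np.ndarray = field(repr=False)
    diag_sum: float
    padding: int
    n_factors: int
    n_clusters: int

    def __post_init__(self) -> None:
        if not np.allclose(self.T @ self.T.T, np.eye(self.T.shape[0]), atol=1e-10):
            raise ValueError("alignment matrix must be orthogonal")

    def factor_to_cluster(self) -> dict[int, int | None]:
        """Map each real factor (0-based) to its aligned cluster (1-based).

        Aligned row ``i`` of the rotated congruence matrix corresponds to
        cluster ``i + 1``; factor ``j`` maps to the cluster whose alignment
        weight ``|T[i, j]|`` is largest.  Factors aligned onto padding rows
        map to ``None``.
        """
        out: dict[int, int | None] = {}
        for j in range(self.n_factors):
            i = int(np.argmax(np.abs(self.T[:, j])))
            out[j] = i + 1 if i < self.n_clusters else None
        return out


def tucker(x: np.ndarray, y: np.ndarray) -> float:
    """Tucker congruence coefficient of two vectors, in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    nx, ny = float(x @ x), float(y @ y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("tucker congruence undefined for a zero vector")
    return float(x @ y) / float(np.sqrt(nx * ny))


def procrustes_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Orthogonal matrix ``T`` minimizing ``||source @ T - target||_F``."""
    m = np.asarray(source, dtype=float).T @ np.asarray(target, dtype=float)
    u, _, vt = linalg.svd(m)
    return u @ vt


def procrustes_align(C: np.ndarray) -> CongruenceResult:
    """Align a factor x cluster congruence matrix by Orthogonal Procrustes.

    The matrix is zero-padded to square whenever the factor and cluster
    counts differ.  With SVD ``C = U S V^T`` the optimizer of
    ``trace(T @ C)`` over orthogonal ``T`` is ``T = V U^T``, and the aligned
    diagonal sum equals the sum of the singular values of the padded matrix.
    """
    c = np.asarray(C, dtype=float)
    if c.ndim != 2:
        raise ValueError("congruence matrix must be 2-D")
    n_f, n_c = c.shape
    s = max(n_f, n_c)
    padded = np.zeros((s, s))
    padded[:n_f, :n_c] = c
    padding = abs(n_f - n_c)

    if not np.any(padded):
        return CongruenceResult(
            C_raw=c, T=np.eye(s), C_aligned=padded, diag_sum=0.0,
            padding=padding, n_factors=n_f, n_clusters=n_c,
        )
    u, sv, vt = linalg.svd(padded)
    t = vt.T @ u.T
    aligned = t @ padded
    return CongruenceResult(
        C_raw=c, T=t, C_aligned=aligned, diag_sum=float(np.trace(aligned)),
        padding=padding, n_factors=n_f, n_clusters=n_c,
    )


def indicator_matrix(part: Partition, *, normalize: bool = True) -> np.ndarray:
    """Item x cluster membership indicator; columns optionally unit-length.

    Normalization keeps cluster size from inflating congruence values.
    """
    n = len(part.labels)
    y = np.zeros((n, part.k))
    for i, a in enumerate(part.assignment):
        y[i, a - 1] = 1.0
    if normalize:
        y = y / np.sqrt(y.sum(axis=0, keepdims=True))
    return y


def _loading_array(L: "LoadingMatrix | np.ndarray") -> tuple[np.ndarray, list[str] | None]:
    arr = getattr(L, "L", None)
    if arr is not None:
        return np.asarray(arr, dtype=float), list(L.labels)
    return np.asarray(L, dtype=float), None


def match_score(L: "LoadingMatrix | np.ndarray", part: Partition) -> CongruenceResult:
    """Procrustes-aligned Tucker congruence of a loading matrix vs. a partition."""
    arr, labels = _loading_array(L)
    if labels is not None and labels != list(part.labels):
        raise ValueError("loading matrix and partition cover different items")
    if arr.shape[0] != len(part.labels):
        raise ValueError("loading rows must match partition items")
    y = indicator_matrix(part, normalize=True)
    c_raw = np.empty((arr.shape[1], part.k))
    for f in range(arr.shape[1]):
        for c in range(part.k):
            c_raw[f, c] = tucker(arr[:, f], y[:, c])
    return procrustes_align(c_raw)


def grid_search(
    m_assoc: AssociationMatrix | np.ndarray,
    part: Partition,
    *,
    m_range: Sequence[int] = (4, 5, 6, 7),
    extractions: Sequence[str] = ("pc", "paf"),
    rotations: Sequence[str] = ("none", "varimax", "quartimax", "promax", "oblimin", "cluster_target"),
    cutoff: float = 0.35,
) -> tuple[pd.DataFrame, "LoadingMatrix | None"]:
    """Rank extraction x rotation x m combinations by aligned congruence.

    Failed combinations are recorded (status ``failed``) and the search
    continues.  Ties in ``diag_sum`` break by lexical (extraction, rotation,
    m) order.  Returns the ranked table and the winning loading matrix.
    """
    from itemclust import efa  # local import to avoid a module cycle

    combos = sorted({(e, r, int(m)) for e in extractions for r in rotations for m in m_range})
    if not combos:
        raise ValueError("empty search grid")

    target = indicator_matrix(part, normalize=True)
    rows = []
    best_key: tuple[float, str, str, int] | None = None
    winner: "efa.LoadingMatrix | None" = None
    for extraction, rotation, m in combos:
        try:
            loadings = efa.extract(m_assoc, m, extraction)
            loadings = efa.rotate(loadings, rotation, target=target)
            result = match_score(loadings, part)
            diag_sum: float = result.diag_sum
            status = "ok"
        except Exception as exc:  # noqa: BLE001 - grid must survive bad cells
            diag_sum, status = np.nan, f"failed: {exc}"
            loadings = None
        rows.append(
            {"extraction": extraction, "rotation": rotation, "m": m,
             "diag_sum": diag_sum, "status": status}
        )
        if loadings is not None:
            key = (-diag_sum, extraction, rotation, m)
            if best_key is None or key < best_key:
                best_key, winner = key, loadings

    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["diag_sum", "extraction", "rotation", "m"],
        ascending=[False, True, True, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    return table, winner
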