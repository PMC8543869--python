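"""Mean-squared-contingency (phi-squared) association between binary items.

For a pair of binary items cross-classified into a 2x2 table with counts
``a`` (1,1), ``b`` (1,0), ``c`` (0,1), ``d`` (0,0) over the subjects observed
on *both* items (pairwise deletion),

    phi2 = (a*d - b*c)**2 / ((a+b) * (c+d) * (a+c) * (b+d))

which equals the Pearson chi-squared statistic of the table divided by the
number of complete pairs.  phi2 lives in [0, 1]; ``1 - phi2`` is the
dissimilarity handed to the clustering stage.

Degenerate margins (an item constant within the complete pairs) carry no
association evidence; phi2 is defined as 0 there and a warning is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from itemclust.datasets import ChecklistDataset

__all__ = [
    "PairTable",
    "AssociationMatrix",
    "DissimilarityMatrix",
    "pair_table",
    "phi2",
    "association_matrix",
    "to_dissimilarity",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairTable:
    """2x2 cross-classification counts over complete pairs."""

    a: int  # item1 = 1, item2 = 1
    b: int  # item1 = 1, item2 = 0
    c: int  # item1 = 0, item2 = 1
    d: int  # item1 = 0, item2 = 0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n_complete(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        """Row and column margins (a+b, c+d, a+c, b+d)."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass
class AssociationMatrix:
    """Symmetric item x item phi2 matrix with complete-pair counts."""

    labels: list[str]
    phi2: np.ndarray = field(repr=False)
    n_pairs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.phi2 = np.asarray(self.phi2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs)
        k = len(self.labels)
        if self.phi2.shape != (k, k):
            raise ValueError(f"phi2 shape {self.phi2.shape} != ({k}, {k})")
        if not np.allclose(self.phi2, self.phi2.T):
            raise ValueError("phi2 matrix must be symmetric")
        if not np.allclose(np.diag(self.phi2), 1.0):
            raise ValueError("phi2 diagonal must be 1")
        if np.any(self.phi2 < -1e-12) or np.any(self.phi2 > 1 + 1e-12):
            raise ValueError("phi2 entries must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phi2, index=self.labels, columns=self.labels)


@dataclass
class DissimilarityMatrix:
    """Symmetric dissimilarity with zero diagonal, entries in [0, 1]."""

    labels: list[str]
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        k = len(self.labels)
        if self.d.shape != (k, k):
            raise ValueError(f"d shape {self.d.shape} != ({k}, {k})")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("dissimilarity must be symmetric")
        if np.any(np.diag(self.d) != 0.0):
            raise ValueError("dissimilarity diagonal must be 0")
        if np.any(self.d < -1e-12):
            raise ValueError("dissimilarity entries must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def pair_table(x: np.ndarray, y: np.ndarray) -> PairTable:
    """Cross-classify two binary-with-missing vectors over complete pairs.

    Indices where either value is missing (nan) are dropped (pairwise
    deletion).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    ok = ~(np.isnan(x) | np.isnan(y))
    xo, yo = x[ok], y[ok]
    a = int(np.sum((xo == 1) & (yo == 1)))
    b = int(np.sum((xo == 1) & (yo == 0)))
    c = int(np.sum((xo == 0) & (yo == 1)))
    d = int(np.sum((xo == 0) & (yo == 0)))
    return PairTable(a, b, c, d)


def phi2(t: PairTable) -> float:
    """Mean squared contingency coefficient of a 2x2 table.

    Equals chi-squared / n_complete.  Returns 0.0 when any margin is zero
    (constant item: no association evidence).
    """
    r1, r0, c1, c0 = t.margins()
    denom = float(r1) * r0 * c1 * c0
    if denom == 0.0:
        logger.debug("degenerate 2x2 margins %s -> phi2 = 0", t)
        return 0.0
    num = float(t.a) * t.d - float(t.b) * t.c
    return (num * num) / denom


def _counts_matrix(responses: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized pairwise 2x2 counts for all item pairs."""
    obs = ~np.isnan(responses)
    ones = np.where(obs, responses == 1.0, False).astype(float)
    zeros = np.where(obs, responses == 0.0, False).astype(float)
    a = ones.T @ ones
    b = ones.T @ zeros
    c = zeros.T @ ones
    d = zeros.T @ zeros
    return a, b, c, d


def association_matrix(
    ds: ChecklistDataset, *, min_pairs: int = 2, warn_degenerate: bool = True
) -> AssociationMatrix:
    """phi2 matrix over all item pairs with pairwise deletion.

    Raises ``ValueError`` naming the first offending pair whose complete-pair
    count falls below ``min_pairs``.
    """
    if ds.n_items < 2:
        raise ValueError("need at least 2 items")
    a, b, c, d = _counts_matrix(ds.responses)
    n_complete = a + b + c + d

    labels = ds.item_ids
    off = ~np.eye(ds.n_items, dtype=bool)
    if np.any(n_complete[off] < min_pairs):
        i, j = np.argwhere((n_complete < min_pairs) & off)[0]
        raise ValueError(
            f"item pair ({labels[i]!r}, {labels[j]!r}) has only "
            f"{int(n_complete[i, j])} complete pairs (min_pairs={min_pairs})"
        )

    r1, r0, c1, c0 = a + b, c + d, a + c, b + d
    denom = r1 * r0 * c1 * c0
    num = a * d - b * c
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(denom > 0, num * num / np.where(denom > 0, denom, 1.0), 0.0)
    if warn_degenerate and np.any((denom == 0) & off):
        n_deg = int(np.sum((denom == 0) & off)) // 2
        logger.warning("%d item pair(s) had degenerate margins; phi2 set to 0", n_deg)
    np.fill_diagonal(values, 1.0)
    values = (values + values.T) / 2.0  # enforce exact symmetry
    return AssociationMatrix(labels=list(labels), phi2=values, n_pairs=n_complete.astype(int))


def to_dissimilarity(
    m: AssociationMatrix, *, form: Literal["one_minus", "sqrt_one_minus"] = "one_minus"
) -> DissimilarityMatrix:
    """Derive the clustering dissimilarity from a phi2 matrix.

    ``one_minus`` (default) gives ``d = 1 - phi2``; ``sqrt_one_minus`` is the
    monotone alternative ``sqrt(1 - phi2)`` exposed for sensitivity checks
    (merge order under single-pair-driven linkages is unaffected).
    """
    d = 1.0 - m.phi2
    if form == "sqrt_one_minus":
        d = np.sqrt(np.clip(d, 0.0, None))
    elif form != "one_minus":
        raise ValueError(f"unknown dissimilarity form {form!r}")
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return DissimilarityMatrix(labels=list(m.labels), d=d)
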