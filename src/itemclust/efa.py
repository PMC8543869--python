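"""Exploratory factor analysis on an item association matrix.

Extraction
    ``pc``  — principal components: loadings are eigenvectors scaled by the
    square roots of the leading eigenvalues.
    ``paf`` — principal axis factoring: iteratively replaces the diagonal
    with communalities and re-decomposes until the communalities stabilize.

Rotation
    ``varimax`` and ``quartimax`` maximize the orthomax criterion by pairwise
    plane rotations with a closed-form optimal angle per pair; ``promax`` is
    varimax followed by an oblique power-4 target regression; ``oblimin``
    (quartimin) uses gradient projection; ``cluster_target`` is an Orthogonal
    Procrustes rotation of the loadings toward a column-normalized cluster
    indicator matrix.

Loading columns are sign-fixed so each column's largest-magnitude entry is
positive; this makes results deterministic across eigensolvers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from itemclust.association import AssociationMatrix

__all__ = [
    "LoadingMatrix",
    "LoadingTable",
    "EXTRACTIONS",
    "ROTATIONS",
    "extract",
    "rotate",
    "threshold_loadings",
]

EXTRACTIONS = ("pc", "paf")
ROTATIONS = ("none", "varimax", "quartimax", "promax", "oblimin", "cluster_target")

#: oblique rotations: communalities are not the row sums of squared pattern
#: loadings, so they are reported as None there
_OBLIQUE = ("promax", "oblimin")


@dataclass
class LoadingMatrix:
    """Item x factor loadings with provenance."""

    labels: list[str]
    L: np.ndarray = field(repr=False)
    extraction: str
    rotation: str
    m: int
    communalities: np.ndarray | None = field(default=None, repr=False)
    eigenvalues: np.ndarray | None = field(default=None, repr=False)
    converged: bool = True

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        if self.L.shape != (len(self.labels), self.m):
            raise ValueError(f"L shape {self.L.shape} != ({len(self.labels)}, {self.m})")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"F{j + 1}" for j in range(self.m)]
        return pd.DataFrame(self.L, index=self.labels, columns=cols)


@dataclass
class LoadingTable:
    """Thresholded view of a loading matrix (blanks below the cutoff)."""

    table: pd.DataFrame
    cutoff: float
    cross_loading: list[str]


def _fix_signs(L: np.ndarray) -> np.ndarray:
    out = L.copy()
    for j in range(out.shape[1]):
        idx = int(np.argmax(np.abs(out[:, j])))
        if out[idx, j] < 0:
            out[:, j] = -out[:, j]
    return out


def _as_assoc(m_assoc: AssociationMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(m_assoc, AssociationMatrix):
        return m_assoc.phi2.copy(), list(m_assoc.labels)
    arr = np.asarray(m_assoc, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"association matrix must be square, got {arr.shape}")
    if not np.allclose(arr, arr.T):
        raise ValueError("association matrix must be symmetric")
    return arr.copy(), [f"item_{i + 1}" for i in range(arr.shape[0])]


def _top_eigen(mat: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(mat)
    order = np.argsort(vals)[::-1]
    return vals[order][:m], vecs[:, order][:, :m]


def _smc_communalities(r: np.ndarray) -> np.ndarray:
    """Squared multiple correlations; falls back to max |off-diagonal|."""
    try:
        inv = np.linalg.inv(r)
        diag = np.diag(inv)
        if np.all(diag > 0):
            smc = 1.0 - 1.0 / diag
            if np.all((smc >= 0) & (smc <= 1)):
                return smc
    except np.linalg.LinAlgError:
        pass
    off = r - np.diag(np.diag(r))
    return np.abs(off).max(axis=1)


def extract(
    m_assoc: AssociationMatrix | np.ndarray,
    m: int,
    extraction: str = "pc",
    *,
    paf_tol: float = 1e-6,
    paf_max_iter: int = 200,
) -> LoadingMatrix:
    """Extract ``m`` factors from a symmetric unit-diagonal matrix."""
    if extraction not in EXTRACTIONS:
        raise ValueError(f"extraction must be one of {EXTRACTIONS}, got {extraction!r}")
    mat, labels = _as_assoc(m_assoc)
    n = mat.shape[0]
    if not 1 <= m <= n:
        raise ValueError(f"m must be in [1, {n}], got {m}")

    converged = True
    if extraction == "pc":
        all_vals = np.sort(np.linalg.eigvalsh(mat))[::-1]
        if m > int(np.sum(all_vals > 1e-12)):
            raise ValueError(
                f"m={m} exceeds the {int(np.sum(all_vals > 1e-12))} positive eigenvalues"
            )
        vals, vecs = _top_eigen(mat, m)
        L = vecs * np.sqrt(np.clip(vals, 0.0, None))
        eigenvalues = vals
    else:  # paf
        h = _smc_communalities(mat)
        reduced = mat.copy()
        for _ in range(paf_max_iter):
            np.fill_diagonal(reduced, h)
            vals, vecs = _top_eigen(reduced, m)
            L = vecs * np.sqrt(np.clip(vals, 0.0, None))
            h_new = np.sum(L**2, axis=1)
            delta = np.max(np.abs(h_new - h))
            h = h_new
            if delta < paf_tol:
                break
        else:
            converged = False
        eigenvalues = vals

    L = _fix_signs(L)
    return LoadingMatrix(
        labels=labels, L=L, extraction=extraction, rotation="none", m=m,
        communalities=np.sum(L**2, axis=1), eigenvalues=eigenvalues, converged=converged,
    )


# --------------------------------------------------------------------------
# rotations


def _orthomax(L: np.ndarray, gamma: float, tol: float = 1e-10, max_sweeps: int = 1000) -> np.ndarray:
    """Pairwise plane rotations to an orthomax stationary point.

    ``gamma = 1`` is varimax, ``gamma = 0`` quartimax.
    """
    n, k = L.shape
    out = L.copy()
    if k < 2:
        return out

    def criterion(a: np.ndarray) -> float:
        a2 = a**2
        return float(np.sum(a2**2) - (gamma / n) * np.sum(a2.sum(axis=0) ** 2))

    crit = criterion(out)
    for _ in range(max_sweeps):
        for p in range(k - 1):
            for q in range(p + 1, k):
                x, y = out[:, p], out[:, q]
                u = x**2 - y**2
                v = 2.0 * x * y
                a_sum, b_sum = u.sum(), v.sum()
                c_sum = float(u @ u - v @ v)
                d_sum = float(2.0 * (u @ v))
                num = d_sum - gamma * 2.0 * a_sum * b_sum / n
                den = c_sum - gamma * (a_sum**2 - b_sum**2) / n
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-14:
                    continue
                cs, sn = np.cos(phi), np.sin(phi)
                out[:, p], out[:, q] = cs * x + sn * y, -sn * x + cs * y
        new_crit = criterion(out)
        if new_crit - crit < tol:
            break
        crit = new_crit
    return out


def _promax(L: np.ndarray, power: int = 4) -> np.ndarray:
    """Hendrickson-White promax: varimax then oblique power target."""
    v = _orthomax(L, gamma=1.0)
    target = np.sign(v) * np.abs(v) ** power
    t, *_ = np.linalg.lstsq(v, target, rcond=None)
    # rescale so the implied factor covariance has unit diagonal
    t = t @ np.diag(np.sqrt(np.diag(np.linalg.inv(t.T @ t))))
    return v @ t


def _quartimin_vgq(L: np.ndarray) -> tuple[float, np.ndarray]:
    k = L.shape[1]
    n_mat = np.ones((k, k)) - np.eye(k)
    l2 = L**2
    f = float(np.sum(l2 * (l2 @ n_mat))) / 4.0
    return f, L * (l2 @ n_mat)


def _oblimin(L: np.ndarray, tol: float = 1e-8, max_iter: int = 1000) -> np.ndarray:
    """Gradient-projection quartimin rotation (oblique)."""
    a = L
    k = a.shape[1]
    t = np.eye(k)
    al = 1.0
    ti = np.linalg.inv(t)
    lam = a @ ti.T
    f, gq = _quartimin_vgq(lam)
    g = -(lam.T @ gq @ ti).T
    for _ in range(max_iter):
        gp = g - t @ np.diag(np.sum(t * g, axis=0))
        s = np.sqrt(np.sum(gp**2))
        if s < tol:
            break
        al *= 2.0
        for _ in range(20):
            x = t - al * gp
            x = x @ np.diag(1.0 / np.sqrt(np.sum(x**2, axis=0)))
            xi = np.linalg.inv(x)
            lam_t = a @ xi.T
            ft, gq_t = _quartimin_vgq(lam_t)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        t, f, lam = x, ft, lam_t
        g = -(lam.T @ gq_t @ np.linalg.inv(t)).T
    return lam


def rotate(
    L: LoadingMatrix,
    rotation: str,
    target: np.ndarray | None = None,
) -> LoadingMatrix:
    """Rotate a loading matrix.

    ``cluster_target`` requires ``target``: an item x cluster indicator (or
    already column-normalized) matrix; the loadings are Procrustes-rotated
    toward it.  Orthogonal rotations preserve per-item communalities.
    """
    if rotation not in ROTATIONS:
        raise ValueError(f"rotation must be one of {ROTATIONS}, got {rotation!r}")
    if rotation == "none":
        return replace(L, rotation="none")
    if L.m < 2:
        return replace(L, rotation=rotation)

    if rotation == "varimax":
        rotated = _orthomax(L.L, gamma=1.0)
    elif rotation == "quartimax":
        rotated = _orthomax(L.L, gamma=0.0)
    elif rotation == "promax":
        rotated = _promax(L.L)
    elif rotation == "oblimin":
        rotated = _oblimin(L.L)
    else:  # cluster_target
        if target is None:
            raise ValueError("cluster_target rotation requires a target matrix")
        from itemclust.congruence import procrustes_rotation

        rotated = L.L @ procrustes_rotation(L.L, np.asarray(target, dtype=float))

    rotated = _fix_signs(rotated)
    comm = None if rotation in _OBLIQUE else np.sum(rotated**2, axis=1)
    return replace(L, L=rotated, rotation=rotation, communalities=comm)


def threshold_loadings(L: LoadingMatrix, cutoff: float = 0.35) -> LoadingTable:
    """Display view keeping only loadings with absolute value > cutoff.

    Items retained on two or more factors are listed as cross-loading.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    frame = L.to_frame()
    masked = frame.where(frame.abs() > cutoff)
    retained = masked.notna().sum(axis=1)
    cross = [str(i) for i in masked.index[retained >= 2]]
    if retained.sum() == 0:
        warnings.warn(f"no loadings exceed cutoff {cutoff}", stacklevel=2)
    return LoadingTable(table=masked, cutoff=cutoff, cross_loading=cross)
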