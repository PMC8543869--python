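"""Latent-threshold simulation of correlated binary checklist data.

Items are generated by thresholding a zero-mean, unit-variance multivariate
normal whose correlation matrix has block compound symmetry: ``rho_within``
inside planted blocks, ``rho_between`` across blocks.  Item ``j`` becomes 1
when its latent value exceeds ``Phi^{-1}(1 - prevalence_j)``, so the marginal
endorsement probability equals the requested prevalence independently of the
correlation structure.  Cells are then masked missing independently.

One seed drives three independent substreams (latent draws, missingness,
fixture decoys), so changing ``missing_rate`` never changes the latent data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from itemclust.datasets import ChecklistDataset, ItemMeta, write_dataset

__all__ = ["SimulationConfig", "simulate_dataset", "block_correlation", "make_checklist_fixture"]

#: Default planted block sizes (seven blocks over 29 items).
DEFAULT_BLOCK_SIZES = (4, 7, 6, 3, 3, 4, 2)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the latent-threshold generator."""

    n_subjects: int = 453
    block_sizes: tuple[int, ...] = DEFAULT_BLOCK_SIZES
    rho_within: float = 0.7
    rho_between: float = 0.05
    prevalences: float | tuple[float, ...] = 0.3
    missing_rate: float = 0.05
    seed: int = 0
    section: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_sizes", tuple(int(b) for b in self.block_sizes))
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if any(b < 1 for b in self.block_sizes):
            raise ValueError("block sizes must be positive")
        if not (0.0 <= self.rho_within < 1.0):
            raise ValueError("rho_within must be in [0, 1)")
        if not (0.0 <= self.rho_between <= self.rho_within):
            raise ValueError("rho_between must be in [0, rho_within]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        p = self.prevalence_vector()
        if np.any((p <= 0.0) | (p >= 1.0)):
            raise ValueError("prevalences must be in (0, 1)")

    @property
    def n_items(self) -> int:
        return sum(self.block_sizes)

    def prevalence_vector(self) -> np.ndarray:
        if np.isscalar(self.prevalences):
            return np.full(self.n_items, float(self.prevalences))
        p = np.asarray(self.prevalences, dtype=float)
        if p.size != self.n_items:
            raise ValueError(f"{p.size} prevalences for {self.n_items} items")
        return p


def block_correlation(
    block_sizes: Sequence[int], rho_within: float, rho_between: float
) -> np.ndarray:
    """Block-compound-symmetry correlation matrix; must be positive definite."""
    sizes = [int(b) for b in block_sizes]
    n = sum(sizes)
    corr = np.full((n, n), float(rho_between))
    start = 0
    for b in sizes:
        corr[start : start + b, start : start + b] = rho_within
        start += b
    np.fill_diagonal(corr, 1.0)
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError(
            "implied latent correlation matrix is not positive definite "
            f"(rho_within={rho_within}, rho_between={rho_between})"
        ) from None
    return corr


def _block_labels(block_sizes: Sequence[int]) -> np.ndarray:
    return np.repeat(np.arange(1, len(block_sizes) + 1), block_sizes)


def simulate_dataset(cfg: SimulationConfig) -> tuple[ChecklistDataset, dict[str, int]]:
    """Draw one dataset plus the planted item -> block labelling.

    Returns ``(dataset, truth)`` where ``truth[item_id]`` is the 1-based index
    of the planted block.  Identical config (including seed) gives bit-identical
    output.
    """
    corr = block_correlation(cfg.block_sizes, cfg.rho_within, cfg.rho_between)
    n, p = cfg.n_subjects, cfg.n_items
    ss = np.random.SeedSequence(cfg.seed)
    latent_ss, missing_ss, _ = ss.spawn(3)

    chol = np.linalg.cholesky(corr)
    z = np.random.default_rng(latent_ss).standard_normal((n, p)) @ chol.T
    thresholds = stats.norm.ppf(1.0 - cfg.prevalence_vector())
    x = (z > thresholds[None, :]).astype(float)

    if cfg.missing_rate > 0:
        miss = np.random.default_rng(missing_ss).random((n, p)) < cfg.missing_rate
        x[miss] = np.nan

    blocks = _block_labels(cfg.block_sizes)
    items = [
        ItemMeta(item_id=f"sec{cfg.section}__b{blocks[j]}_i{j + 1}", label=f"b{blocks[j]}_i{j + 1}", section=cfg.section)
        for j in range(p)
    ]
    subjects = [f"s{i + 1:04d}" for i in range(n)]
    ds = ChecklistDataset(subject_ids=subjects, items=items, responses=x)
    truth = {it.item_id: int(blocks[j]) for j, it in enumerate(items)}
    return ds, truth


#: Section layout of the bundled checklist fixture: the analysed sections hold
#: 19 + 4 + 6 items; the others are decoys that Step-1 selection must drop.
FIXTURE_SECTIONS = {1: 3, 2: 2, 3: 19, 4: 3, 5: 4, 6: 2, 7: 6, 8: 2}
ANALYSIS_SECTIONS = (3, 5, 7)


def make_checklist_fixture(
    seed: int,
    path: str | Path | None = None,
    *,
    n_subjects: int = 120,
    missing_rate: float = 0.03,
) -> Path:
    """Write a full checklist-shaped CSV for variable-selection tests.

    Sections 3/5/7 contain 19/4/6 items (29 analysable variables); the other
    sections hold decoy items that must be dropped by selection.  Column
    structure is seed-independent; response values are not.
    """
    if path is None:
        path = Path(f"checklist_fixture_seed{seed}.csv")
    path = Path(path)

    n_total = sum(FIXTURE_SECTIONS.values())
    cfg = SimulationConfig(
        n_subjects=n_subjects,
        block_sizes=(n_total,),
        rho_within=0.0,
        rho_between=0.0,
        prevalences=0.4,
        missing_rate=missing_rate,
        seed=seed,
    )
    ds, _ = simulate_dataset(cfg)

    items: list[ItemMeta] = []
    for section in sorted(FIXTURE_SECTIONS):
        for q in range(FIXTURE_SECTIONS[section]):
            items.append(
                ItemMeta(item_id=f"sec{section}__q{q + 1:02d}", label=f"q{q + 1:02d}", section=section)
            )
    assert len(items) == n_total
    fixture = ChecklistDataset(
        subject_ids=ds.subject_ids, items=items, responses=ds.responses
    )
    return write_dataset(fixture, path)


def with_seed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``cfg`` with a different seed (convenience for seed sweeps)."""
    return replace(cfg, seed=seed)
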