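"""Reading, writing and selecting checklist-shaped binary tables.

A *checklist dataset* is a wide table: one row per subject, one column per
dichotomous item, cells in ``{0, 1, missing}``.  Missingness is carried as an
explicit :func:`numpy.isnan` mask on a float matrix — never as a sentinel
integer — because every downstream statistic uses pairwise deletion and needs
an unambiguous mask.

Item metadata (a section number per item, used for variable selection) comes
either from an in-header naming convention ``sec<k>__<label>`` or from a
two-column sidecar file mapping ``item_id`` to ``section``.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemMeta",
    "ChecklistDataset",
    "ParseError",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "select_variables",
    "write_matrix",
    "read_matrix",
]

_SECTION_HEADER = re.compile(r"^sec(\d+)__(.+)$")

DEFAULT_MISSING_SENTINELS = ("", "NA", "NaN", "nan")


class ParseError(ValueError):
    """A cell or header could not be interpreted; names row/column."""


class ValidationError(ValueError):
    """The parsed table violates a dataset invariant."""


@dataclass(frozen=True)
class ItemMeta:
    """Metadata for one checklist item."""

    item_id: str
    label: str = ""
    section: int = 1

    def __post_init__(self) -> None:
        if self.section < 1:
            raise ValidationError(f"item {self.item_id!r}: section must be >= 1, got {self.section}")


@dataclass
class ChecklistDataset:
    """Subjects x binary items with explicit missingness.

    ``responses`` is a float matrix whose entries are 0.0, 1.0 or ``nan``
    (missing).  Rows align with ``subject_ids``, columns with ``items``.
    """

    subject_ids: list[str]
    items: list[ItemMeta]
    responses: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        n, p = self.responses.shape
        if n != len(self.subject_ids):
            raise ValidationError(
                f"responses has {n} rows but {len(self.subject_ids)} subject ids"
            )
        if p != len(self.items):
            raise ValidationError(f"responses has {p} columns but {len(self.items)} items")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            dupes = sorted({s for s in self.subject_ids if self.subject_ids.count(s) > 1})
            raise ValidationError(f"duplicate subject ids: {dupes}")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValidationError(f"duplicate item ids: {dupes}")
        observed = self.responses[~np.isnan(self.responses)]
        bad = observed[(observed != 0.0) & (observed != 1.0)]
        if bad.size:
            raise ValidationError(f"non-binary observed values present, e.g. {bad[0]!r}")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def mask(self) -> np.ndarray:
        """Boolean matrix, True where the cell is missing."""
        return np.isnan(self.responses)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.responses, index=self.subject_ids, columns=self.item_ids)

    def column(self, item_id: str) -> np.ndarray:
        return self.responses[:, self.item_ids.index(item_id)]

    def sections_present(self) -> set[int]:
        return {it.section for it in self.items}


def _parse_cell(raw: str, missing: Sequence[str], row: str, col: str) -> float:
    token = raw.strip()
    if token in missing:
        return np.nan
    if token in ("0", "1"):
        return float(token)
    # tolerate "0.0"/"1.0" exports
    try:
        val = float(token)
    except ValueError:
        raise ParseError(f"row {row!r}, column {col!r}: cannot parse {raw!r} as 0/1/missing") from None
    if val in (0.0, 1.0):
        return val
    raise ParseError(f"row {row!r}, column {col!r}: value {raw!r} is not 0/1/missing")


def _item_meta_from_header(name: str, meta: Mapping[str, int] | None) -> ItemMeta:
    m = _SECTION_HEADER.match(name)
    if m:
        return ItemMeta(item_id=name, label=m.group(2), section=int(m.group(1)))
    if meta is not None and name in meta:
        return ItemMeta(item_id=name, label=name, section=int(meta[name]))
    return ItemMeta(item_id=name, label=name, section=1)


def _read_sidecar(path: str | Path, delimiter: str | None) -> dict[str, int]:
    df = pd.read_csv(path, sep=delimiter, engine="python", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"metadata sidecar {path} needs columns (item_id, section)")
    id_col, sec_col = df.columns[0], df.columns[1]
    return {str(r[id_col]): int(r[sec_col]) for _, r in df.iterrows()}


def read_dataset(
    path: str | Path,
    *,
    delimiter: str | None = None,
    subject_col: str | int = 0,
    missing: Sequence[str] = DEFAULT_MISSING_SENTINELS,
    metadata: str | Path | Mapping[str, int] | None = None,
) -> ChecklistDataset:
    """Read a checklist-shaped delimited table.

    Parameters
    ----------
    path
        Delimited text file; first row is a header.
    delimiter
        Explicit delimiter; ``None`` auto-detects (CSV/TSV).
    subject_col
        Name or position of the subject-id column.
    missing
        Cell tokens treated as missing (empty cell always qualifies).
    metadata
        Optional sidecar path or mapping ``item_id -> section``; overrides
        nothing when headers already follow the ``sec<k>__<label>`` convention.

    Raises
    ------
    ParseError
        For any cell not interpretable as 0/1/missing (names row and column).
    ValidationError
        For duplicate subject ids or shape inconsistencies.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, engine="python", dtype=str, keep_default_na=False)
    if isinstance(subject_col, int):
        subject_col = df.columns[subject_col]
    if subject_col not in df.columns:
        raise ParseError(f"subject id column {subject_col!r} not in header")
    subject_ids = [str(s) for s in df[subject_col]]
    item_cols = [c for c in df.columns if c != subject_col]
    if not item_cols:
        raise ValidationError("no item columns found")

    meta_map: Mapping[str, int] | None
    if metadata is None:
        meta_map = None
    elif isinstance(metadata, (str, Path)):
        meta_map = _read_sidecar(metadata, delimiter)
    else:
        meta_map = metadata

    responses = np.empty((len(subject_ids), len(item_cols)))
    for j, col in enumerate(item_cols):
        raw = df[col].tolist()
        for i, cell in enumerate(raw):
            responses[i, j] = _parse_cell(cell, missing, subject_ids[i], col)

    items = [_item_meta_from_header(c, meta_map) for c in item_cols]
    return ChecklistDataset(subject_ids=subject_ids, items=items, responses=responses)


def write_dataset(
    ds: ChecklistDataset,
    path: str | Path,
    *,
    delimiter: str = ",",
    missing_token: str = "",
    subject_col: str = "subject_id",
) -> Path:
    """Write a dataset so that :func:`read_dataset` round-trips it exactly."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow([subject_col] + ds.item_ids)
        for i, sid in enumerate(ds.subject_ids):
            row: list[str] = [sid]
            for v in ds.responses[i]:
                row.append(missing_token if np.isnan(v) else str(int(v)))
            writer.writerow(row)
    return path


def select_variables(ds: ChecklistDataset, sections: Iterable[int]) -> ChecklistDataset:
    """Restrict a dataset to items whose section is in ``sections``.

    Column order is preserved; selecting every section present returns an
    equivalent dataset.  Raises :class:`ValidationError` when nothing matches.
    """
    wanted = set(int(s) for s in sections)
    if not wanted:
        raise ValidationError("sections must be non-empty")
    keep = [j for j, it in enumerate(ds.items) if it.section in wanted]
    if not keep:
        raise ValidationError(
            f"no items in sections {sorted(wanted)}; present: {sorted(ds.sections_present())}"
        )
    return ChecklistDataset(
        subject_ids=list(ds.subject_ids),
        items=[ds.items[j] for j in keep],
        responses=ds.responses[:, keep].copy(),
    )


def write_matrix(
    matrix: np.ndarray | pd.DataFrame,
    path: str | Path,
    *,
    labels: Sequence[str] | None = None,
    delimiter: str = ",",
) -> Path:
    """Write a labelled square matrix as delimited text (full precision).

    Round-trips through :func:`read_matrix` to within 1e-12 (repr-exact for
    doubles).  Non-square input is rejected.
    """
    if isinstance(matrix, pd.DataFrame):
        labels = [str(c) for c in matrix.columns]
        values = matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError(f"matrix must be square, got shape {values.shape}")
    n = values.shape[0]
    if labels is None:
        labels = [f"item_{i + 1}" for i in range(n)]
    if len(labels) != n:
        raise ValidationError(f"{len(labels)} labels for {n} rows")
    df = pd.DataFrame(values, index=list(labels), columns=list(labels))
    df.to_csv(path, sep=delimiter, float_format="%.17g", index_label="item_id")
    return Path(path)


def read_matrix(path: str | Path, *, delimiter: str = ",") -> pd.DataFrame:
    """Read a labelled square matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1]:
        raise ValidationError(f"matrix file {path} is not square: {df.shape}")
    return df
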