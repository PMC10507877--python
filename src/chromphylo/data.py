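"""Domain types and readers/writers for cCRE-style binary accessibility tables.

The central container is :class:`AccessibilityMatrix`: one row per candidate
cis-regulatory element ("site"), one 0/1 column per cell type, recording the
absence/presence of an ATAC-seq/DNase-seq peak.  Genomic coordinates are
carried as opaque site identity (BED-style 0-based half-open for synthetic
output); the package never does coordinate arithmetic with them.

Missing values are not supported: the upstream peak index is a complete 0/1
table, so any non-binary token is reported as a parse error rather than
silently imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError, InputError, ParseError

__all__ = [
    "GenomicInterval",
    "CellType",
    "AccessibilityMatrix",
    "read_accessibility_table",
    "write_accessibility_table",
    "subset_cells",
    "filter_sites",
]

_ROLES = ("stem", "progenitor", "terminal")


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval identifying one site (cCRE)."""

    chrom: str
    start: int
    end: int
    site_id: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ContractError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}")


@dataclass(frozen=True)
class CellType:
    """A cell type column: short label plus its place in the hierarchy."""

    name: str
    role: str = "terminal"

    def __post_init__(self):
        if self.role not in _ROLES:
            raise ContractError(f"unknown cell role {self.role!r}; expected one of {_ROLES}")


class AccessibilityMatrix:
    """Binary site x cell matrix with genomic-interval site identities.

    ``values`` has shape (n_sites, n_cells) with entries in {0, 1}.
    """

    def __init__(self, sites: Sequence[GenomicInterval],
                 cells: Sequence[CellType], values: np.ndarray):
        values = np.asarray(values, dtype=np.uint8)
        if values.ndim != 2 or values.shape != (len(sites), len(cells)):
            raise ContractError(
                f"values shape {values.shape} inconsistent with "
                f"{len(sites)} sites x {len(cells)} cells")
        if values.size and not np.isin(values, (0, 1)).all():
            raise ContractError("matrix entries must be 0 or 1")
        ids = [s.site_id for s in sites]
        if len(set(ids)) != len(ids):
            raise ContractError("site_id values must be unique within a matrix")
        names = [c.name for c in cells]
        if len(set(names)) != len(names):
            raise ContractError("cell names must be unique within a panel")
        self.sites = list(sites)
        self.cells = list(cells)
        self.values = values

    # -- basic protocol ----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def cell_names(self) -> list[str]:
        return [c.name for c in self.cells]

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.cell_names.index(name)
        except ValueError:
            raise ConfigurationError(f"unknown cell {name!r}; have {self.cell_names}")
        return self.values[:, j]

    def columns(self, names: Iterable[str]) -> np.ndarray:
        return np.column_stack([self.column(n) for n in names])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "chrom": [s.chrom for s in self.sites],
            "start": [s.start for s in self.sites],
            "end": [s.end for s in self.sites],
        })
        for j, c in enumerate(self.cells):
            df[c.name] = self.values[:, j]
        return df

    def __eq__(self, other) -> bool:
        # data identity: sites, cell names (roles are panel annotation) and values
        if not isinstance(other, AccessibilityMatrix):
            return NotImplemented
        return (self.sites == other.sites
                and self.cell_names == other.cell_names
                and np.array_equal(self.values, other.values))

    def __repr__(self) -> str:
        return (f"AccessibilityMatrix({self.n_sites} sites x "
                f"{self.n_cells} cells: {', '.join(self.cell_names)})")


def _resolve_roles(names: Sequence[str],
                   roles: dict[str, str] | None) -> list[CellType]:
    # Roles for the known murine hematopoietic panel; anything else defaults
    # to "terminal" (the role only matters for panel bookkeeping).
    from .hematopoiesis import CELL_ROLES
    lookup = dict(CELL_ROLES)
    if roles:
        lookup.update(roles)
    return [CellType(n, lookup.get(n, "terminal")) for n in names]


def read_accessibility_table(path, cell_columns: Sequence[str],
                             coordinate_columns: Sequence[str] = ("chrom", "start", "end"),
                             roles: dict[str, str] | None = None) -> AccessibilityMatrix:
    """Read a tab-separated cCRE table into an :class:`AccessibilityMatrix`.

    The reader takes an explicit list of cell columns and ignores everything
    else (real upstream tables carry extra epigenetic-state columns), so it
    is robust to file-version drift.  ``site_id`` is synthesised as
    ``chrom:start-end``.
    """
    path = Path(path)
    if len(coordinate_columns) != 3:
        raise ConfigurationError("coordinate_columns must name (chrom, start, end)")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"empty input file: {path}")
    if df.shape[1] == 0:
        raise InputError(f"empty input file: {path}")
    for col in list(coordinate_columns) + list(cell_columns):
        if col not in df.columns:
            raise ConfigurationError(
                f"column {col!r} not found in {path.name}; have {list(df.columns)}")
    cchrom, cstart, cend = coordinate_columns
    values = np.empty((len(df), len(cell_columns)), dtype=np.uint8)
    for j, col in enumerate(cell_columns):
        tokens = df[col].to_numpy()
        ok0, ok1 = tokens == "0", tokens == "1"
        bad = ~(ok0 | ok1)
        if bad.any():
            i = int(np.argmax(bad))
            raise ParseError(
                f"non-binary token {tokens[i]!r} in column {col!r}, data row {i}")
        values[:, j] = ok1
    sites = []
    for chrom, start, end in zip(df[cchrom], df[cstart], df[cend]):
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            raise ParseError(f"non-integer coordinate in row {chrom}:{start}-{end}")
        sites.append(GenomicInterval(str(chrom), start_i, end_i,
                                     f"{chrom}:{start_i}-{end_i}"))
    return AccessibilityMatrix(sites, _resolve_roles(list(cell_columns), roles), values)


def write_accessibility_table(matrix: AccessibilityMatrix, path) -> None:
    """Write a matrix as a tab-separated table readable by
    :func:`read_accessibility_table` (header: chrom/start/end then cells)."""
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def subset_cells(matrix: AccessibilityMatrix, names: Sequence[str]) -> AccessibilityMatrix:
    """Restrict and reorder cell columns to ``names``; sites unchanged."""
    names = list(names)
    if not names:
        raise ConfigurationError("cannot subset to an empty cell panel")
    by_name = {c.name: (j, c) for j, c in enumerate(matrix.cells)}
    missing = [n for n in names if n not in by_name]
    if missing:
        raise ConfigurationError(f"unknown cells {missing}; have {matrix.cell_names}")
    cols = [by_name[n][0] for n in names]
    return AccessibilityMatrix(matrix.sites, [by_name[n][1] for n in names],
                               matrix.values[:, cols])


def filter_sites(matrix: AccessibilityMatrix, keep: Sequence[bool]) -> AccessibilityMatrix:
    """Keep the rows flagged true, preserving order; cells unchanged."""
    keep = np.asarray(keep, dtype=bool)
    if keep.shape != (matrix.n_sites,):
        raise ContractError(
            f"mask length {keep.shape} does not match {matrix.n_sites} sites")
    sites = [s for s, k in zip(matrix.sites, keep) if k]
    return AccessibilityMatrix(sites, matrix.cells, matrix.values[keep])
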