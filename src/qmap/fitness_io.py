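"""I/O and identifier handling for double-mutant fitness and score matrices.

The on-disk dialect is plain TSV: the first row carries the array-strain
identifiers (cell (0,0) is ignored), the first column carries the
query-strain identifiers, and each remaining cell holds a decimal fitness
value or the missing token (default ``"NA"``). Values are written with six
significant digits, which round-trips exactly for the screens this package
targets (median-normalised fitness near 1).

Edge lists follow the BioGRID TAB column conventions by default but any
column names can be selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

MISSING_TOKEN = "NA"

#: Default BioGRID TAB 2.0 column names.
BIOGRID_ID_COLUMNS = ("Systematic Name Interactor A", "Systematic Name Interactor B")
BIOGRID_CATEGORY_COLUMN = "Experimental System"
BIOGRID_ORGANISM_COLUMN = "Organism Interactor A"


@dataclass
class FitnessMatrix:
    """An m x n grid of double-mutant fitness values.

    Rows are query strains, columns are array strains. Missing measurements
    are NaN; a value of 0 encodes lethality (a biological measurement, not
    absence of data), so all present values must be non-negative.
    """

    query_ids: list[str]
    array_ids: list[str]
    values: np.ndarray
    name: str = ""

    #: Whether negative entries are permitted (overridden by ScoreMatrix).
    _signed = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D grid")
        m, n = self.values.shape
        if m != len(self.query_ids) or n != len(self.array_ids):
            raise ValidationError(
                f"shape {self.values.shape} does not match id lists "
                f"({len(self.query_ids)} x {len(self.array_ids)})"
            )
        if not self._signed:
            bad = np.argwhere(self.values < 0)
            if bad.size:
                a, b = bad[0]
                raise ValidationError(
                    f"negative fitness value at row {self.query_ids[a]!r}, "
                    f"column {self.array_ids[b]!r}: {self.values[a, b]}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "FitnessMatrix":
        return replace(self, query_ids=list(self.query_ids),
                       array_ids=list(self.array_ids), values=self.values.copy())

    def value_at(self, query: str, array: str) -> float:
        """Value for a (query, array) pair; ids must be unique."""
        a = self.query_ids.index(query)
        b = self.array_ids.index(array)
        return float(self.values[a, b])


@dataclass
class EdgeRecord:
    """One interaction record from an edge list (self pairs allowed on read)."""

    gene_a: str
    gene_b: str
    category: str
    source: str = ""


def read_fitness_matrix(path: str | Path, missing_token: str = MISSING_TOKEN,
                        name: str | None = None) -> FitnessMatrix:
    """Read a fitness matrix from the TSV dialect described in the module docs.

    Raises :class:`FormatError` for ragged rows or an empty/malformed header
    and :class:`ValidationError` for negative fitness values (the error names
    the offending row and column).
    """
    return _read_matrix(path, missing_token, name, signed=False)


def read_score_matrix(path: str | Path, missing_token: str = MISSING_TOKEN,
                      name: str | None = None) -> "ScoreMatrix":
    """Read a (signed) interaction score matrix in the same TSV dialect."""
    from .interaction_scoring import ScoreMatrix

    fm = _read_matrix(path, missing_token, name, signed=True)
    return ScoreMatrix(query_ids=fm.query_ids, array_ids=fm.array_ids,
                       scores=fm.values, name=fm.name)


def _read_matrix(path: str | Path, missing_token: str, name: str | None,
                 signed: bool) -> FitnessMatrix:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].strip():
        raise FormatError(f"{path}: empty file or blank header row")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: header row holds no array identifiers")
    array_ids = [c.strip() for c in header[1:]]
    n = len(array_ids)
    query_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != n + 1:
            raise FormatError(
                f"{path}:{lineno}: expected {n + 1} columns, found {len(cells)}"
            )
        qid = cells[0].strip()
        query_ids.append(qid)
        row = []
        for b, cell in enumerate(cells[1:]):
            cell = cell.strip()
            if cell == missing_token or cell == "":
                row.append(np.nan)
                continue
            try:
                v = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: cell ({qid!r}, {array_ids[b]!r}) is not "
                    f"a number or the missing token: {cell!r}"
                ) from None
            row.append(v)
        rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    values = np.array(rows, dtype=float)
    cls = FitnessMatrix
    fm = cls.__new__(cls)
    fm.query_ids = query_ids
    fm.array_ids = array_ids
    fm.name = name if name is not None else path.stem
    fm._signed = signed  # type: ignore[attr-defined]
    fm.values = values
    cls.__post_init__(fm)
    return fm


def write_matrix(m, path: str | Path, missing_token: str = MISSING_TOKEN) -> None:
    """Write a FitnessMatrix or ScoreMatrix as TSV with 6 significant digits.

    ``read_fitness_matrix(write_matrix(x))`` reproduces identifiers, ordering
    and missingness exactly, and values to the printed precision.
    """
    values = getattr(m, "scores", None)
    if values is None:
        values = m.values
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["#"] + list(m.array_ids)) + "\n")
        for qid, row in zip(m.query_ids, values):
            cells = [qid] + [missing_token if np.isnan(v) else f"{v:.6g}" for v in row]
            fh.write("\t".join(cells) + "\n")


def merge_duplicates(fm: FitnessMatrix) -> FitnessMatrix:
    """Combine duplicate query rows and array columns by element-wise mean.

    The mean is taken over present values only (missing entries are ignored;
    a position missing in every duplicate stays missing). Output order is by
    first occurrence of each identifier. Idempotent on duplicate-free input.
    """
    values, query_ids = _merge_axis(fm.values, fm.query_ids)
    values, array_ids = _merge_axis(values.T, fm.array_ids)
    merged = fm.copy()
    merged.query_ids = query_ids
    merged.array_ids = array_ids
    merged.values = np.ascontiguousarray(values.T)
    return merged


def _merge_axis(values: np.ndarray, ids: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, gid in enumerate(ids):
        if gid not in groups:
            groups[gid] = []
            order.append(gid)
        groups[gid].append(i)
    if all(len(g) == 1 for g in groups.values()):
        return values, list(ids)
    out = np.empty((len(order), values.shape[1]))
    for k, gid in enumerate(order):
        block = values[groups[gid]]
        counts = np.sum(~np.isnan(block), axis=0)
        with np.errstate(invalid="ignore"):
            # all-missing positions stay missing (0/0 -> NaN)
            out[k] = np.nansum(block, axis=0) / counts
    return out, order


def read_edge_list(path: str | Path,
                   category_column: str = BIOGRID_CATEGORY_COLUMN,
                   id_columns: tuple[str, str] = BIOGRID_ID_COLUMNS,
                   organism_filter: str | None = None,
                   organism_column: str = BIOGRID_ORGANISM_COLUMN,
                   ) -> list[EdgeRecord]:
    """Read a BioGRID-style tab-delimited edge list.

    Parameters
    ----------
    category_column
        Header name of the experimental-system / category column.
    id_columns
        Header names of the two interactor identifier columns.
    organism_filter
        If given, keep only rows whose ``organism_column`` equals this value
        (string comparison after trimming, so taxon ids work too).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse tab-delimited file: {exc}") from exc
    needed = [id_columns[0], id_columns[1], category_column]
    if organism_filter is not None:
        needed.append(organism_column)
    for col in needed:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if organism_filter is not None:
        df = df[df[organism_column].str.strip() == organism_filter.strip()]
    records = []
    for _, row in df.iterrows():
        records.append(EdgeRecord(
            gene_a=str(row[id_columns[0]]).strip(),
            gene_b=str(row[id_columns[1]]).strip(),
            category=str(row[category_column]).strip(),
            source=str(path.name),
        ))
    return records
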