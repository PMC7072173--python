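"""Reading and writing cBioPortal-style TSV matrices.

The dialect mirrors a cBioPortal ``data_CNA`` extract: the first column is
``gene_id`` (Ensembl-style), an optional second column is ``gene_symbol``,
and every remaining column is one tumor sample.  Cells are tab-separated;
an empty string or ``NA`` marks a missing value.

Copy-number matrices hold the five-level GISTIC discrete codes:
-2 (deep deletion), -1 (shallow deletion), 0 (diploid), 1 (gain),
2 (high-level amplification).  Expression matrices hold non-negative
RSEM-style abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Legal GISTIC discrete copy-number codes.
VALID_CNA_CODES = frozenset({-2, -1, 0, 1, 2})

#: Strings treated as a missing cell on input.
MISSING_TOKENS = frozenset({"", "NA", "NaN", "nan"})

GENE_ID_COL = "gene_id"
GENE_SYMBOL_COL = "gene_symbol"


class MatrixFormatError(ValueError):
    """Raised when an input table violates the matrix dialect."""


@dataclass
class CnaMatrix:
    """Gene x sample matrix of GISTIC discrete copy-number codes.

    ``codes`` is a float DataFrame so that missing cells can be NaN; every
    non-missing cell is an integer in {-2, -1, 0, 1, 2}.
    """

    codes: pd.DataFrame
    gene_symbols: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def gene_ids(self) -> list[str]:
        return list(self.codes.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.codes.columns)

    @property
    def n_missing(self) -> int:
        return int(self.codes.isna().to_numpy().sum())

    def validate(self) -> None:
        if self.codes.index.has_duplicates:
            raise MatrixFormatError("duplicate gene ids in CNA matrix")
        if self.codes.columns.has_duplicates:
            raise MatrixFormatError("duplicate sample ids in CNA matrix")
        vals = self.codes.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and (np.any(finite != np.round(finite)) or not set(np.unique(finite)) <= set(VALID_CNA_CODES)):
            bad = finite[(finite != np.round(finite)) | ~np.isin(finite, list(VALID_CNA_CODES))][0]
            raise MatrixFormatError(f"invalid GISTIC code {bad!r}; allowed codes are -2..2")
        if self.gene_symbols is not None and not self.gene_symbols.index.equals(self.codes.index):
            raise MatrixFormatError("gene_symbols index does not match codes index")


@dataclass
class ExprMatrix:
    """Gene x sample matrix of non-negative expression abundances."""

    values: pd.DataFrame
    gene_symbols: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            raise MatrixFormatError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise MatrixFormatError("duplicate sample ids in expression matrix")
        vals = self.values.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            raise MatrixFormatError("negative value in expression matrix")


@dataclass
class Cohort:
    """One tumor series: an acronym plus its CNA and (optional) expression data."""

    acronym: str
    cna: CnaMatrix
    expr: ExprMatrix | None = None

    def __post_init__(self) -> None:
        if not self.acronym:
            raise ValueError("cohort acronym must be non-empty")

    @property
    def sample_ids(self) -> list[str]:
        """Samples shared by every matrix present in the cohort."""
        samples = list(self.cna.sample_ids)
        if self.expr is not None:
            expr_set = set(self.expr.sample_ids)
            samples = [s for s in samples if s in expr_set]
        return samples

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _read_raw(path: str | Path) -> tuple[pd.DataFrame, bool]:
    """Read a matrix TSV, returning (frame indexed by gene_id, has_symbol)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != GENE_ID_COL:
        raise MatrixFormatError(
            f"{path}: malformed header; first column must be {GENE_ID_COL!r}, got {header[:1]!r}"
        )
    has_symbol = len(header) > 1 and header[1] == GENE_SYMBOL_COL
    sample_cols = header[2:] if has_symbol else header[1:]
    dupes = pd.Index(sample_cols)[pd.Index(sample_cols).duplicated()]
    if len(dupes):
        raise MatrixFormatError(f"{path}: duplicate sample columns {sorted(set(dupes))}")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    # drop rows with unusable gene ids before indexing
    bad_gene = raw[GENE_ID_COL].isin(MISSING_TOKENS)
    for gid in raw.loc[bad_gene, GENE_ID_COL]:
        logger.warning("%s: dropping row with unparseable gene id %r", path, gid)
    raw = raw[~bad_gene]
    dup = raw[GENE_ID_COL].duplicated(keep="first")
    for gid in raw.loc[dup, GENE_ID_COL]:
        logger.warning("%s: duplicate gene id %s; keeping first occurrence", path, gid)
    raw = raw[~dup].set_index(GENE_ID_COL)
    return raw, has_symbol


def _parse_cells(raw: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    cells = raw.mask(raw.isin(MISSING_TOKENS))
    parsed = cells.apply(pd.to_numeric, errors="coerce")
    bad = parsed.isna() & cells.notna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise MatrixFormatError(
            f"{path}: unparseable cell {cells.iat[gi, si]!r} at gene "
            f"{bad.index[gi]!r}, sample {bad.columns[si]!r}"
        )
    return parsed.astype(float)


def read_cna_matrix(path: str | Path) -> CnaMatrix:
    """Read a discrete copy-number matrix, validating the GISTIC code set.

    Rows with missing gene ids are dropped with a warning; a duplicate gene
    id keeps the first row.  Any cell outside {-2,...,2}, or non-integer,
    raises :class:`MatrixFormatError` naming the offending gene and sample.
    """
    raw, has_symbol = _read_raw(path)
    symbols = raw.pop(GENE_SYMBOL_COL) if has_symbol else None
    parsed = _parse_cells(raw, path)
    arr = parsed.to_numpy()
    bad = ~np.isnan(arr) & (~np.isin(arr, list(VALID_CNA_CODES)) | (arr != np.round(arr)))
    if bad.any():
        gi, si = np.argwhere(bad)[0]
        raise MatrixFormatError(
            f"{path}: invalid GISTIC code {arr[gi, si]!r} at gene "
            f"{parsed.index[gi]!r}, sample {parsed.columns[si]!r}; allowed codes are -2..2"
        )
    return CnaMatrix(codes=parsed, gene_symbols=symbols)


def read_expr_matrix(path: str | Path) -> ExprMatrix:
    """Read a non-negative expression matrix; a negative cell is a hard error."""
    raw, has_symbol = _read_raw(path)
    symbols = raw.pop(GENE_SYMBOL_COL) if has_symbol else None
    parsed = _parse_cells(raw, path)
    arr = parsed.to_numpy()
    bad = ~np.isnan(arr) & (arr < 0)
    if bad.any():
        gi, si = np.argwhere(bad)[0]
        raise MatrixFormatError(
            f"{path}: negative expression value {arr[gi, si]!r} at gene "
            f"{parsed.index[gi]!r}, sample {parsed.columns[si]!r}"
        )
    return ExprMatrix(values=parsed, gene_symbols=symbols)


def _write_matrix(frame: pd.DataFrame, symbols: pd.Series | None,
                  path: str | Path, integer: bool) -> None:
    out = frame.copy()
    if integer:
        out = out.map(lambda v: "" if pd.isna(v) else str(int(v)))
    else:
        out = out.map(lambda v: "" if pd.isna(v) else format(float(v), ".10g"))
    out.insert(0, GENE_ID_COL, out.index)
    if symbols is not None:
        out.insert(1, GENE_SYMBOL_COL, symbols.values)
    out.to_csv(path, sep="\t", index=False)


def write_cna_matrix(matrix: CnaMatrix, path: str | Path) -> None:
    _write_matrix(matrix.codes, matrix.gene_symbols, path, integer=True)


def write_expr_matrix(matrix: ExprMatrix, path: str | Path) -> None:
    _write_matrix(matrix.values, matrix.gene_symbols, path, integer=False)


def write_table(rows: pd.DataFrame, path: str | Path,
                schema: list[str] | None = None) -> None:
    """Write a result table as UTF-8 TSV with a header and no index column.

    ``schema`` optionally fixes the column order; columns absent from the
    frame are a hard error.
    """
    frame = rows
    if schema is not None:
        missing = [c for c in schema if c not in frame.columns]
        if missing:
            raise ValueError(f"table missing schema columns {missing}")
        frame = frame[schema]
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
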