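"""Tabular I/O for expression matrices, pseudotime tables and result matrices.

File dialect: tab-separated values, ``.`` decimal point, UNIX newlines.
Header and row-name handling is always explicit (flags), never autodetected,
so numeric gene identifiers cannot be silently misread as data.

Coordinate convention throughout the package: genes are rows, cells are
columns, i.e. the expression matrix is X in R^{G x C}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

# 17 significant digits round-trips any IEEE double through decimal text.
_FLOAT_FMT = ".17g"


class FormatError(ValueError):
    """Structural problem in an input file (ragged rows, empty file)."""


class ParseError(ValueError):
    """A field failed to parse; message carries row/column coordinates."""


class AlignmentError(ValueError):
    """Cell identifiers of expression and pseudotime inputs do not match."""


@dataclass
class ExpressionDataset:
    """Observed expression matrix X (G genes x C cells) with identifiers.

    Values are arbitrary real expression units, typically log-scale
    scRNA-seq expression.  All entries must be finite; identifiers must
    be unique.  At least two cells are required because the downstream
    dynamics fit needs two pseudotime points.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        G, C = self.values.shape
        if G < 1:
            raise FormatError("expression matrix needs at least one gene row")
        if C < 2:
            raise FormatError(
                "expression matrix needs at least two cells "
                "(two pseudotime points) to fit dynamics"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ParseError(
                f"non-finite expression value at gene row {bad[0]}, cell column {bad[1]}"
            )
        if not self.gene_ids:
            self.gene_ids = [_synth_id("g", i) for i in range(G)]
        if not self.cell_ids:
            self.cell_ids = [_synth_id("c", i) for i in range(C)]
        if len(self.gene_ids) != G:
            raise FormatError(f"{len(self.gene_ids)} gene ids for {G} rows")
        if len(self.cell_ids) != C:
            raise FormatError(f"{len(self.cell_ids)} cell ids for {C} columns")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class PseudotimeTable:
    """Per-cell pseudotime values t_c, aligned to dataset columns.

    Pseudotime is a unitless, non-negative ordering of cells along an
    inferred progression.  At least two distinct values are required,
    otherwise the exponential dynamics are unidentifiable.  Tied values
    are permitted (cross-sectional snapshots).
    """

    cell_ids: list[str]
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.ndim != 1:
            raise FormatError("pseudotimes must be a 1-D vector")
        if len(self.cell_ids) != self.times.size:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {self.times.size} times"
            )
        if self.times.size < 2:
            raise FormatError("need at least two pseudotime points")
        if not np.all(np.isfinite(self.times)):
            raise ParseError("non-finite pseudotime value")
        if np.any(self.times < 0):
            bad = int(np.argmin(self.times))
            raise ParseError(
                f"negative pseudotime {self.times[bad]} for cell {self.cell_ids[bad]!r}"
            )
        if np.unique(self.times).size < 2:
            raise FormatError("all pseudotimes identical; dynamics unidentifiable")
        _check_unique(self.cell_ids, "cell")

    @property
    def n_cells(self) -> int:
        return self.times.size


def _synth_id(prefix: str, i: int) -> str:
    return f"{prefix}{i + 1:04d}"


def _check_unique(ids: list[str], kind: str) -> None:
    seen: set[str] = set()
    for name in ids:
        if name in seen:
            raise FormatError(f"duplicate {kind} id {name!r}")
        seen.add(name)


def _parse_float(token: str, row: int, col: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"cannot parse {token!r} as a number at row {row}, column {col}"
        ) from None


def read_expression(
    path: str | Path,
    delimiter: str = "\t",
    has_header: bool = False,
    has_rownames: bool = False,
) -> ExpressionDataset:
    """Read a genes x cells expression matrix from delimited text.

    ``has_header``/``has_rownames`` are explicit: a header line supplies
    cell ids, a leading column supplies gene ids.  When absent, positional
    ids ``g0001...`` / ``c0001...`` are synthesized in file order.
    """
    lines = _read_lines(path)
    cell_ids: list[str] = []
    if has_header:
        header = lines[0].split(delimiter)
        cell_ids = header[1:] if has_rownames else header
        lines = lines[1:]
        if not lines:
            raise FormatError(f"no data rows in {path}")
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    width: int | None = None
    for lineno, line in enumerate(lines, start=2 if has_header else 1):
        fields = line.split(delimiter)
        if has_rownames:
            gene_ids.append(fields[0])
            fields = fields[1:]
        if width is None:
            width = len(fields)
        elif len(fields) != width:
            raise FormatError(
                f"ragged row at line {lineno} of {path}: "
                f"expected {width} fields, got {len(fields)}"
            )
        rows.append(
            [_parse_float(tok, len(rows), j) for j, tok in enumerate(fields)]
        )
    return ExpressionDataset(np.array(rows, dtype=np.float64), gene_ids, cell_ids)


def read_pseudotime(path: str | Path, column_layout: str = "id_time") -> PseudotimeTable:
    """Read a pseudotime table, one cell per line.

    Layouts: ``index_time`` (integer cell index + time, the original
    SCODE convention), ``id_time`` (cell id string + time), ``time_only``
    (a single time field; positional cell ids are synthesized).
    """
    if column_layout not in ("index_time", "id_time", "time_only"):
        raise ValueError(f"unknown pseudotime layout {column_layout!r}")
    lines = _read_lines(path)
    cell_ids: list[str] = []
    times: list[float] = []
    for i, line in enumerate(lines):
        fields = line.split("\t")
        if column_layout == "time_only":
            if len(fields) != 1:
                raise FormatError(
                    f"line {i + 1}: expected 1 field for time_only, got {len(fields)}"
                )
            cell_ids.append(_synth_id("c", i))
            times.append(_parse_float(fields[0], i, 0))
        else:
            if len(fields) != 2:
                raise FormatError(
                    f"line {i + 1}: expected 2 fields for {column_layout}, got {len(fields)}"
                )
            if column_layout == "index_time":
                try:
                    idx = int(fields[0])
                except ValueError:
                    raise ParseError(
                        f"cannot parse cell index {fields[0]!r} at line {i + 1}"
                    ) from None
                cell_ids.append(_synth_id("c", idx))
            else:
                cell_ids.append(fields[0])
            times.append(_parse_float(fields[1], i, 1))
    return PseudotimeTable(cell_ids, np.array(times, dtype=np.float64))


def align(
    dataset: ExpressionDataset,
    times: PseudotimeTable,
    normalize: bool = True,
) -> tuple[ExpressionDataset, PseudotimeTable]:
    """Co-order pseudotimes to the dataset's column order.

    With ``normalize`` (default), times are rescaled to [0, 1] by dividing
    by the maximum, which keeps e^{b t} within floating-point range for
    the default sampling range of b.  The rescaling factor is logged.
    Idempotent: aligning an already aligned, normalized pair is a no-op.
    """
    if dataset.n_cells != times.n_cells:
        raise AlignmentError(
            f"{dataset.n_cells} dataset cells vs {times.n_cells} pseudotime entries"
        )
    pos = {cid: k for k, cid in enumerate(times.cell_ids)}
    missing_in_times = [c for c in dataset.cell_ids if c not in pos]
    missing_in_data = [c for c in times.cell_ids if c not in set(dataset.cell_ids)]
    if missing_in_times or missing_in_data:
        raise AlignmentError(
            "cell id mismatch; missing from pseudotime table: "
            f"{missing_in_times[:10]}; missing from dataset: {missing_in_data[:10]}"
        )
    order = [pos[c] for c in dataset.cell_ids]
    t = times.times[order]
    if normalize:
        tmax = float(t.max())
        if tmax > 0 and tmax != 1.0:
            logger.info("normalizing pseudotime by factor %.6g", tmax)
            t = t / tmax
    return dataset, PseudotimeTable(list(dataset.cell_ids), t)


def write_matrix(
    matrix: np.ndarray,
    path: str | Path,
    row_ids: list[str] | None = None,
    col_ids: list[str] | None = None,
) -> None:
    """Write a real matrix as TSV at full round-trip precision.

    Output bytes are deterministic for a fixed input.  A header line is
    written iff ``col_ids`` is given; a leading id column iff ``row_ids``.
    """
    M = np.atleast_2d(np.asarray(matrix, dtype=np.float64))
    if M.size == 0:
        raise FormatError("refusing to write an empty matrix")
    n_rows, n_cols = M.shape
    if row_ids is not None and len(row_ids) != n_rows:
        raise FormatError(f"{len(row_ids)} row ids for {n_rows} rows")
    if col_ids is not None and len(col_ids) != n_cols:
        raise FormatError(f"{len(col_ids)} column ids for {n_cols} columns")
    out: list[str] = []
    if col_ids is not None:
        head = list(col_ids)
        if row_ids is not None:
            head = [""] + head
        out.append("\t".join(head))
    for i in range(n_rows):
        cells = [format(v, _FLOAT_FMT) for v in M[i]]
        if row_ids is not None:
            cells = [row_ids[i]] + cells
        out.append("\t".join(cells))
    Path(path).write_text("\n".join(out) + "\n")


def _read_lines(path: str | Path) -> list[str]:
    text = Path(path).read_text()
    lines = [ln for ln in text.split("\n") if ln != ""]
    if not lines:
        raise FormatError(f"empty input file: {path}")
    return lines
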