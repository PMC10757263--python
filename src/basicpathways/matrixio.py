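"""Lossless TSV round trip for labelled rational matrices.

Layout: first row holds column labels (first cell is a corner label),
first column holds row labels, and every cell is an integer or "p/q"
string, so the file re-parses to exactly the matrix that was written.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

from .errors import MatrixIOError
from .ratmat import RationalMatrix, format_fraction

PathLike = Union[str, Path]


def save_matrix(
    M: RationalMatrix,
    path: PathLike,
    row_labels: Sequence[str],
    col_labels: Sequence[str],
    corner: str = "id",
) -> None:
    if len(row_labels) != M.nrows or len(col_labels) != M.ncols:
        raise MatrixIOError(
            f"label counts ({len(row_labels)}, {len(col_labels)}) do not match "
            f"matrix shape {M.shape}"
        )
    lines = ["\t".join([corner, *col_labels])]
    for i, label in enumerate(row_labels):
        lines.append(
            "\t".join([label, *(format_fraction(x) for x in M.rows[i])])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_matrix(path: PathLike) -> tuple[RationalMatrix, list[str], list[str]]:
    """Read a labelled TSV matrix; returns (matrix, row_labels, col_labels)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise MatrixIOError("empty matrix file")
    header = lines[0].split("\t")
    col_labels = header[1:]
    width = len(col_labels)
    if width == 0:
        raise MatrixIOError("matrix file has no data columns")
    row_labels: list[str] = []
    rows: list[list[str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != width + 1:
            raise MatrixIOError(
                f"line {lineno}: expected {width + 1} cells, found {len(cells)}"
            )
        row_labels.append(cells[0])
        rows.append(cells[1:])
    if not rows:
        raise MatrixIOError("matrix file has no data rows")
    try:
        M = RationalMatrix(rows)
    except (ValueError, ZeroDivisionError) as exc:
        raise MatrixIOError(f"bad rational cell: {exc}") from exc
    return M, row_labels, col_labels
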