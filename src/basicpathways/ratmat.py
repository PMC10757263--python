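"""Dense matrices of exact rational numbers.

Every quantity in this package that feeds a zero test (singleton counting,
sparsity, rank, cone membership) is stored as a :class:`fractions.Fraction`,
so equality to zero is exact and never subject to floating-point tolerance.
Matrices are small (tens of rows/columns), so a plain row-major list of
lists is both simple and fast enough.
"""

from __future__ import annotations

from fractions import Fraction
from math import gcd
from typing import Iterable, Sequence, Union

Rational = Union[int, str, Fraction]


def as_fraction(x: Rational) -> Fraction:
    """Convert *x* to an exact Fraction.

    Accepts ints, Fractions, "p/q" strings, and decimal strings such as
    "0.5" (converted exactly, 0.5 -> 1/2).
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, bool):  # bool is an int subclass; reject to catch bugs
        raise TypeError("boolean is not a rational coefficient")
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, float):
        raise TypeError(
            "float coefficients are not accepted; pass an int, Fraction, "
            "or a string such as '1/3' or '0.5'"
        )
    if isinstance(x, str):
        return Fraction(x)  # Fraction parses both "p/q" and decimal strings exactly
    raise TypeError(f"cannot interpret {x!r} as a rational number")


def format_fraction(x: Fraction) -> str:
    """Serialize a Fraction as an integer string or 'p/q'."""
    if x.denominator == 1:
        return str(x.numerator)
    return f"{x.numerator}/{x.denominator}"


class RationalMatrix:
    """A dense matrix of exact rationals.

    Instances are mutable only through explicit methods; the column-operation
    engine copies before modifying so intermediate matrices can be logged.
    """

    __slots__ = ("rows", "nrows", "ncols")

    def __init__(self, rows: Iterable[Sequence[Rational]]):
        self.rows: list[list[Fraction]] = [
            [as_fraction(x) for x in row] for row in rows
        ]
        self.nrows = len(self.rows)
        self.ncols = len(self.rows[0]) if self.rows else 0
        for row in self.rows:
            if len(row) != self.ncols:
                raise ValueError("ragged rows: all rows must have equal length")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def zeros(cls, nrows: int, ncols: int) -> "RationalMatrix":
        return cls([[0] * ncols for _ in range(nrows)])

    @classmethod
    def identity(cls, n: int) -> "RationalMatrix":
        m = cls.zeros(n, n)
        for i in range(n):
            m.rows[i][i] = Fraction(1)
        return m

    @classmethod
    def from_columns(cls, cols: Sequence[Sequence[Rational]]) -> "RationalMatrix":
        ncols = len(cols)
        nrows = len(cols[0]) if ncols else 0
        return cls([[cols[j][i] for j in range(ncols)] for i in range(nrows)])

    def copy(self) -> "RationalMatrix":
        out = RationalMatrix.__new__(RationalMatrix)
        out.rows = [row[:] for row in self.rows]
        out.nrows = self.nrows
        out.ncols = self.ncols
        return out

    # -- basic queries --------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def __getitem__(self, ij: tuple[int, int]) -> Fraction:
        i, j = ij
        return self.rows[i][j]

    def __setitem__(self, ij: tuple[int, int], value: Rational) -> None:
        i, j = ij
        self.rows[i][j] = as_fraction(value)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, RationalMatrix)
            and self.shape == other.shape
            and self.rows == other.rows
        )

    def __hash__(self):  # pragma: no cover - matrices are not hashable
        raise TypeError("RationalMatrix is unhashable")

    def __repr__(self) -> str:
        return f"RationalMatrix({self.nrows}x{self.ncols})"

    def column(self, j: int) -> list[Fraction]:
        return [self.rows[i][j] for i in range(self.nrows)]

    def row(self, i: int) -> list[Fraction]:
        return self.rows[i][:]

    def columns(self) -> list[list[Fraction]]:
        return [self.column(j) for j in range(self.ncols)]

    def is_nonnegative(self) -> bool:
        return all(x >= 0 for row in self.rows for x in row)

    def is_zero(self) -> bool:
        return all(x == 0 for row in self.rows for x in row)

    def nonzero_count(self) -> int:
        return sum(1 for row in self.rows for x in row if x != 0)

    # -- arithmetic -----------------------------------------------------------

    def __matmul__(self, other: "RationalMatrix") -> "RationalMatrix":
        if self.ncols != other.nrows:
            raise ValueError(
                f"shape mismatch: {self.shape} @ {other.shape}"
            )
        out = RationalMatrix.zeros(self.nrows, other.ncols)
        for i in range(self.nrows):
            srow = self.rows[i]
            orow = out.rows[i]
            for k in range(self.ncols):
                a = srow[k]
                if a == 0:
                    continue
                brow = other.rows[k]
                for j in range(other.ncols):
                    if brow[j] != 0:
                        orow[j] += a * brow[j]
        return out

    def matvec(self, v: Sequence[Rational]) -> list[Fraction]:
        if len(v) != self.ncols:
            raise ValueError(f"length mismatch: matrix has {self.ncols} columns")
        vf = [as_fraction(x) for x in v]
        return [
            sum((row[j] * vf[j] for j in range(self.ncols)), Fraction(0))
            for row in self.rows
        ]

    def hstack(self, other: "RationalMatrix") -> "RationalMatrix":
        if self.nrows != other.nrows:
            raise ValueError("row count mismatch in hstack")
        return RationalMatrix(
            [self.rows[i] + other.rows[i] for i in range(self.nrows)]
        )

    def vstack(self, other: "RationalMatrix") -> "RationalMatrix":
        if self.ncols != other.ncols:
            raise ValueError("column count mismatch in vstack")
        return RationalMatrix(self.rows + other.rows)

    def submatrix(self, row_idx: Sequence[int], col_idx: Sequence[int]) -> "RationalMatrix":
        return RationalMatrix(
            [[self.rows[i][j] for j in col_idx] for i in row_idx]
        )

    def scaled(self, c: Rational) -> "RationalMatrix":
        cf = as_fraction(c)
        return RationalMatrix([[cf * x for x in row] for row in self.rows])

    # -- exact rank -----------------------------------------------------------

    def rank(self) -> int:
        """Exact rank by fraction-free (Bareiss) Gaussian elimination.

        Entries are first scaled row-wise to integers so that the Bareiss
        recurrence stays in integer arithmetic throughout.
        """
        if self.nrows == 0 or self.ncols == 0:
            return 0
        # clear denominators per row (row scaling preserves rank)
        work: list[list[int]] = []
        for row in self.rows:
            denom_lcm = 1
            for x in row:
                denom_lcm = denom_lcm * x.denominator // gcd(denom_lcm, x.denominator)
            work.append([int(x * denom_lcm) for x in row])
        n, m = self.nrows, self.ncols
        rank = 0
        prev_pivot = 1
        pivot_col = 0
        r = 0
        while r < n and pivot_col < m:
            # find pivot in column pivot_col at or below row r
            piv = None
            for i in range(r, n):
                if work[i][pivot_col] != 0:
                    piv = i
                    break
            if piv is None:
                pivot_col += 1
                continue
            work[r], work[piv] = work[piv], work[r]
            p = work[r][pivot_col]
            for i in range(r + 1, n):
                for j in range(pivot_col + 1, m):
                    work[i][j] = (p * work[i][j] - work[i][pivot_col] * work[r][j]) // prev_pivot
                work[i][pivot_col] = 0
            prev_pivot = p
            rank += 1
            r += 1
            pivot_col += 1
        return rank


def rref(M: RationalMatrix) -> tuple[RationalMatrix, list[int]]:
    """Reduced row-echelon form over exact rationals; returns (R, pivot columns)."""
    R = M.copy()
    pivots: list[int] = []
    r = 0
    for c in range(R.ncols):
        piv = next((i for i in range(r, R.nrows) if R.rows[i][c] != 0), None)
        if piv is None:
            continue
        R.rows[r], R.rows[piv] = R.rows[piv], R.rows[r]
        p = R.rows[r][c]
        R.rows[r] = [x / p for x in R.rows[r]]
        for i in range(R.nrows):
            if i != r and R.rows[i][c] != 0:
                f = R.rows[i][c]
                R.rows[i] = [x - f * y for x, y in zip(R.rows[i], R.rows[r])]
        pivots.append(c)
        r += 1
        if r == R.nrows:
            break
    return R, pivots


def nullspace(M: RationalMatrix) -> list[list[Fraction]]:
    """Exact basis of Null(M), one vector per free column."""
    R, pivots = rref(M)
    free = [c for c in range(M.ncols) if c not in pivots]
    basis: list[list[Fraction]] = []
    for fc in free:
        v = [Fraction(0)] * M.ncols
        v[fc] = Fraction(1)
        for r_i, pc in enumerate(pivots):
            v[pc] = -R.rows[r_i][fc]
        basis.append(v)
    return basis


def solve_exact(A: RationalMatrix, b: Sequence[Fraction]) -> Union[list[Fraction], None]:
    """A particular exact solution of A x = b (free variables set to 0).

    Returns None when the system is inconsistent.
    """
    aug = A.hstack(RationalMatrix([[x] for x in b]))
    R, pivots = rref(aug)
    if A.ncols in pivots:  # pivot in the appended column: inconsistent
        return None
    x = [Fraction(0)] * A.ncols
    for r_i, pc in enumerate(pivots):
        x[pc] = R.rows[r_i][A.ncols]
    return x


def primitive_column(col: Sequence[Fraction]) -> list[Fraction]:
    """Scale a rational vector to primitive integer form.

    The result has integer entries with overall gcd 1 and the same direction
    (scaling factor is strictly positive). The zero vector is returned as is.
    """
    denom_lcm = 1
    for x in col:
        denom_lcm = denom_lcm * x.denominator // gcd(denom_lcm, x.denominator)
    ints = [int(x * denom_lcm) for x in col]
    g = 0
    for v in ints:
        g = gcd(g, abs(v))
    if g == 0:
        return [Fraction(0)] * len(col)
    return [Fraction(v, g) for v in ints]
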