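"""Singleton bookkeeping for rational matrices.

A *singleton row* has exactly one nonzero entry; that entry is a
*singleton element* of its column. A matrix is *singleton complete* when
every column owns at least one singleton element; the number of columns
owning none is the *singleton deficiency index*. ("Singleton row rank"
and "singleton row index" are used interchangeably for the count of
singleton rows.)

These counts matter because a singleton element pins the mixing
coefficient of its column: if row i is a singleton row of a null-basis
matrix W with entry w_ij, then any v = W.r has v_i = r_j * w_ij, so r_j
can be read off one component of v. Column operations are therefore
scored by how much singleton structure they destroy or create.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .errors import DomainError
from .ratmat import RationalMatrix


@dataclass(frozen=True)
class SingletonProfile:
    singleton_rows: frozenset[int]
    column_singletons: dict[int, frozenset[int]]  # column j -> its singleton rows i(j)
    row_rank: int
    deficiency_index: int

    @property
    def complete(self) -> bool:
        return self.deficiency_index == 0

    def deficient_columns(self) -> list[int]:
        return [j for j, rows in self.column_singletons.items() if not rows]

    def pick_singleton_row(self, j: int) -> int:
        """The canonical i(j): smallest singleton row of column j."""
        rows = self.column_singletons[j]
        if not rows:
            raise DomainError(f"column {j} has no singleton element")
        return min(rows)


@dataclass(frozen=True)
class SingletonCost:
    """Cost of a column operation; positive = degradation.

    type_I : decrease in singleton row rank
    type_II : increase in singleton deficiency index
    """

    type_I: int
    type_II: int

    def __iter__(self):
        yield self.type_I
        yield self.type_II


def singleton_profile(M: RationalMatrix) -> SingletonProfile:
    singleton_rows: set[int] = set()
    col_map: dict[int, set[int]] = {j: set() for j in range(M.ncols)}
    for i, row in enumerate(M.rows):
        nz = [j for j, x in enumerate(row) if x != 0]
        if len(nz) == 1:
            singleton_rows.add(i)
            col_map[nz[0]].add(i)
    deficiency = sum(1 for j in range(M.ncols) if not col_map[j])
    return SingletonProfile(
        singleton_rows=frozenset(singleton_rows),
        column_singletons={j: frozenset(v) for j, v in col_map.items()},
        row_rank=len(singleton_rows),
        deficiency_index=deficiency,
    )


def sparsity(M: RationalMatrix) -> Fraction:
    """Exact fraction of zero entries (1 means the zero matrix)."""
    total = M.nrows * M.ncols
    if total == 0:
        raise DomainError("sparsity of an empty matrix is undefined")
    return Fraction(total - M.nonzero_count(), total)


def sparsity_2dp(M: RationalMatrix) -> float:
    """Sparsity rounded half-up to two decimals, for report comparison."""
    s = sparsity(M)
    return float((100 * s + Fraction(1, 2)).__floor__()) / 100


def singleton_cost(M_before: RationalMatrix, M_after: RationalMatrix) -> SingletonCost:
    if M_before.shape != M_after.shape:
        raise DomainError(
            f"shape mismatch: {M_before.shape} vs {M_after.shape}"
        )
    before = singleton_profile(M_before)
    after = singleton_profile(M_after)
    return SingletonCost(
        type_I=before.row_rank - after.row_rank,
        type_II=after.deficiency_index - before.deficiency_index,
    )
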