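"""Transforming G into the nonnegative basic-pathways matrix W.

The engine applies the three elementary column operations — positive
scaling, column swap, and adding a positive multiple of one column to
another — to the fundamental null basis G. Each operation preserves the
span (the columns always remain a null basis of S) and keeps the top
r x r block nonnegative.

``eliminate_negatives`` repairs the bottom block row by row, starting
from row n and moving upward. A row that is entrywise nonnegative can
never regain a negative entry (a new negative would need an existing
negative in that row), so every repaired row is settled for good. Within
the current row, each negative entry w_ij is cancelled exactly by
c_j <- c_j + a*c_k with w_ik > 0 and a = -w_ij/w_ik.

The pivot is chosen to minimize measured singleton cost (Type-I, then
Type-II), breaking ties by pivot sparsity and column index. A greedy
choice can paint the sweep into a corner — a later row may be left with
no positive entry in any column even though a nonnegative basis exists —
so the elimination runs as a deterministic depth-first search: first the
strict bottom-up repair order with backtracking over pivot choices, then,
only if that tree is exhausted, an adaptive order that repairs the most
constrained row first (equivalent to running the sweep on a row-permuted
network). On feasible inputs the greedy branch almost always succeeds
outright.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Literal, Optional, Sequence

from .errors import DegeneracyError, DomainError
from .model import StoichiometricModel
from .nullbasis import FundamentalNullBasis, build_fundamental_null_basis
from .ratmat import RationalMatrix, primitive_column
from .singleton import SingletonProfile, singleton_profile

OpKind = Literal["scale", "swap", "add_multiple"]


@dataclass(frozen=True)
class ColumnOperation:
    kind: OpKind
    target: int
    source: Optional[int] = None  # swap / add_multiple only
    coefficient: Optional[Fraction] = None  # scale / add_multiple only

    def __post_init__(self):
        if self.kind == "scale":
            if self.coefficient is None or self.coefficient <= 0:
                raise DomainError("scale coefficient must be strictly positive")
        elif self.kind == "swap":
            if self.source is None:
                raise DomainError("swap needs a source column")
        elif self.kind == "add_multiple":
            if self.source is None or self.coefficient is None:
                raise DomainError("add_multiple needs a source and a coefficient")
            if self.coefficient == 0:
                raise DomainError("add_multiple coefficient must be nonzero")
        else:
            raise DomainError(f"unknown operation kind {self.kind!r}")


def apply_column_op(M: RationalMatrix, op: ColumnOperation) -> RationalMatrix:
    """Return a new matrix with *op* applied; the input is untouched."""
    for idx in (op.target, op.source):
        if idx is not None and not (0 <= idx < M.ncols):
            raise DomainError(f"column index {idx} out of range for {M.shape}")
    out = M.copy()
    if op.kind == "scale":
        for i in range(out.nrows):
            out.rows[i][op.target] *= op.coefficient
    elif op.kind == "swap":
        for i in range(out.nrows):
            row = out.rows[i]
            row[op.target], row[op.source] = row[op.source], row[op.target]
    else:  # add_multiple
        for i in range(out.nrows):
            src = out.rows[i][op.source]
            if src != 0:
                out.rows[i][op.target] += op.coefficient * src
    return out


@dataclass(frozen=True)
class BasicPathwayBasis:
    """A nonnegative null basis W = (BP_1, ..., BP_r) with its operation log."""

    W: RationalMatrix
    op_log: tuple[ColumnOperation, ...]
    source: FundamentalNullBasis

    @property
    def model(self) -> StoichiometricModel:
        return self.source.model

    @property
    def r(self) -> int:
        return self.W.ncols

    @property
    def n(self) -> int:
        return self.W.nrows

    @property
    def profile(self) -> SingletonProfile:
        return singleton_profile(self.W)

    def column(self, j: int) -> list[Fraction]:
        return self.W.column(j)

    def replay(self) -> RationalMatrix:
        """Re-apply the operation log to G; must reproduce W bit-exactly."""
        M = self.source.G.copy()
        for op in self.op_log:
            M = apply_column_op(M, op)
        return M


# -- pivot scoring -----------------------------------------------------------


def _measured_cost(M: RationalMatrix, i: int, j: int, k: int) -> tuple[int, int]:
    """Singleton cost (Type-I, Type-II) of c_j <- c_j + a*c_k cancelling row i."""
    a = -M.rows[i][j] / M.rows[i][k]
    trial = apply_column_op(
        M, ColumnOperation("add_multiple", target=j, source=k, coefficient=a)
    )
    before = singleton_profile(M)
    after = singleton_profile(trial)
    return (before.row_rank - after.row_rank,
            after.deficiency_index - before.deficiency_index)


def default_pivot_key(
    M: RationalMatrix, i: int, j: int, k: int
) -> tuple:
    """Ranking key for pivot candidates; lower is better.

    Order: measured Type-I cost, measured Type-II cost, nonzero count of the
    pivot column, pivot column index. The cost terms implement the
    minimize-net-singleton-cost objective; the sparsity term prefers pivots
    that cause little fill-in; the index makes the rule deterministic.
    """
    t1, t2 = _measured_cost(M, i, j, k)
    nnz = sum(1 for x in M.column(k) if x != 0)
    return (t1, t2, nnz, k)


PivotKey = Callable[[RationalMatrix, int, int, int], tuple]


def _canonicalize(M: RationalMatrix, log: list[ColumnOperation]) -> RationalMatrix:
    """Scale every column to primitive integer form, logging the scalings."""
    for j in range(M.ncols):
        col = M.column(j)
        prim = primitive_column(col)
        # find the positive scaling factor (columns are nonzero: basis)
        factor = None
        for x, p in zip(col, prim):
            if x != 0:
                factor = p / x
                break
        if factor is not None and factor != 1:
            op = ColumnOperation("scale", target=j, coefficient=factor)
            M = apply_column_op(M, op)
            log.append(op)
    return M


def _stranded_row(M: RationalMatrix) -> Optional[int]:
    """A row holding a negative entry but no positive one anywhere.

    Such a row can never be repaired: every further operation adds positive
    multiples of columns that are nonpositive in that row. Used to prune
    dead search branches early.
    """
    for i, row in enumerate(M.rows):
        has_neg = False
        has_pos = False
        for x in row:
            if x < 0:
                has_neg = True
            elif x > 0:
                has_pos = True
                break
        if has_neg and not has_pos:
            return i
    return None


def eliminate_negatives(
    G: FundamentalNullBasis,
    pivot_key: PivotKey = default_pivot_key,
    max_nodes: int = 50_000,
) -> BasicPathwayBasis:
    """Transform G into an entrywise-nonnegative basic-pathways basis W.

    Raises DegeneracyError when a row has no positive pivot anywhere in the
    search tree (the model needs network reduction first).
    """
    r, n = G.r, G.n
    log: list[ColumnOperation] = []
    budget = [max_nodes]

    def pivot_count(M: RationalMatrix, i: int) -> int:
        return sum(1 for x in M.rows[i] if x > 0)

    def clean_row(M, ops, i, adaptive):
        """Remove every negative entry of row i (left to right), branching
        over pivot choices, then continue with the remaining rows."""
        row = M.rows[i]
        j_neg = next((j for j in range(r) if row[j] < 0), None)
        if j_neg is None:
            return sweep(M, ops, adaptive)
        pivots = [k for k in range(r) if k != j_neg and row[k] > 0]
        scored = []
        for k in pivots:
            if budget[0] <= 0:
                raise _BudgetExhausted()
            budget[0] -= 1
            a = -row[j_neg] / row[k]
            op = ColumnOperation(
                "add_multiple", target=j_neg, source=k, coefficient=a
            )
            trial = apply_column_op(M, op)
            if _stranded_row(trial) is not None:
                continue  # provably dead: skip without descending
            scored.append((pivot_key(M, i, j_neg, k), op, trial))
        scored.sort(key=lambda item: item[0])
        for _, op, trial in scored:
            result = clean_row(trial, ops + [op], i, adaptive)
            if result is not None:
                return result
        return None

    def sweep(M, ops, adaptive):
        """Pick the next row to repair. An entrywise-nonnegative row can
        never regain a negative entry (new negatives in a row need an
        existing negative there), so each cleaned row is settled for good
        and the dirty-row set shrinks monotonically. The strict pass takes
        rows bottom-up with no alternatives; the adaptive pass branches
        over the repair order (most-constrained row first), which is
        equivalent to running the strict sweep on a row-permuted network."""
        dirty = [
            i
            for i in range(n - 1, r - 1, -1)
            if any(M.rows[i][j] < 0 for j in range(r))
        ]
        if not dirty:
            return M, ops
        if not adaptive:
            return clean_row(M, ops, dirty[0], adaptive)
        dirty.sort(key=lambda i: pivot_count(M, i))
        for i in dirty:
            result = clean_row(M, ops, i, adaptive)
            if result is not None:
                return result
        return None

    class _BudgetExhausted(Exception):
        pass

    solved = None
    for adaptive in (False, True):
        budget[0] = max_nodes
        try:
            solved = sweep(G.G.copy(), [], adaptive)
        except _BudgetExhausted:
            solved = None
        if solved is not None:
            break
    if solved is None:
        raise DegeneracyError(
            "no sequence of positive column operations removes all negative "
            "entries within the search budget; run reduce_network and retry "
            "on the reduced model"
        )
    W, log = solved
    W = _canonicalize(W, log)
    assert W.is_nonnegative()
    return BasicPathwayBasis(W=W, op_log=tuple(log), source=G)


def compute_basic_pathways(
    model: StoichiometricModel,
    sparsify_result: bool = True,
    pivot_key: PivotKey = default_pivot_key,
) -> BasicPathwayBasis:
    """Model-to-W convenience pipeline: G construction plus elimination."""
    G = build_fundamental_null_basis(model)
    basis = eliminate_negatives(G, pivot_key=pivot_key)
    if sparsify_result:
        basis = sparsify(basis)
    return basis


# -- sparsification ----------------------------------------------------------


def _lex_quality(M: RationalMatrix) -> tuple[int, int]:
    prof = singleton_profile(M)
    return (prof.deficiency_index, M.nonzero_count())


def sparsify(basis: BasicPathwayBasis) -> BasicPathwayBasis:
    """Guarded subtraction pass: c_j <- c_j - a*c_k keeping W >= 0.

    For each ordered pair (j, k) the largest a > 0 that keeps column j
    nonnegative is a = min over rows with w_ik > 0 of w_ij / w_ik; the
    replacement is kept only when it strictly improves the pair
    (deficiency index, nonzero count) lexicographically. Iterates to a
    fixed point. Subtraction sits outside the positive-coefficient
    elimination, so the pass re-checks nonnegativity by construction and
    preserves rank (elementary column operation with j != k).
    """
    W = basis.W.copy()
    log = list(basis.op_log)
    improved = True
    while improved:
        improved = False
        best = _lex_quality(W)
        for j in range(W.ncols):
            for k in range(W.ncols):
                if j == k:
                    continue
                ratios = [
                    W.rows[i][j] / W.rows[i][k]
                    for i in range(W.nrows)
                    if W.rows[i][k] > 0
                ]
                if not ratios:
                    continue
                a = min(ratios)
                if a <= 0:
                    continue
                op = ColumnOperation("add_multiple", target=j, source=k, coefficient=-a)
                trial = apply_column_op(W, op)
                if _lex_quality(trial) < best:
                    W = trial
                    log.append(op)
                    best = _lex_quality(W)
                    improved = True
    W = _canonicalize(W, log)
    assert W.is_nonnegative()
    return BasicPathwayBasis(W=W, op_log=tuple(log), source=basis.source)


# -- permutation variants ----------------------------------------------------


def permuted_basis(
    model: StoichiometricModel,
    row_permutation: Sequence[int],
    sparsify_result: bool = False,
) -> BasicPathwayBasis:
    """Run the pipeline on a metabolite-permuted model, then un-permute.

    ``row_permutation`` maps new position -> original metabolite index.
    Because basic-pathway bases are not unique, different permutations can
    give genuinely different (all valid) bases for the same model.
    """
    m = model.m
    perm = list(row_permutation)
    if sorted(perm) != list(range(m)):
        raise DomainError(
            f"row_permutation must be a bijection on 0..{m - 1}"
        )
    permuted = StoichiometricModel(
        metabolite_ids=tuple(model.metabolite_ids[p] for p in perm),
        reaction_ids=model.reaction_ids,
        S0=model.S0.submatrix(perm, range(model.r)),
        reversible=model.reversible,
        dilution_rates=tuple(model.dilution_rates[p] for p in perm),
        provenance=model.provenance + ("permuted",),
    )
    basis = compute_basic_pathways(permuted, sparsify_result=sparsify_result)
    # un-permute the bottom m rows (dilution fluxes) back to original order
    r = model.r
    inverse = [0] * m
    for new_pos, orig in enumerate(perm):
        inverse[orig] = new_pos
    rows = [basis.W.rows[i][:] for i in range(r)] + [
        basis.W.rows[r + inverse[i]][:] for i in range(m)
    ]
    W = RationalMatrix(rows)
    G_orig = build_fundamental_null_basis(model)
    return BasicPathwayBasis(W=W, op_log=basis.op_log, source=G_orig)
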