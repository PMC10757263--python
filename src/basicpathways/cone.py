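"""Flux-cone operations over a basic-pathway basis.

The admissible set is the closed, pointed polyhedral cone
N+ = {v >= 0 : S v = 0}. A basic-pathway basis W spans Null(S), so any
steady pathway v has a unique coefficient vector r with v = W r. When W
is singleton complete, v >= 0 holds iff r >= 0, and every r_j is read
off a single component of v. When W is singleton deficient, the
coefficients of deficient columns may legitimately be negative, bounded
below by the requirement that W r stays entrywise nonnegative; those
bounds are computed here exactly.

Strict inequalities in the bound derivations are implemented as their
closures: the admissible set includes boundary pathways with zero fluxes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional, Sequence

from .errors import DomainError
from .ratmat import (
    RationalMatrix,
    Rational,
    as_fraction,
    nullspace,
    primitive_column,
    solve_exact,
)
from .transform import BasicPathwayBasis


def _as_vec(v: Sequence[Rational]) -> list[Fraction]:
    return [as_fraction(x) for x in v]


def is_admissible(S: RationalMatrix, v: Sequence[Rational]) -> bool:
    """True iff S v = 0 exactly and every component of v is >= 0."""
    vf = _as_vec(v)
    if len(vf) != S.ncols:
        raise DomainError(
            f"vector length {len(vf)} does not match {S.ncols} columns"
        )
    if any(x < 0 for x in vf):
        return False
    return all(x == 0 for x in S.matvec(vf))


@dataclass(frozen=True)
class PathwayDecomposition:
    coefficients: tuple[Fraction, ...]
    independent_components: tuple[int, ...]  # flux indices read as free parameters
    dependent_components: dict[int, Fraction]  # remaining fluxes, reconstructed
    residual: Fraction  # max |v - W r|; exactly 0 on success


def decompose_pathway(
    W: BasicPathwayBasis, v: Sequence[Rational]
) -> PathwayDecomposition:
    """Coefficients r with v = W r, via singleton reads plus a small solve.

    Every singleton-complete column's coefficient comes directly from its
    singleton row: r_j = v_i(j) / w_i(j)j. The remaining d deficient-column
    coefficients solve the exact residual system restricted to the rows
    where those columns appear. Requires v in Null(S); v need not be
    nonnegative for the algebra.
    """
    vf = _as_vec(v)
    n, r = W.n, W.r
    if len(vf) != n:
        raise DomainError(f"vector length {len(vf)} does not match n={n}")
    Svals = _augmented_S(W).matvec(vf)
    bad_rows = [i for i, x in enumerate(Svals) if x != 0]
    if bad_rows:
        raise DomainError(
            f"vector is not a steady-state pathway; S.v is nonzero in rows {bad_rows}"
        )
    prof = W.profile
    coeffs: list[Optional[Fraction]] = [None] * r
    for j in range(r):
        if prof.column_singletons[j]:
            i = prof.pick_singleton_row(j)
            coeffs[j] = vf[i] / W.W[i, j]
    deficient = [j for j in range(r) if coeffs[j] is None]
    if deficient:
        residual_vec = list(vf)
        for j in range(r):
            if coeffs[j] is not None and coeffs[j] != 0:
                for i in range(n):
                    residual_vec[i] -= coeffs[j] * W.W[i, j]
        rows = [
            i for i in range(n) if any(W.W[i, j] != 0 for j in deficient)
        ]
        A = W.W.submatrix(rows, deficient)
        sol = solve_exact(A, [residual_vec[i] for i in rows])
        # a true null vector always yields a consistent system
        assert sol is not None, "inconsistent residual system for a null vector"
        for j, val in zip(deficient, sol):
            coeffs[j] = val
    final = [c if c is not None else Fraction(0) for c in coeffs]
    recon = W.W.matvec(final)
    residual = max(
        (abs(a - b) for a, b in zip(vf, recon)), default=Fraction(0)
    )
    assert residual == 0, "exact reconstruction failed"
    independents = _independent_rows(W, prof, deficient)
    dependents = {
        i: vf[i] for i in range(n) if i not in set(independents)
    }
    return PathwayDecomposition(
        coefficients=tuple(final),
        independent_components=tuple(independents),
        dependent_components=dependents,
        residual=residual,
    )


def _independent_rows(W: BasicPathwayBasis, prof, deficient: list[int]) -> list[int]:
    """One flux index per column: i(j) for complete columns, then pivot rows
    extending them to an independent set for the deficient ones."""
    chosen = []
    used: set[int] = set()
    for j in range(W.r):
        if prof.column_singletons[j]:
            i = prof.pick_singleton_row(j)
            chosen.append(i)
            used.add(i)
    if deficient:
        # extend with rows that make the selected square system invertible
        base_cols = [j for j in range(W.r) if prof.column_singletons[j]]
        for i in range(W.n):
            if len(chosen) == W.r:
                break
            if i in used:
                continue
            trial_rows = chosen + [i]
            sub = W.W.submatrix(trial_rows, base_cols + deficient)
            if sub.rank() == len(trial_rows):
                chosen.append(i)
                used.add(i)
    return sorted(chosen)


def _augmented_S(W: BasicPathwayBasis) -> RationalMatrix:
    from .model import augment_with_dilution

    return augment_with_dilution(W.model).S


@dataclass(frozen=True)
class CoefficientBounds:
    """Exact lower-bound data for deficient-column coefficients.

    ``constraint_rows`` holds pairs (weights, c_j): the inequality reads
    sum_k |r_k| * weights[k] <= c_j over the deficient columns, for every
    row j in which all deficient-column entries are strictly positive.
    For d = 1 the single scalar bound is also exposed directly.
    """

    deficient_columns: tuple[int, ...]
    fixed_nonneg: dict[int, Fraction]
    lower_bound_d1: Optional[Fraction]
    constraint_rows: tuple[tuple[tuple[Fraction, ...], Fraction], ...]

    def is_feasible(self, coefficients: Sequence[Rational]) -> bool:
        """Membership in {r : W r >= 0} for the stored basis — by direct check."""
        return self._check(coefficients)

    def _attach(self, W: BasicPathwayBasis):
        object.__setattr__(self, "_W", W)
        return self

    def _check(self, coefficients: Sequence[Rational]) -> bool:
        W: BasicPathwayBasis = getattr(self, "_W")
        return all(x >= 0 for x in W.W.matvec(_as_vec(coefficients)))


def _full_coefficients(
    W: BasicPathwayBasis,
    fixed: Mapping[int, Fraction],
    deficient: Sequence[int],
    deficient_values: Sequence[Fraction],
) -> list[Fraction]:
    r = W.r
    out = [Fraction(0)] * r
    for j, val in fixed.items():
        out[j] = val
    for j, val in zip(deficient, deficient_values):
        out[j] = val
    return out


def coefficient_lower_bounds(
    W: BasicPathwayBasis, fixed: Mapping[int, Rational]
) -> CoefficientBounds:
    """Bounds on deficient-column coefficients keeping W r >= 0.

    ``fixed`` supplies a nonnegative coefficient for every singleton-complete
    column. For deficiency d = 1 the exact closed bound is returned:
    r_1 >= -min over rows i with w_i1 > 0 of (sum_j fixed_j w_ij) / w_i1.
    For d >= 2 the active inequality system over all-positive rows is
    returned together with a direct membership predicate.
    """
    prof = W.profile
    deficient = prof.deficient_columns()
    d = len(deficient)
    if d == 0:
        raise DomainError(
            "basis is singleton complete: nonnegative pathways correspond "
            "exactly to nonnegative coefficient vectors, no bounds needed"
        )
    fixed_f = {int(j): as_fraction(x) for j, x in fixed.items()}
    complete = [j for j in range(W.r) if j not in deficient]
    missing = [j for j in complete if j not in fixed_f]
    if missing:
        raise DomainError(f"missing fixed coefficients for complete columns {missing}")
    if any(v < 0 for v in fixed_f.values()):
        raise DomainError("fixed coefficients of complete columns must be >= 0")

    def c_of_row(i: int) -> Fraction:
        return sum(
            (fixed_f[j] * W.W[i, j] for j in complete), Fraction(0)
        )

    constraint_rows = []
    for i in range(W.n):
        weights = tuple(W.W[i, j] for j in deficient)
        if all(w > 0 for w in weights):
            constraint_rows.append((weights, c_of_row(i)))
    lower_bound_d1 = None
    if d == 1:
        j1 = deficient[0]
        candidates = [
            c_of_row(i) / W.W[i, j1] for i in range(W.n) if W.W[i, j1] > 0
        ]
        if candidates:
            lower_bound_d1 = -min(candidates)
    bounds = CoefficientBounds(
        deficient_columns=tuple(deficient),
        fixed_nonneg=fixed_f,
        lower_bound_d1=lower_bound_d1,
        constraint_rows=tuple(constraint_rows),
    )
    return bounds._attach(W)


def r_min_surface(
    W: BasicPathwayBasis,
    fixed: Mapping[int, Rational],
    direction: Sequence[Rational],
) -> Optional[Fraction]:
    """Radial feasibility bound along a direction in deficient-coefficient space.

    ``direction`` g >= 0 (not all zero) gives magnitudes |r| = rho * g for the
    deficient columns; the returned r_Min is the largest rho such that every
    0 <= rho <= r_Min keeps W r >= 0 (None when unbounded). The minimum runs
    over all rows with positive projected weight, so the bound is tight: at
    rho = r_Min some component of W r is exactly zero.
    """
    prof = W.profile
    deficient = prof.deficient_columns()
    if not deficient:
        raise DomainError("basis is singleton complete; no deficient directions")
    g = _as_vec(direction)
    if len(g) != len(deficient):
        raise DomainError(
            f"direction must have {len(deficient)} components (one per deficient column)"
        )
    if any(x < 0 for x in g):
        raise DomainError("direction components must be nonnegative")
    if all(x == 0 for x in g):
        raise DomainError("direction must be nonzero")
    fixed_f = {int(j): as_fraction(x) for j, x in fixed.items()}
    complete = [j for j in range(W.r) if j not in deficient]
    ratios = []
    for i in range(W.n):
        denom = sum(
            (g[k] * W.W[i, j] for k, j in enumerate(deficient)), Fraction(0)
        )
        if denom > 0:
            c_i = sum((fixed_f.get(j, Fraction(0)) * W.W[i, j] for j in complete), Fraction(0))
            ratios.append(c_i / denom)
    if not ratios:
        return None
    return min(ratios)


# -- extreme-ray testing and brute-force enumeration ------------------------


def is_extreme_ray(S: RationalMatrix, v: Sequence[Rational]) -> bool:
    """Support-rank test: v spans an extreme ray of {v >= 0 : S v = 0} iff
    rank of S restricted to the support of v equals |support| - 1."""
    vf = _as_vec(v)
    if all(x == 0 for x in vf):
        raise DomainError("the zero vector spans no ray")
    if not is_admissible(S, vf):
        raise DomainError("vector is not an admissible pathway")
    support = [j for j, x in enumerate(vf) if x != 0]
    sub = S.submatrix(range(S.nrows), support)
    return sub.rank() == len(support) - 1


def enumerate_extreme_rays_bruteforce(
    S: RationalMatrix, max_columns: int = 16, force: bool = False
) -> list[tuple[Fraction, ...]]:
    """All extreme rays of {v >= 0 : S v = 0}, by support enumeration.

    Exponential in the column count; refuses more than ``max_columns``
    columns unless forced. Returns primitive integer representatives,
    sorted, one per ray.
    """
    n = S.ncols
    if n > max_columns and not force:
        raise DomainError(
            f"{n} columns exceeds the brute-force guard ({max_columns}); "
            "pass force=True to override"
        )
    rays: dict[tuple[Fraction, ...], None] = {}
    cols = range(n)
    for size in range(1, n + 1):
        for support in itertools.combinations(cols, size):
            sub = S.submatrix(range(S.nrows), support)
            null = nullspace(sub)
            if len(null) != 1:
                continue
            w = null[0]
            if any(x == 0 for x in w):
                continue  # support is not exactly this set
            if all(x > 0 for x in w):
                pass
            elif all(x < 0 for x in w):
                w = [-x for x in w]
            else:
                continue
            v = [Fraction(0)] * n
            for idx, x in zip(support, w):
                v[idx] = x
            rays[tuple(primitive_column(v))] = None
    return sorted(rays.keys())
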