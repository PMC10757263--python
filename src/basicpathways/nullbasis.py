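"""The fundamental null basis G and the degenerate-row network reduction.

For S = (S0 | -Lambda) the null space has dimension r and a basis comes in
closed form: a flux vector (v0; v1) is steady iff v1 = Lambda^{-1} S0 v0,
so stacking the r x r identity over Lambda^{-1} S0 gives

    G = ( I_r ; Lambda^{-1} S0 ),

an n x r matrix whose columns g_1..g_r span Null(S) and whose embedded
identity block makes it a fundamental null basis (and trivially singleton
complete). No linear solve is involved.

If some S0 row has no strictly positive entry, the metabolite behind it can
only be consumed or diluted; at steady state its concentration (and every
flux touching it) is forced to zero. ``reduce_network`` removes such rows
and their incident columns to a fixed point, since each removal sweep can
expose new positive-free rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import DegeneracyError
from .model import StoichiometricModel
from .ratmat import RationalMatrix


@dataclass(frozen=True)
class FundamentalNullBasis:
    G: RationalMatrix  # n x r
    model: StoichiometricModel

    @property
    def r(self) -> int:
        return self.G.ncols

    @property
    def n(self) -> int:
        return self.G.nrows

    @property
    def top_block(self) -> RationalMatrix:
        return self.G.submatrix(range(self.r), range(self.r))

    @property
    def bottom_block(self) -> RationalMatrix:
        return self.G.submatrix(range(self.r, self.n), range(self.r))


@dataclass(frozen=True)
class ReductionResult:
    reduced_model: Optional[StoichiometricModel]  # None when everything was removed
    removed_metabolites: frozenset[str]
    removed_reactions: frozenset[str]
    iterations: int

    @property
    def is_empty(self) -> bool:
        return self.reduced_model is None

    @property
    def removed_anything(self) -> bool:
        return bool(self.removed_metabolites or self.removed_reactions)


def positive_free_rows(S0: RationalMatrix) -> list[int]:
    """Indices of rows without any strictly positive entry."""
    return [
        i for i, row in enumerate(S0.rows) if not any(x > 0 for x in row)
    ]


def build_fundamental_null_basis(model: StoichiometricModel) -> FundamentalNullBasis:
    """Construct G = (I_r ; Lambda^{-1} S0) for a non-degenerate model."""
    bad = positive_free_rows(model.S0)
    if bad:
        mets = ", ".join(model.metabolite_ids[i] for i in bad)
        raise DegeneracyError(
            f"rows without a positive entry (metabolites: {mets}); "
            "run reduce_network first — these concentrations vanish at steady state"
        )
    bottom = RationalMatrix(
        [
            [model.S0[i, j] / model.dilution_rates[i] for j in range(model.r)]
            for i in range(model.m)
        ]
    )
    G = RationalMatrix.identity(model.r).vstack(bottom)
    return FundamentalNullBasis(G=G, model=model)


def reduce_network(model: StoichiometricModel) -> ReductionResult:
    """Remove positive-free rows and their incident columns, to a fixed point.

    Removed metabolites are those whose concentration must vanish at steady
    state; removed reactions are those whose flux is thereby forced to zero.
    An empty result means the only admissible pathway is v = 0.
    """
    met_idx = list(range(model.m))
    rxn_idx = list(range(model.r))
    removed_mets: set[int] = set()
    removed_rxns: set[int] = set()
    iterations = 0
    while True:
        sub = model.S0.submatrix(met_idx, rxn_idx) if met_idx and rxn_idx else None
        if sub is None:
            break
        bad_local = positive_free_rows(sub)
        if not bad_local:
            break
        iterations += 1
        bad_global = {met_idx[i] for i in bad_local}
        removed_mets |= bad_global
        # drop every column with a nonzero entry in a removed row
        dead_cols = {
            j
            for j in rxn_idx
            if any(model.S0[i, j] != 0 for i in bad_global)
        }
        removed_rxns |= dead_cols
        met_idx = [i for i in met_idx if i not in bad_global]
        rxn_idx = [j for j in rxn_idx if j not in dead_cols]
    removed_met_ids = frozenset(model.metabolite_ids[i] for i in removed_mets)
    removed_rxn_ids = frozenset(model.reaction_ids[j] for j in removed_rxns)
    if not met_idx or not rxn_idx:
        return ReductionResult(
            reduced_model=None,
            removed_metabolites=frozenset(model.metabolite_ids) if not met_idx else removed_met_ids,
            removed_reactions=frozenset(model.reaction_ids) if not rxn_idx else removed_rxn_ids,
            iterations=iterations,
        )
    if not removed_mets and not removed_rxns:
        return ReductionResult(
            reduced_model=model,
            removed_metabolites=frozenset(),
            removed_reactions=frozenset(),
            iterations=0,
        )
    reduced = StoichiometricModel(
        metabolite_ids=tuple(model.metabolite_ids[i] for i in met_idx),
        reaction_ids=tuple(model.reaction_ids[j] for j in rxn_idx),
        S0=model.S0.submatrix(met_idx, rxn_idx),
        reversible=tuple(model.reversible[j] for j in rxn_idx),
        dilution_rates=tuple(model.dilution_rates[i] for i in met_idx),
        provenance=model.provenance + ("reduced",),
    )
    return ReductionResult(
        reduced_model=reduced,
        removed_metabolites=removed_met_ids,
        removed_reactions=removed_rxn_ids,
        iterations=iterations,
    )


def nullity(S: RationalMatrix) -> int:
    """Dimension of Null(S) = ncols - rank, by exact fraction-free elimination."""
    return S.ncols - S.rank()
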