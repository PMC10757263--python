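"""Reaction-network models and their stoichiometric matrices.

A model holds the internal stoichiometry S0 (m metabolites x r internal
reactions, exact rationals), per-reaction reversibility flags, and a
strictly positive dilution rate per metabolite. A growing cell drains
every metabolite at a rate proportional to its concentration, which adds
one pseudo-reaction per metabolite: the augmented stoichiometric matrix is

    S = (S0 | -Lambda),   Lambda = diag(lambda_1, ..., lambda_m)

with Lambda the dilution-rate diagonal (identity for a cell whose growth
rate has been absorbed into the dilution fluxes). Dilution columns always
come last, in metabolite order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence, Union

from .errors import ModelValidationError
from .ratmat import RationalMatrix, as_fraction, format_fraction

PathLike = Union[str, Path]


@dataclass(frozen=True)
class StoichiometricModel:
    """A validated metabolic reaction network.

    Attributes
    ----------
    metabolite_ids : ordered unique identifiers, length m
    reaction_ids : ordered unique identifiers of internal reactions, length r
    S0 : m x r internal stoichiometry, exact rationals
    reversible : one flag per internal reaction
    dilution_rates : strictly positive rate per metabolite (1/time)
    provenance : free-form notes (e.g. which reactions were reversed)
    """

    metabolite_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    S0: RationalMatrix
    reversible: tuple[bool, ...]
    dilution_rates: tuple[Fraction, ...]
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        m, r = len(self.metabolite_ids), len(self.reaction_ids)
        if m < 1 or r < 1:
            raise ModelValidationError("a model needs at least one metabolite and one reaction")
        if len(set(self.metabolite_ids)) != m:
            raise ModelValidationError("duplicate metabolite ids")
        if len(set(self.reaction_ids)) != r:
            raise ModelValidationError("duplicate reaction ids")
        if self.S0.shape != (m, r):
            raise ModelValidationError(
                f"S0 shape {self.S0.shape} does not match m={m}, r={r}"
            )
        if len(self.reversible) != r:
            raise ModelValidationError("reversible flags must match reaction count")
        if len(self.dilution_rates) != m:
            raise ModelValidationError("dilution rates must match metabolite count")
        if any(lam <= 0 for lam in self.dilution_rates):
            raise ModelValidationError("dilution rates must be strictly positive")
        for j, rid in enumerate(self.reaction_ids):
            if all(self.S0[i, j] == 0 for i in range(m)):
                raise ModelValidationError(
                    f"reaction {rid!r} has all-zero stoichiometry"
                )

    # -- basic dimensions -----------------------------------------------------

    @property
    def m(self) -> int:
        return len(self.metabolite_ids)

    @property
    def r(self) -> int:
        return len(self.reaction_ids)

    @property
    def n(self) -> int:
        """Total reaction count of the augmented system (internal + dilution)."""
        return self.m + self.r

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction id {reaction_id!r}") from None

    def metabolite_index(self, metabolite_id: str) -> int:
        try:
            return self.metabolite_ids.index(metabolite_id)
        except ValueError:
            raise KeyError(f"unknown metabolite id {metabolite_id!r}") from None

    def flux_labels(self) -> list[str]:
        """Row labels of null-basis matrices: reaction ids then dilution ids."""
        return list(self.reaction_ids) + [f"delta_{met}" for met in self.metabolite_ids]


@dataclass(frozen=True)
class AugmentedStoichiometry:
    """The m x (r+m) matrix S = (S0 | -Lambda) with column bookkeeping."""

    S: RationalMatrix
    column_roles: tuple[str, ...]  # reaction id, or "dilution:<metabolite>"
    provenance: StoichiometricModel

    @property
    def m(self) -> int:
        return self.S.nrows

    @property
    def n(self) -> int:
        return self.S.ncols


def augment_with_dilution(model: StoichiometricModel) -> AugmentedStoichiometry:
    """Append one dilution column per metabolite: S = (S0 | -Lambda)."""
    m = model.m
    dil = RationalMatrix.zeros(m, m)
    for i, lam in enumerate(model.dilution_rates):
        dil[i, i] = -lam
    S = model.S0.hstack(dil)
    roles = tuple(model.reaction_ids) + tuple(
        f"dilution:{met}" for met in model.metabolite_ids
    )
    return AugmentedStoichiometry(S=S, column_roles=roles, provenance=model)


def reverse_reactions(
    model: StoichiometricModel, reaction_ids: Sequence[str]
) -> StoichiometricModel:
    """Negate the named S0 columns (choose the opposite direction as positive).

    Applying the same set twice returns the original model.
    """
    idx = {model.reaction_index(rid) for rid in reaction_ids}
    S0 = model.S0.copy()
    for j in idx:
        for i in range(model.m):
            S0[i, j] = -S0[i, j]
    marker = "reversed:" + ",".join(sorted(set(reaction_ids)))
    prov = list(model.provenance)
    if prov and prov[-1] == marker:
        prov.pop()  # double reversal restores the original orientation
    else:
        prov.append(marker)
    return StoichiometricModel(
        metabolite_ids=model.metabolite_ids,
        reaction_ids=model.reaction_ids,
        S0=S0,
        reversible=model.reversible,
        dilution_rates=model.dilution_rates,
        provenance=tuple(prov),
    )


def split_reversible(
    model: StoichiometricModel, reaction_ids: Sequence[str]
) -> StoichiometricModel:
    """Insert, after each named reaction, a new column equal to its negation.

    This is the "two columns per reversible reaction" treatment: both
    directions become irreversible columns, and the flux cone stays pointed.
    New ids carry a ``_rev`` suffix.
    """
    split_at = {model.reaction_index(rid) for rid in reaction_ids}
    new_cols: list[list[Fraction]] = []
    new_ids: list[str] = []
    new_rev: list[bool] = []
    for j, rid in enumerate(model.reaction_ids):
        col = model.S0.column(j)
        new_cols.append(col)
        new_ids.append(rid)
        new_rev.append(model.reversible[j])
        if j in split_at:
            new_cols.append([-x for x in col])
            new_ids.append(f"{rid}_rev")
            new_rev.append(False)
    if not reaction_ids:
        return model
    return StoichiometricModel(
        metabolite_ids=model.metabolite_ids,
        reaction_ids=tuple(new_ids),
        S0=RationalMatrix.from_columns(new_cols),
        reversible=tuple(new_rev),
        dilution_rates=model.dilution_rates,
        provenance=model.provenance + ("split:" + ",".join(sorted(set(reaction_ids))),),
    )


# -- JSON model I/O ----------------------------------------------------------
#
# Schema:
# {
#   "metabolites": [{"id": "A", "dilution_rate": "1"}, ...],
#   "reactions": [{"id": "v1", "reversible": false,
#                  "stoichiometry": {"A": "1"}}, ...]
# }
# Coefficients may be integers, "p/q" strings, or decimal strings; all are
# parsed exactly.


def model_to_dict(model: StoichiometricModel) -> dict:
    mets = []
    for i, met in enumerate(model.metabolite_ids):
        entry: dict = {"id": met}
        if model.dilution_rates[i] != 1:
            entry["dilution_rate"] = format_fraction(model.dilution_rates[i])
        mets.append(entry)
    rxns = []
    for j, rid in enumerate(model.reaction_ids):
        stoich = {
            met: format_fraction(model.S0[i, j])
            for i, met in enumerate(model.metabolite_ids)
            if model.S0[i, j] != 0
        }
        rxns.append(
            {"id": rid, "reversible": model.reversible[j], "stoichiometry": stoich}
        )
    return {"metabolites": mets, "reactions": rxns}


def model_from_dict(doc: Mapping) -> StoichiometricModel:
    if not isinstance(doc, Mapping):
        raise ModelValidationError("model document must be a JSON object")
    for key in ("metabolites", "reactions"):
        if key not in doc or not isinstance(doc[key], list):
            raise ModelValidationError(f"missing or non-list field {key!r}")
    met_ids: list[str] = []
    rates: list[Fraction] = []
    for entry in doc["metabolites"]:
        if not isinstance(entry, Mapping) or "id" not in entry:
            raise ModelValidationError("each metabolite needs an 'id' field")
        met_ids.append(str(entry["id"]))
        raw = entry.get("dilution_rate", 1)
        try:
            rates.append(as_fraction(raw))
        except (TypeError, ValueError) as exc:
            raise ModelValidationError(
                f"bad dilution_rate for metabolite {entry['id']!r}: {exc}"
            ) from exc
    rxn_ids: list[str] = []
    reversible: list[bool] = []
    cols: list[list[Fraction]] = []
    met_pos = {met: i for i, met in enumerate(met_ids)}
    for entry in doc["reactions"]:
        if not isinstance(entry, Mapping) or "id" not in entry:
            raise ModelValidationError("each reaction needs an 'id' field")
        rid = str(entry["id"])
        rxn_ids.append(rid)
        reversible.append(bool(entry.get("reversible", False)))
        stoich = entry.get("stoichiometry")
        if not isinstance(stoich, Mapping):
            raise ModelValidationError(
                f"reaction {rid!r}: 'stoichiometry' must be an object"
            )
        col = [Fraction(0)] * len(met_ids)
        for met, coeff in stoich.items():
            if met not in met_pos:
                raise ModelValidationError(
                    f"reaction {rid!r} references unknown metabolite {met!r}"
                )
            try:
                col[met_pos[met]] = as_fraction(coeff)
            except (TypeError, ValueError) as exc:
                raise ModelValidationError(
                    f"reaction {rid!r}: bad coefficient for {met!r}: {exc}"
                ) from exc
        cols.append(col)
    if not met_ids or not rxn_ids:
        raise ModelValidationError("model must have at least one metabolite and one reaction")
    return StoichiometricModel(
        metabolite_ids=tuple(met_ids),
        reaction_ids=tuple(rxn_ids),
        S0=RationalMatrix.from_columns(cols),
        reversible=tuple(reversible),
        dilution_rates=tuple(rates),
    )


def load_model(path: PathLike) -> StoichiometricModel:
    """Load and validate a model from its JSON file."""
    text = Path(path).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelValidationError(f"not valid JSON: {exc}") from exc
    return model_from_dict(doc)


def save_model(model: StoichiometricModel, path: PathLike) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1) + "\n")
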