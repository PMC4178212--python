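"""Metabolic network data model.

A :class:`MetabolicModel` is the usual constraint-based-modeling container:
an ordered set of metabolites, an ordered set of reactions with signed
stoichiometries and flux bounds, gene–protein–reaction rules, and a pathway
(subsystem) label per reaction.  The stoichiometric matrix ``S``
(metabolites x reactions) is derived from the reaction stoichiometries;
steady state means ``S @ v = 0`` for the flux vector ``v``.

Boundary (exchange) reactions are one-sided stoichiometries crossing the
system boundary (``-> M`` or ``M ->``) and are flagged explicitly rather
than detected heuristically.  Compartments are plain string tags; a
metabolite shuttled between compartments (e.g. the cytosol -> endoplasmic
reticulum glucose-6-phosphate transport of hepatic gluconeogenesis) is two
metabolite entries linked by an ordinary transport reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gpr import Gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ValidationReport",
    "ModelValidationError",
    "validate_model",
    "DEFAULT_BOUND",
]

#: Magnitude of the default flux bound applied when a file omits bounds:
#: [-DEFAULT_BOUND, DEFAULT_BOUND] for reversible reactions,
#: [0, DEFAULT_BOUND] for irreversible ones.
DEFAULT_BOUND = 1000.0


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: Gpr | None = None
    pathway: str = ""
    is_exchange: bool = False

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites x reactions); column j is reaction j's stoichiometry."""
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                S[met_index[met], j] = coef
        return S

    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            if r.gpr is not None:
                out |= r.gpr.genes()
        return out


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations


def validate_model(model: MetabolicModel) -> ValidationReport:
    """Check structural invariants; report violations and dead-end warnings.

    Violations: empty/duplicate identifiers, reactions referencing unknown
    metabolites, empty stoichiometries, crossed bounds.  Warnings flag
    dead-end metabolites — produced but never consumed, or vice versa,
    taking reaction reversibility into account — which force zero flux
    through every reaction touching them at steady state.
    """
    report = ValidationReport()
    met_ids = set()
    for m in model.metabolites:
        if not m.id:
            report.violations.append("metabolite with empty id")
        elif m.id in met_ids:
            report.violations.append(f"duplicate metabolite id {m.id!r}")
        met_ids.add(m.id)
        if not m.compartment:
            report.violations.append(f"metabolite {m.id!r} has empty compartment")

    rxn_ids = set()
    producible: dict[str, bool] = {m: False for m in met_ids}
    consumable: dict[str, bool] = {m: False for m in met_ids}
    for r in model.reactions:
        if not r.id:
            report.violations.append("reaction with empty id")
        elif r.id in rxn_ids:
            report.violations.append(f"duplicate reaction id {r.id!r}")
        rxn_ids.add(r.id)
        if not r.stoichiometry:
            report.violations.append(f"reaction {r.id!r} has empty stoichiometry")
        if r.lower_bound > r.upper_bound:
            report.violations.append(
                f"reaction {r.id!r} has lower bound {r.lower_bound} > upper bound {r.upper_bound}"
            )
        for met, coef in r.stoichiometry.items():
            if met not in met_ids:
                report.violations.append(
                    f"reaction {r.id!r} references unknown metabolite {met!r}"
                )
                continue
            forward = r.upper_bound > 0
            backward = r.lower_bound < 0
            if coef > 0:
                producible[met] = producible[met] or forward
                consumable[met] = consumable[met] or backward
            elif coef < 0:
                consumable[met] = consumable[met] or forward
                producible[met] = producible[met] or backward

    for m in model.metabolites:
        prod, cons = producible.get(m.id, False), consumable.get(m.id, False)
        if prod != cons:
            side = "produced but never consumed" if prod else "consumed but never produced"
            report.warnings.append(f"dead-end metabolite {m.id!r}: {side}")
    return report


def assert_valid(model: MetabolicModel) -> None:
    report = validate_model(model)
    if not report.valid:
        raise ModelValidationError("; ".join(report.violations))
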