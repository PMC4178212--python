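"""Model readers and writer.

Two on-disk encodings are supported:

* a compact JSON dialect (documented by ``schema/model_schema.json``
  shipped with the package) with top-level ``metabolites`` and
  ``reactions`` arrays; reaction entries carry
  ``id, stoich, lb, ub, gpr, pathway, exchange``;
* a read-only subset of SBML Level 3 with FBC-style flux bounds and
  gene-product associations, the format genome-scale human
  reconstructions are distributed in.

The JSON round trip (write -> read) is the identity on valid models.
Unsupported SBML constructs are skipped with a logged warning, never
silently.  Reactions without explicit bounds receive the conventional
defaults [-1000, 1000] (reversible) or [0, 1000] (irreversible).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .gpr import GprParseError, gpr_to_string, parse_gpr
from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    validate_model,
)

__all__ = ["read_model_json", "write_model", "read_model_sbml", "ModelParseError"]

log = logging.getLogger(__name__)


class ModelParseError(ValueError):
    """Raised when a model file cannot be parsed into a valid model."""


def _check(model: MetabolicModel, source: str) -> MetabolicModel:
    report = validate_model(model)
    if not report.valid:
        raise ModelValidationError(f"{source}: " + "; ".join(report.violations))
    for w in report.warnings:
        log.warning("%s: %s", source, w)
    return model


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def read_model_json(path: str | Path) -> MetabolicModel:
    """Read a model from the JSON dialect, preserving file order."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "metabolites" not in doc or "reactions" not in doc:
        raise ModelParseError(f"{path}: expected top-level 'metabolites' and 'reactions'")

    metabolites = []
    for entry in doc["metabolites"]:
        try:
            metabolites.append(
                Metabolite(
                    id=str(entry["id"]),
                    name=str(entry.get("name", "")),
                    compartment=str(entry.get("compartment", "c")),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ModelParseError(f"{path}: malformed metabolite record {entry!r}") from exc

    reactions = []
    for entry in doc["reactions"]:
        try:
            gpr = parse_gpr(entry.get("gpr", ""))
        except GprParseError as exc:
            raise ModelParseError(
                f"{path}: reaction {entry.get('id')!r} has unparseable GPR ({exc})"
            ) from exc
        try:
            reactions.append(
                Reaction(
                    id=str(entry["id"]),
                    stoichiometry={str(k): float(v) for k, v in entry["stoich"].items()},
                    lower_bound=float(entry.get("lb", 0.0)),
                    upper_bound=float(entry.get("ub", DEFAULT_BOUND)),
                    gpr=gpr,
                    pathway=str(entry.get("pathway", "")),
                    is_exchange=bool(entry.get("exchange", False)),
                )
            )
        except (KeyError, TypeError, ValueError, AttributeError) as exc:
            raise ModelParseError(f"{path}: malformed reaction record {entry!r}") from exc

    return _check(MetabolicModel(metabolites, reactions), str(path))


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write a model to the JSON dialect; re-reading yields an equal model."""
    report = validate_model(model)
    if not report.valid:
        raise ModelValidationError("; ".join(report.violations))
    doc = {
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoich": r.stoichiometry,
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "gpr": gpr_to_string(r.gpr),
                "pathway": r.pathway,
                "exchange": r.is_exchange,
            }
            for r in model.reactions
        ],
    }
    Path(path).write_text(
        json.dumps(doc, indent=1, ensure_ascii=False) + "\n", encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# SBML (read-only subset)
# ---------------------------------------------------------------------------

def read_model_sbml(path: str | Path) -> MetabolicModel:
    """Read an SBML Level 3 document with FBC bounds and GPR associations."""
    import libsbml

    path = Path(path)
    doc = libsbml.readSBMLFromString(path.read_text(encoding="utf-8"))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        first = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(f"{path}: SBML parse error: {first.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"{path}: document contains no model")

    metabolites = []
    for sp in sbml_model.getListOfSpecies():
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "c",
            )
        )

    parameters = {
        p.getId(): p.getValue() for p in sbml_model.getListOfParameters()
    }

    reactions = []
    for rx in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for sr in rx.getListOfReactants():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for sr in rx.getListOfProducts():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        if rx.getNumModifiers() > 0:
            log.warning("%s: reaction %s: modifier species skipped", path, rx.getId())
        if rx.isSetKineticLaw():
            log.warning("%s: reaction %s: kinetic law skipped", path, rx.getId())

        reversible = rx.getReversible()
        lb = -DEFAULT_BOUND if reversible else 0.0
        ub = DEFAULT_BOUND
        gpr = None
        fbc = rx.getPlugin("fbc")
        if fbc is not None:
            if fbc.isSetLowerFluxBound():
                lb = parameters.get(fbc.getLowerFluxBound(), lb)
            else:
                log.warning(
                    "%s: reaction %s: no lower flux bound, default %s applied",
                    path, rx.getId(), lb,
                )
            if fbc.isSetUpperFluxBound():
                ub = parameters.get(fbc.getUpperFluxBound(), ub)
            else:
                log.warning(
                    "%s: reaction %s: no upper flux bound, default %s applied",
                    path, rx.getId(), ub,
                )
            if fbc.isSetGeneProductAssociation():
                gpr = _convert_association(
                    fbc.getGeneProductAssociation().getAssociation(), sbml_model
                )
        else:
            log.warning(
                "%s: reaction %s: no fbc data, default bounds applied", path, rx.getId()
            )

        pathway = ""
        notes = rx.getNotesString() if rx.isSetNotes() else ""
        if "SUBSYSTEM:" in notes:
            pathway = notes.split("SUBSYSTEM:", 1)[1].split("<", 1)[0].strip()

        only_reactants = all(v <= 0 for v in stoich.values())
        only_products = all(v >= 0 for v in stoich.values())
        reactions.append(
            Reaction(
                id=rx.getId(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                pathway=pathway,
                is_exchange=only_reactants or only_products,
            )
        )

    return _check(MetabolicModel(metabolites, reactions), str(path))


def _convert_association(assoc, sbml_model):
    """Convert an FBC gene-product association tree to a GPR tree."""
    import libsbml

    from .gpr import Gpr

    if assoc is None:
        return None
    if assoc.isGeneProductRef():
        gp = sbml_model.getPlugin("fbc").getGeneProduct(assoc.getGeneProduct())
        label = gp.getLabel() if gp is not None and gp.isSetLabel() else assoc.getGeneProduct()
        return Gpr("gene", gene=label)
    op = "and" if assoc.isFbcAnd() else "or"
    children = tuple(
        _convert_association(assoc.getAssociation(i), sbml_model)
        for i in range(assoc.getNumAssociations())
    )
    return Gpr(op, children=children)
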