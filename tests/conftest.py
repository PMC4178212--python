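"""Shared fixtures: small hand-built networks and file fixtures.

The canonical toy is a four-reaction linear chain
``-> A -> B -> C ->`` with bounds [0, 10] everywhere and single-gene
GPRs on the two internal conversions; its optimal cue-agreement
solutions can be enumerated by hand.
"""

from __future__ import annotations

import numpy as np
import pytest

from fluxcue.expression import ReactionStateAssignment
from fluxcue.gpr import parse_gpr
from fluxcue.model import MetabolicModel, Metabolite, Reaction


def make_chain(ub: float = 10.0) -> MetabolicModel:
    mets = [
        Metabolite("A", name="metabolite A", compartment="c"),
        Metabolite("B", name="metabolite B", compartment="c"),
        Metabolite("C", name="metabolite C", compartment="c"),
    ]
    rxns = [
        Reaction("R1", {"A": 1.0}, 0.0, ub, is_exchange=True),
        Reaction("R2", {"A": -1.0, "B": 1.0}, 0.0, ub, gpr=parse_gpr("g2")),
        Reaction("R3", {"B": -1.0, "C": 1.0}, 0.0, ub, gpr=parse_gpr("g3")),
        Reaction("R4", {"C": -1.0}, 0.0, ub, is_exchange=True),
    ]
    return MetabolicModel(mets, rxns)


def make_diamond(ub: float = 10.0) -> MetabolicModel:
    """-> A, then A->B->D and A->C->D in parallel, then D ->."""
    mets = [Metabolite(m) for m in "ABCD"]
    rxns = [
        Reaction("SRC", {"A": 1.0}, 0.0, ub, gpr=parse_gpr("g_src"), is_exchange=True),
        Reaction("AB", {"A": -1.0, "B": 1.0}, 0.0, ub, gpr=parse_gpr("g_ab")),
        Reaction("BD", {"B": -1.0, "D": 1.0}, 0.0, ub, gpr=parse_gpr("g_bd")),
        Reaction("AC", {"A": -1.0, "C": 1.0}, 0.0, ub, gpr=parse_gpr("g_ac")),
        Reaction("CD", {"C": -1.0, "D": 1.0}, 0.0, ub, gpr=parse_gpr("g_cd")),
        Reaction("SNK", {"D": -1.0}, 0.0, ub, gpr=parse_gpr("g_snk"), is_exchange=True),
    ]
    return MetabolicModel(mets, rxns)


def states_for(model: MetabolicModel, condition: str = "test", **overrides: int):
    states = {r.id: 0 for r in model.reactions}
    states.update(overrides)
    return ReactionStateAssignment(condition, states)


def random_cued_network(rng: np.random.Generator, max_cues: int = 8):
    """A random small network with random cues for oracle cross-checks.

    Parallel linear chains of random length, a random subset of internal
    reactions made reversible, and at most ``max_cues`` random +1/-1 cues.
    """
    n_chains = int(rng.integers(2, 4))
    length = int(rng.integers(3, 5))
    mets, rxns = [], []
    for p in range(n_chains):
        chain_mets = [Metabolite(f"m{p}_{i}") for i in range(length + 1)]
        mets.extend(chain_mets)
        rxns.append(
            Reaction(f"up{p}", {chain_mets[0].id: 1.0}, 0.0, 10.0, is_exchange=True)
        )
        for i in range(length):
            reversible = bool(rng.random() < 0.3)
            rxns.append(
                Reaction(
                    f"r{p}_{i}",
                    {chain_mets[i].id: -1.0, chain_mets[i + 1].id: 1.0},
                    -10.0 if reversible else 0.0,
                    10.0,
                )
            )
        rxns.append(
            Reaction(f"ex{p}", {chain_mets[-1].id: -1.0}, 0.0, 10.0, is_exchange=True)
        )
    model = MetabolicModel(mets, rxns)
    n_cues = int(rng.integers(1, max_cues + 1))
    cued = rng.choice(len(rxns), size=min(n_cues, len(rxns)), replace=False)
    states = {r.id: 0 for r in rxns}
    for j in cued:
        states[rxns[j].id] = int(rng.choice([-1, 1]))
    return model, ReactionStateAssignment("random", states)


@pytest.fixture
def chain() -> MetabolicModel:
    return make_chain()


@pytest.fixture
def diamond() -> MetabolicModel:
    return make_diamond()


SBML_CHAIN = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
      xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2"
      level="3" version="1" fbc:required="false">
  <model id="toy_chain" fbc:strict="false">
    <listOfCompartments>
      <compartment id="c" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="A" name="metabolite A" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="B" name="metabolite B" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="C" name="metabolite C" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="lb_zero" value="0" constant="true"/>
      <parameter id="ub_ten" value="10" constant="true"/>
    </listOfParameters>
    <fbc:listOfGeneProducts>
      <fbc:geneProduct fbc:id="G_g2" fbc:label="g2"/>
      <fbc:geneProduct fbc:id="G_g3" fbc:label="g3"/>
    </fbc:listOfGeneProducts>
    <listOfReactions>
      <reaction id="R1" reversible="false" fast="false" fbc:lowerFluxBound="lb_zero" fbc:upperFluxBound="ub_ten">
        <listOfProducts>
          <speciesReference species="A" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="R2" reversible="false" fast="false" fbc:lowerFluxBound="lb_zero" fbc:upperFluxBound="ub_ten">
        <listOfReactants>
          <speciesReference species="A" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="B" stoichiometry="1" constant="true"/>
        </listOfProducts>
        <fbc:geneProductAssociation>
          <fbc:geneProductRef fbc:geneProduct="G_g2"/>
        </fbc:geneProductAssociation>
      </reaction>
      <reaction id="R3" reversible="false" fast="false" fbc:lowerFluxBound="lb_zero" fbc:upperFluxBound="ub_ten">
        <listOfReactants>
          <speciesReference species="B" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="C" stoichiometry="1" constant="true"/>
        </listOfProducts>
        <fbc:geneProductAssociation>
          <fbc:geneProductRef fbc:geneProduct="G_g3"/>
        </fbc:geneProductAssociation>
      </reaction>
      <reaction id="R4" reversible="false" fast="false" fbc:lowerFluxBound="lb_zero" fbc:upperFluxBound="ub_ten">
        <listOfReactants>
          <speciesReference species="C" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""


@pytest.fixture
def sbml_chain_path(tmp_path):
    path = tmp_path / "chain.xml"
    path.write_text(SBML_CHAIN)
    return path
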