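"""Model containers, SBML/JSON round trips, and the Petri-net projection."""

import numpy as np
import pytest

from fluxbridge import (
    ConstraintModel,
    KineticModel,
    KineticReaction,
    ModelInvariantError,
    SBMLParseError,
    Species,
    export_petri_net,
    read_constraint_sbml,
    read_kinetic_sbml,
    simulate_to_steady_state,
    write_constraint_json,
    write_constraint_sbml,
    write_kinetic_sbml,
)
from fluxbridge.model_io import Compartment
from fluxbridge import synthetic_fixtures as sf

NO_RATE_LAW_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version2/core" level="3" version="2">
  <model id="m">
    <listOfCompartments>
      <compartment id="c" constant="true" size="1"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="c" initialConcentration="1"
               hasOnlySubstanceUnits="false" boundaryCondition="false"
               constant="false"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="RX" reversible="false">
        <listOfReactants>
          <speciesReference species="A" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""


@pytest.mark.parametrize("motif", ["chain", "branch", "zoo"])
def test_kinetic_sbml_round_trip(motif, chain, branch, zoo, tmp_path):
    """Writing then reading a kinetic model preserves its structure and rates."""
    kinetic = {"chain": chain, "branch": branch, "zoo": zoo}[motif][0]
    path = tmp_path / "kinetic.xml"
    write_kinetic_sbml(kinetic, path)
    back = read_kinetic_sbml(path)
    assert back.reaction_ids == kinetic.reaction_ids
    assert back.species_ids == kinetic.species_ids
    for orig, rt in zip(kinetic.reactions, back.reactions):
        assert rt.stoichiometry == orig.stoichiometry
        assert rt.reversible == orig.reversible
    for orig, rt in zip(kinetic.species, back.species):
        assert rt.boundary == orig.boundary
        assert rt.initial_concentration == pytest.approx(
            orig.initial_concentration
        )


def test_round_tripped_rate_laws_give_same_steady_state(chain, tmp_path):
    kinetic, _, _ = chain
    path = tmp_path / "kinetic.xml"
    write_kinetic_sbml(kinetic, path)
    back = read_kinetic_sbml(path)
    ss_a = simulate_to_steady_state(kinetic)
    ss_b = simulate_to_steady_state(back)
    for rid in kinetic.reaction_ids:
        assert ss_b.fluxes[rid] == pytest.approx(ss_a.fluxes[rid], rel=1e-8)


@pytest.mark.parametrize("fmt", ["json", "sbml"])
def test_constraint_model_round_trip_exact(branch, tmp_path, fmt):
    """R, M, S, L, U and the objective survive write/read exactly."""
    _, model, _ = branch
    path = tmp_path / ("gem.json" if fmt == "json" else "gem.xml")
    (write_constraint_json if fmt == "json" else write_constraint_sbml)(
        model, str(path)
    )
    back = read_constraint_sbml(str(path))
    assert back.reaction_ids == model.reaction_ids
    assert back.metabolite_ids == model.metabolite_ids
    np.testing.assert_array_equal(back.S, model.S)
    np.testing.assert_array_equal(back.lower, model.lower)
    np.testing.assert_array_equal(back.upper, model.upper)
    np.testing.assert_array_equal(back.objective, model.objective)


def test_kinetic_reader_rejects_undeclared_species(tmp_path):
    model = KineticModel(
        species=[Species("A", "c", 1.0)],
        reactions=[
            KineticReaction("R1", {"A": -1.0, "GHOST": 1.0}, "k * A", {"k": 1.0})
        ],
        compartments=[Compartment("c")],
    )
    path = tmp_path / "bad.xml"
    write_kinetic_sbml(model, path)  # writer does not validate references
    with pytest.raises(SBMLParseError, match="GHOST"):
        read_kinetic_sbml(path)


def test_kinetic_reader_requires_rate_laws(tmp_path):
    path = tmp_path / "norate.xml"
    path.write_text(NO_RATE_LAW_SBML)
    with pytest.raises(SBMLParseError, match="no rate law.*RX"):
        read_kinetic_sbml(path)


def test_malformed_sbml_is_a_parse_error(tmp_path):
    path = tmp_path / "broken.xml"
    path.write_text("<sbml><model></sbml>")
    with pytest.raises(SBMLParseError):
        read_kinetic_sbml(path)


def test_constraint_reader_rejects_inverted_bounds(branch, tmp_path):
    import json

    _, model, _ = branch
    path = tmp_path / "gem.json"
    write_constraint_json(model, str(path))
    raw = json.loads(path.read_text())
    raw["reactions"][0]["lower_bound"] = 5.0
    raw["reactions"][0]["upper_bound"] = -5.0
    path.write_text(json.dumps(raw))
    with pytest.raises((ModelInvariantError, ValueError)):
        read_constraint_sbml(str(path))


def test_constraint_reader_rejects_missing_bounds(branch, tmp_path):
    import json

    _, model, _ = branch
    path = tmp_path / "gem.json"
    write_constraint_json(model, str(path))
    raw = json.loads(path.read_text())
    del raw["reactions"][0]["lower_bound"]
    path.write_text(json.dumps(raw))
    with pytest.raises(SBMLParseError, match="missing flux bounds"):
        read_constraint_sbml(str(path))


def test_petri_net_of_citramalate_synthesis_reaction():
    """One 3-substrate/3-product reaction: 6 places, 1 transition, 3+3 arcs."""
    mets = ["accoa_c", "pyr_c", "h2o_c", "coa_c", "h_c", "citramalate_c"]
    S = np.array([[-1.0], [-1.0], [-1.0], [1.0], [1.0], [1.0]])
    model = ConstraintModel(
        reaction_ids=["CIMA"],
        metabolite_ids=mets,
        S=S,
        lower=np.zeros(1),
        upper=np.array([1000.0]),
        objective=np.zeros(1),
    )
    view = export_petri_net(model)
    assert len(view.places) == 6
    assert len(view.transitions) == 1
    incoming = [a for a in view.arcs if a[1] == "CIMA"]
    outgoing = [a for a in view.arcs if a[0] == "CIMA"]
    assert len(incoming) == 3 and len(outgoing) == 3
    dot = view.to_dot()
    assert "shape=circle" in dot and "shape=box" in dot


def test_petri_net_arcs_match_stoichiometry_nonzeros(chain, branch):
    """Arc count equals nnz(S); the graph is strictly bipartite."""
    for _, model, _ in (chain, branch):
        view = export_petri_net(model)
        assert len(view.arcs) == int(np.count_nonzero(model.S))
        places = set(view.places)
        transitions = set(view.transitions)
        for src, dst, weight in view.arcs:
            assert (src in places) != (src in transitions)
            assert {src, dst} & places and {src, dst} & transitions
            assert weight > 0


def test_petri_net_of_empty_model_is_empty():
    model = ConstraintModel(
        reaction_ids=[], metabolite_ids=[],
        S=np.zeros((0, 0)), lower=np.zeros(0), upper=np.zeros(0),
        objective=np.zeros(0),
    )
    view = export_petri_net(model)
    assert view.places == [] and view.transitions == [] and view.arcs == []


def test_kinetic_petri_net_uses_reaction_stoichiometry(branch):
    kinetic, _, _ = branch
    view = export_petri_net(kinetic)
    expected = sum(
        sum(1 for c in r.stoichiometry.values() if c != 0)
        for r in kinetic.reactions
    )
    assert len(view.arcs) == expected
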