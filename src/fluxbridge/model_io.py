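"""Model containers and file input/output.

Two model formalisms are handled:

* :class:`KineticModel` — an ODE model with explicit rate laws, read from and
  written to SBML (Level 2 or Level 3 kinetic-law encodings are tolerated).
* :class:`ConstraintModel` — the stoichiometric tuple {R, M, S, L, U} plus
  objective weights c, read from SBML-fbc or BiGG-style JSON via COBRApy and
  normalised into a plain array-based container.

Both can be projected onto a bipartite Petri-net view (metabolites as places,
reactions as transitions) and serialised to Graphviz DOT text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import cobra
import cobra.io
import libsbml
import numpy as np
import sympy as sp

__all__ = [
    "Species",
    "KineticReaction",
    "Compartment",
    "KineticModel",
    "ConstraintModel",
    "PetriNetView",
    "SBMLParseError",
    "ModelInvariantError",
    "read_kinetic_sbml",
    "write_kinetic_sbml",
    "read_constraint_sbml",
    "write_constraint_sbml",
    "write_constraint_json",
    "export_petri_net",
]


class SBMLParseError(ValueError):
    """Raised when an SBML/JSON model file cannot be parsed or validated."""


class ModelInvariantError(ValueError):
    """Raised when a model violates a structural invariant (e.g. L > U)."""


# --------------------------------------------------------------------------
# Kinetic model
# --------------------------------------------------------------------------

from sympy.parsing.sympy_parser import convert_xor, standard_transformations

#: ``^`` in SBML infix means power.
_RATE_LAW_TRANSFORMATIONS = standard_transformations + (convert_xor,)

#: sympy names made available inside rate-law expressions.
_RATE_LAW_FUNCTIONS = {
    "exp": sp.exp,
    "ln": sp.log,
    "log": sp.log,
    "log10": lambda x: sp.log(x, 10),
    "sqrt": sp.sqrt,
    "abs": sp.Abs,
    "pow": sp.Pow,
}


@dataclass(frozen=True)
class Species:
    """One chemical species of a kinetic model.

    ``initial_concentration`` is in mM.  ``boundary`` species are held at a
    fixed concentration during integration (sources/sinks).
    """

    id: str
    compartment: str
    initial_concentration: float
    boundary: bool = False


@dataclass(frozen=True)
class KineticReaction:
    """A reaction with signed stoichiometry and a rate-law expression.

    The rate law is an infix expression (SBML L3 syntax; ``^`` means power)
    over species ids, local parameters, model-wide parameters and compartment
    sizes.  Rates are interpreted in concentration units, mM s⁻¹.
    """

    id: str
    stoichiometry: dict[str, float]
    rate_law: str
    parameters: dict[str, float] = field(default_factory=dict)
    reversible: bool = False
    name: str = ""


@dataclass(frozen=True)
class Compartment:
    id: str
    name: str = ""
    size: float = 1.0


@dataclass
class KineticModel:
    """An ODE metabolic model: species, compartments and rate-law reactions."""

    species: list[Species]
    reactions: list[KineticReaction]
    compartments: list[Compartment]
    parameters: dict[str, float] = field(default_factory=dict)
    id: str = "kinetic_model"

    # -- lookups -----------------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_species(self, species_id: str) -> Species:
        for s in self.species:
            if s.id == species_id:
                return s
        raise KeyError(f"unknown species id {species_id!r}")

    def get_reaction(self, reaction_id: str) -> KineticReaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise KeyError(f"unknown reaction id {reaction_id!r}")

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants; raise :class:`ModelInvariantError`.

        Checks that stoichiometries reference declared species, that initial
        concentrations are nonnegative, and that every rate law parses and
        references only declared species/parameters/compartments.
        """
        declared = set(self.species_ids)
        if len(declared) != len(self.species):
            raise ModelInvariantError("duplicate species ids")
        for rxn in self.reactions:
            missing = set(rxn.stoichiometry) - declared
            if missing:
                raise ModelInvariantError(
                    f"reaction {rxn.id!r} references undeclared species {sorted(missing)}"
                )
        for s in self.species:
            if s.initial_concentration < 0:
                raise ModelInvariantError(
                    f"species {s.id!r} has negative initial concentration"
                )
        for rxn in self.reactions:
            expr = parse_rate_law(self, rxn)
            unknown = {
                str(sym) for sym in expr.free_symbols if str(sym) not in declared
            }
            if unknown:
                raise ModelInvariantError(
                    f"rate law of {rxn.id!r} references unknown symbols {sorted(unknown)}"
                )


def parse_rate_law(model: KineticModel, reaction: KineticReaction) -> sp.Expr:
    """Parse a reaction's rate law into a sympy expression.

    Numeric parameters (local, then global, then compartment sizes) are
    substituted immediately, so the only free symbols left are species ids.
    """
    local: dict[str, object] = dict(_RATE_LAW_FUNCTIONS)
    for comp in model.compartments:
        local[comp.id] = sp.Float(comp.size)
    for name, value in model.parameters.items():
        local[name] = sp.Float(value)
    for name, value in reaction.parameters.items():
        local[name] = sp.Float(value)
    for sid in model.species_ids:
        local[sid] = sp.Symbol(sid)
    try:
        expr = sp.parse_expr(
            reaction.rate_law,
            local_dict=local,
            transformations=_RATE_LAW_TRANSFORMATIONS,
        )
    except (SyntaxError, TypeError, sp.SympifyError) as exc:
        raise ModelInvariantError(
            f"rate law of {reaction.id!r} does not parse: {reaction.rate_law!r}"
        ) from exc
    bad_funcs = {
        f.func.__name__
        for f in expr.atoms(sp.Function)
        if isinstance(f.func, sp.core.function.UndefinedFunction)
    }
    if bad_funcs:
        raise ModelInvariantError(
            f"rate law of {reaction.id!r} calls unknown functions {sorted(bad_funcs)}"
        )
    return expr


def read_kinetic_sbml(path: str) -> KineticModel:
    """Read a kinetic SBML file (L2 or L3) into a :class:`KineticModel`.

    Every reaction must carry a kinetic law.  Parse errors and referential
    problems raise :class:`SBMLParseError` naming the offending element.
    """
    doc = libsbml.readSBML(str(path))
    _raise_sbml_errors(doc, path)
    doc.checkInternalConsistency()
    _raise_sbml_errors(doc, path)
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLParseError(f"{path}: file contains no SBML model")

    compartments = [
        Compartment(
            id=c.getId(),
            name=c.getName() or "",
            size=c.getSize() if c.isSetSize() and not math.isnan(c.getSize()) else 1.0,
        )
        for c in sbml_model.getListOfCompartments()
    ]
    comp_size = {c.id: c.size for c in compartments}

    species = []
    for s in sbml_model.getListOfSpecies():
        if s.isSetInitialConcentration():
            conc = s.getInitialConcentration()
        elif s.isSetInitialAmount():
            size = comp_size.get(s.getCompartment(), 1.0)
            conc = s.getInitialAmount() / size if size else s.getInitialAmount()
        else:
            conc = 0.0
        boundary = bool(s.getBoundaryCondition()) or bool(
            s.isSetConstant() and s.getConstant()
        )
        species.append(
            Species(
                id=s.getId(),
                compartment=s.getCompartment(),
                initial_concentration=float(conc),
                boundary=boundary,
            )
        )
    declared = {s.id for s in species}

    global_params = {
        p.getId(): p.getValue()
        for p in sbml_model.getListOfParameters()
        if p.isSetValue()
    }

    reactions = []
    for rxn in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in rxn.getListOfReactants():
            sid = ref.getSpecies()
            if sid not in declared:
                raise SBMLParseError(
                    f"{path}: reaction {rxn.getId()!r} references undeclared species {sid!r}"
                )
            stoich[sid] = stoich.get(sid, 0.0) - _stoich_value(ref)
        for ref in rxn.getListOfProducts():
            sid = ref.getSpecies()
            if sid not in declared:
                raise SBMLParseError(
                    f"{path}: reaction {rxn.getId()!r} references undeclared species {sid!r}"
                )
            stoich[sid] = stoich.get(sid, 0.0) + _stoich_value(ref)
        kl = rxn.getKineticLaw()
        if kl is None or kl.getMath() is None:
            raise SBMLParseError(
                f"{path}: no rate law for reaction {rxn.getId()!r}"
            )
        formula = libsbml.formulaToL3String(kl.getMath())
        local_params: dict[str, float] = {}
        # L3 local parameters
        for p in kl.getListOfLocalParameters():
            local_params[p.getId()] = p.getValue()
        # L2 parameters nested in the kinetic law
        for p in kl.getListOfParameters():
            local_params.setdefault(p.getId(), p.getValue())
        reactions.append(
            KineticReaction(
                id=rxn.getId(),
                stoichiometry=stoich,
                rate_law=formula,
                parameters=local_params,
                reversible=bool(rxn.getReversible()),
                name=rxn.getName() or "",
            )
        )

    model = KineticModel(
        species=species,
        reactions=reactions,
        compartments=compartments,
        parameters=global_params,
        id=sbml_model.getId() or "kinetic_model",
    )
    model.validate()
    return model


def write_kinetic_sbml(model: KineticModel, path: str) -> None:
    """Write a :class:`KineticModel` as SBML Level 3 Version 2."""
    doc = libsbml.SBMLDocument(3, 2)
    m = doc.createModel()
    m.setId(model.id)
    for comp in model.compartments:
        c = m.createCompartment()
        c.setId(comp.id)
        if comp.name:
            c.setName(comp.name)
        c.setSize(comp.size)
        c.setConstant(True)
    for s in model.species:
        sb = m.createSpecies()
        sb.setId(s.id)
        sb.setCompartment(s.compartment)
        sb.setInitialConcentration(s.initial_concentration)
        sb.setBoundaryCondition(s.boundary)
        sb.setConstant(False)
        sb.setHasOnlySubstanceUnits(False)
    for name, value in model.parameters.items():
        p = m.createParameter()
        p.setId(name)
        p.setValue(value)
        p.setConstant(True)
    for rxn in model.reactions:
        rb = m.createReaction()
        rb.setId(rxn.id)
        if rxn.name:
            rb.setName(rxn.name)
        rb.setReversible(rxn.reversible)
        for sid, coeff in sorted(rxn.stoichiometry.items()):
            if coeff < 0:
                ref = rb.createReactant()
                ref.setStoichiometry(-coeff)
            else:
                ref = rb.createProduct()
                ref.setStoichiometry(coeff)
            ref.setSpecies(sid)
            ref.setConstant(True)
        kl = rb.createKineticLaw()
        math_ast = libsbml.parseL3Formula(rxn.rate_law)
        if math_ast is None:
            raise ModelInvariantError(
                f"rate law of {rxn.id!r} is not valid L3 infix: {rxn.rate_law!r}"
            )
        kl.setMath(math_ast)
        for pname, pvalue in sorted(rxn.parameters.items()):
            lp = kl.createLocalParameter()
            lp.setId(pname)
            lp.setValue(pvalue)
    libsbml.writeSBMLToFile(doc, str(path))


def _stoich_value(ref: libsbml.SpeciesReference) -> float:
    v = ref.getStoichiometry()
    if math.isnan(v):
        return 1.0
    return float(v)


def _raise_sbml_errors(doc: libsbml.SBMLDocument, path: str) -> None:
    messages = []
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            messages.append(f"line {err.getLine()}: {err.getMessage().strip()}")
    if messages:
        raise SBMLParseError(f"{path}: " + "; ".join(messages))


# --------------------------------------------------------------------------
# Constraint-based model
# --------------------------------------------------------------------------


@dataclass
class ConstraintModel:
    """A constraint-based model: the tuple {R, M, S, L, U} plus objective c.

    ``S`` has one row per metabolite and one column per reaction; fluxes and
    bounds are in mmol gDW⁻¹ h⁻¹ (the biomass flux is read as h⁻¹).
    """

    reaction_ids: list[str]
    metabolite_ids: list[str]
    S: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    objective: np.ndarray
    reaction_names: list[str] = field(default_factory=list)
    metabolite_compartments: list[str] = field(default_factory=list)
    id: str = "constraint_model"

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.objective = np.asarray(self.objective, dtype=float)
        if not self.reaction_names:
            self.reaction_names = list(self.reaction_ids)
        if not self.metabolite_compartments:
            self.metabolite_compartments = [
                m.rsplit("_", 1)[-1] if "_" in m else "c" for m in self.metabolite_ids
            ]
        self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}
        self._met_index = {m: i for i, m in enumerate(self.metabolite_ids)}

    # -- basic queries -----------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self._rxn_index[reaction_id]
        except KeyError:
            raise KeyError(f"unknown reaction id {reaction_id!r}") from None

    def metabolite_index(self, metabolite_id: str) -> int:
        try:
            return self._met_index[metabolite_id]
        except KeyError:
            raise KeyError(f"unknown metabolite id {metabolite_id!r}") from None

    def stoichiometry_of(self, reaction_id: str) -> dict[str, float]:
        """Signed stoichiometry map of one reaction."""
        j = self.reaction_index(reaction_id)
        col = self.S[:, j]
        return {
            self.metabolite_ids[i]: float(col[i]) for i in np.nonzero(col)[0]
        }

    def is_reversible(self, reaction_id: str) -> bool:
        return bool(self.lower[self.reaction_index(reaction_id)] < 0)

    def copy(self) -> "ConstraintModel":
        return ConstraintModel(
            reaction_ids=list(self.reaction_ids),
            metabolite_ids=list(self.metabolite_ids),
            S=self.S.copy(),
            lower=self.lower.copy(),
            upper=self.upper.copy(),
            objective=self.objective.copy(),
            reaction_names=list(self.reaction_names),
            metabolite_compartments=list(self.metabolite_compartments),
            id=self.id,
        )

    def validate(self) -> None:
        m, n = self.S.shape
        if n != self.n_reactions or m != self.n_metabolites:
            raise ModelInvariantError(
                f"S is {m}x{n} but model has {self.n_metabolites} metabolites "
                f"and {self.n_reactions} reactions"
            )
        bad = np.nonzero(self.lower > self.upper)[0]
        if bad.size:
            names = [self.reaction_ids[i] for i in bad[:5]]
            raise ModelInvariantError(
                f"lower bound exceeds upper bound for reactions {names}"
            )

    # -- conversion to/from COBRApy ---------------------------------------
    def to_cobra(self) -> cobra.Model:
        model = cobra.Model(self.id)
        mets = []
        for mid, comp in zip(self.metabolite_ids, self.metabolite_compartments):
            met = cobra.Metabolite(mid, compartment=comp)
            mets.append(met)
        rxns = []
        for j, rid in enumerate(self.reaction_ids):
            rxn = cobra.Reaction(rid, name=self.reaction_names[j])
            rxn.lower_bound = float(self.lower[j])
            rxn.upper_bound = float(self.upper[j])
            rxns.append(rxn)
        model.add_metabolites(mets)
        model.add_reactions(rxns)
        for j, rxn in enumerate(rxns):
            col = self.S[:, j]
            rxn.add_metabolites(
                {mets[i]: float(col[i]) for i in np.nonzero(col)[0]}
            )
        obj = {
            rxns[j]: float(self.objective[j])
            for j in np.nonzero(self.objective)[0]
        }
        if obj:
            model.objective = model.problem.Objective(
                sum(coef * rxn.flux_expression for rxn, coef in obj.items()),
                direction="max",
            )
        return model

    @classmethod
    def from_cobra(cls, model: cobra.Model) -> "ConstraintModel":
        met_ids = [m.id for m in model.metabolites]
        met_index = {m: i for i, m in enumerate(met_ids)}
        n = len(model.reactions)
        S = np.zeros((len(met_ids), n))
        lower = np.zeros(n)
        upper = np.zeros(n)
        for j, rxn in enumerate(model.reactions):
            lower[j] = rxn.lower_bound
            upper[j] = rxn.upper_bound
            for met, coeff in rxn.metabolites.items():
                S[met_index[met.id], j] = coeff
        objective = np.zeros(n)
        coeffs = cobra.util.solver.linear_reaction_coefficients(model)
        for rxn, coef in coeffs.items():
            objective[model.reactions.index(rxn)] = coef
        return cls(
            reaction_ids=[r.id for r in model.reactions],
            metabolite_ids=met_ids,
            S=S,
            lower=lower,
            upper=upper,
            objective=objective,
            reaction_names=[r.name or r.id for r in model.reactions],
            metabolite_compartments=[m.compartment or "c" for m in model.metabolites],
            id=model.id or "constraint_model",
        )


def read_constraint_sbml(path: str) -> ConstraintModel:
    """Read a constraint-based model from SBML-fbc or BiGG-style JSON.

    The dialect is chosen by file extension (``.json`` versus anything else).
    Missing flux bounds are an error — no silent defaulting — as is a declared
    objective that cannot be resolved, or any reaction with L > U.
    """
    path = str(path)
    if path.endswith(".json"):
        _check_json_bounds(path)
        cobra_model = cobra.io.load_json_model(path)
    else:
        _check_sbml_fbc_bounds(path)
        try:
            cobra_model = cobra.io.read_sbml_model(path)
        except Exception as exc:  # cobra wraps libsbml failures opaquely
            raise SBMLParseError(f"{path}: {exc}") from exc
    model = ConstraintModel.from_cobra(cobra_model)
    model.validate()
    return model


def _check_json_bounds(path: str) -> None:
    import json

    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SBMLParseError(f"{path}: invalid JSON ({exc})") from exc
    for rxn in raw.get("reactions", []):
        if "lower_bound" not in rxn or "upper_bound" not in rxn:
            raise SBMLParseError(
                f"{path}: missing flux bounds for reaction {rxn.get('id')!r}"
            )


def _check_sbml_fbc_bounds(path: str) -> None:
    doc = libsbml.readSBML(path)
    _raise_sbml_errors(doc, path)
    m = doc.getModel()
    if m is None:
        raise SBMLParseError(f"{path}: file contains no SBML model")
    for rxn in m.getListOfReactions():
        fbc = rxn.getPlugin("fbc")
        if fbc is None or not (
            fbc.isSetLowerFluxBound() and fbc.isSetUpperFluxBound()
        ):
            raise SBMLParseError(
                f"{path}: missing flux bounds for reaction {rxn.getId()!r}"
            )
    mplug = m.getPlugin("fbc")
    if mplug is not None and mplug.getNumObjectives() > 0:
        active = mplug.getActiveObjective()
        if active is not None:
            declared = {r.getId() for r in m.getListOfReactions()}
            for fo in active.getListOfFluxObjectives():
                if fo.getReaction() not in declared:
                    raise SBMLParseError(
                        f"{path}: objective references unknown reaction "
                        f"{fo.getReaction()!r}"
                    )


def write_constraint_sbml(model: ConstraintModel, path: str) -> None:
    cobra.io.write_sbml_model(model.to_cobra(), str(path))


def write_constraint_json(model: ConstraintModel, path: str) -> None:
    cobra.io.save_json_model(model.to_cobra(), str(path))


# --------------------------------------------------------------------------
# Petri-net view
# --------------------------------------------------------------------------


@dataclass
class PetriNetView:
    """Bipartite Petri-net projection of a metabolic network.

    Places are metabolites, transitions are reactions; a reactant contributes
    a place→transition arc and a product a transition→place arc, each weighted
    by the absolute stoichiometric coefficient.
    """

    places: list[str]
    transitions: list[str]
    arcs: list[tuple[str, str, float]]  # (source, target, |coefficient|)

    def to_dot(self) -> str:
        lines = ["digraph petri_net {", "  rankdir=LR;"]
        place_set = set(self.places)
        for p in self.places:
            lines.append(f'  "p_{p}" [label="{p}", shape=circle];')
        for t in self.transitions:
            lines.append(f'  "t_{t}" [label="{t}", shape=box];')
        for src, dst, w in self.arcs:
            src_node = f"p_{src}" if src in place_set else f"t_{src}"
            dst_node = f"p_{dst}" if dst in place_set else f"t_{dst}"
            label = f"{w:g}"
            lines.append(f'  "{src_node}" -> "{dst_node}" [label="{label}"];')
        lines.append("}")
        return "\n".join(lines)


def export_petri_net(model: "ConstraintModel | KineticModel") -> PetriNetView:
    """Project a kinetic or constraint-based model onto its Petri-net view."""
    if isinstance(model, KineticModel):
        places = list(model.species_ids)
        transitions = list(model.reaction_ids)
        stoichs = [(r.id, r.stoichiometry) for r in model.reactions]
    else:
        places = list(model.metabolite_ids)
        transitions = list(model.reaction_ids)
        stoichs = [(rid, model.stoichiometry_of(rid)) for rid in model.reaction_ids]
    arcs: list[tuple[str, str, float]] = []
    for rid, stoich in stoichs:
        for met, coeff in sorted(stoich.items()):
            if coeff < 0:
                arcs.append((met, rid, abs(coeff)))
            elif coeff > 0:
                arcs.append((rid, met, abs(coeff)))
    return PetriNetView(places=places, transitions=transitions, arcs=arcs)


def _copy_with(model: KineticModel, **changes) -> KineticModel:
    """Shallow-copy a kinetic model with replaced fields."""
    base = dict(
        species=list(model.species),
        reactions=list(model.reactions),
        compartments=list(model.compartments),
        parameters=dict(model.parameters),
        id=model.id,
    )
    base.update(changes)
    return KineticModel(**base)
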