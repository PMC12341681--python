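"""Matched kinetic/constraint toy model pairs with closed-form ground truth.

These generators stand in for a genome-scale model pair (a central-carbon
kinetic model and a genome-scale stoichiometric reconstruction) at a scale
where every pipeline quantity can be computed by hand:

* ``make_linear_chain`` — an inflow–chain–outflow motif whose steady-state
  flux equals the inflow rate on every reaction, plus two dead-end
  reactions in the constraint model that are necessarily dormant;
* ``make_branch_fixture`` — glucose splitting between a biomass branch and
  a product branch.  The ODEs force strictly positive flux on both
  branches, while the constraint model alone routes everything into
  whichever branch is the objective: the growth/product bifurcation in
  miniature.  Its constraint model carries the cytosolic citramalate
  precursors so the producer-strain extension applies to it;
* ``make_category_zoo`` — one reaction pair per mapping category C0–C4
  (differing exactly by ±H₂O, HCO₃⁻/CO₂, a reversibility flag, or swapped
  sides) plus a two-to-one C5 subnetwork pair.

Fixtures are emitted as real SBML/JSON files by :func:`write_fixture`, so
file-reading code paths are exercised end to end.  The kinetic defaults
reproduce the reference study conditions: glucose uptake 0.23 mM s⁻¹ and a
growth rate of 0.1 h⁻¹ (chemostat dilution).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .mapping_translation import (
    CONVERSION_FACTOR,
    Category,
    MappingEntry,
    write_mapping_csv,
)
from .model_io import (
    Compartment,
    ConstraintModel,
    KineticModel,
    KineticReaction,
    Species,
    write_constraint_json,
    write_kinetic_sbml,
)

__all__ = [
    "FixtureSpec",
    "make_linear_chain",
    "make_branch_fixture",
    "make_category_zoo",
    "generate",
    "write_fixture",
]

_CYTOSOL = Compartment(id="c", name="cytosol", size=1.0)
_DEFAULT_BOUND = 1000.0


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a fixture, for CLI and batch generation."""

    motif: str = "linear-chain"  # linear-chain | branch-biomass-product | category-zoo
    n_reactions: int = 3
    seed: int = 0


def generate(spec: FixtureSpec):
    if spec.motif == "linear-chain":
        return make_linear_chain(n=spec.n_reactions, seed=spec.seed)
    if spec.motif == "branch-biomass-product":
        return make_branch_fixture(seed=spec.seed)
    if spec.motif == "category-zoo":
        return make_category_zoo()
    raise ValueError(f"unknown motif {spec.motif!r}")


def _constraint_model(
    reactions: list[tuple[str, dict[str, float], float, float]],
    metabolites: list[str],
    objective_id: str,
    model_id: str,
) -> ConstraintModel:
    met_index = {m: i for i, m in enumerate(metabolites)}
    S = np.zeros((len(metabolites), len(reactions)))
    lower = np.zeros(len(reactions))
    upper = np.zeros(len(reactions))
    rxn_ids = []
    for j, (rid, stoich, lo, hi) in enumerate(reactions):
        rxn_ids.append(rid)
        lower[j], upper[j] = lo, hi
        for met, coeff in stoich.items():
            S[met_index[met], j] = coeff
    objective = np.zeros(len(reactions))
    objective[rxn_ids.index(objective_id)] = 1.0
    model = ConstraintModel(
        reaction_ids=rxn_ids,
        metabolite_ids=list(metabolites),
        S=S,
        lower=lower,
        upper=upper,
        objective=objective,
        metabolite_compartments=["c"] * len(metabolites),
        id=model_id,
    )
    model.validate()
    return model


# --------------------------------------------------------------------------
# Linear chain
# --------------------------------------------------------------------------


def make_linear_chain(
    n: int = 3,
    k_in: float = 1.0,
    rate_constants: list[float] | None = None,
    seed: int = 0,
) -> tuple[KineticModel, ConstraintModel, list[MappingEntry]]:
    """Inflow → A₁ → … → A_{n−1} → outflow, n reactions in total.

    At steady state every reaction carries exactly ``k_in`` mM s⁻¹ (chain
    flux conservation), independent of the mass-action rate constants —
    which are drawn reproducibly from ``seed`` when not given.  The
    constraint model replicates the chain (all pairs category C0) and adds
    two dead-end reactions with no route to an exchange, so they are
    dormant at any optimum fraction.
    """
    if n < 2:
        raise ValueError("chain needs at least 2 reactions")
    if k_in <= 0:
        raise ValueError("inflow rate must be positive")
    n_internal = n - 1  # reactions consuming a species
    if rate_constants is None:
        rng = np.random.default_rng(seed)
        rate_constants = rng.uniform(0.3, 3.0, size=n_internal).round(6).tolist()
    if len(rate_constants) != n_internal or any(k <= 0 for k in rate_constants):
        raise ValueError(f"need {n_internal} positive rate constants")

    species_ids = [f"A{i}_c" for i in range(1, n)]
    species = [
        Species(id=sid, compartment="c", initial_concentration=1.0)
        for sid in species_ids
    ]
    reactions = [
        KineticReaction(
            id="R1",
            stoichiometry={species_ids[0]: 1.0},
            rate_law="k_in",
            parameters={"k_in": k_in},
        )
    ]
    for i, k in enumerate(rate_constants):
        src = species_ids[i]
        stoich = {src: -1.0}
        if i + 1 < len(species_ids):
            stoich[species_ids[i + 1]] = 1.0
        reactions.append(
            KineticReaction(
                id=f"R{i + 2}",
                stoichiometry=stoich,
                rate_law=f"k * {src}",
                parameters={"k": float(k)},
            )
        )
    kinetic = KineticModel(
        species=species,
        reactions=reactions,
        compartments=[_CYTOSOL],
        id="chain_kinetic",
    )
    kinetic.validate()

    cbm_reactions = [
        (r.id, dict(r.stoichiometry), 0.0, _DEFAULT_BOUND) for r in reactions
    ]
    # dead-end branch: A1 -> D1 -> D2 with no exit; necessarily zero flux
    cbm_reactions.append(
        ("DEAD1", {species_ids[0]: -1.0, "D1_c": 1.0}, 0.0, _DEFAULT_BOUND)
    )
    cbm_reactions.append(("DEAD2", {"D1_c": -1.0, "D2_c": 1.0}, 0.0, _DEFAULT_BOUND))
    constraint = _constraint_model(
        cbm_reactions,
        metabolites=species_ids + ["D1_c", "D2_c"],
        objective_id=f"R{n}",
        model_id="chain_gem",
    )
    mapping = [
        MappingEntry((r.id,), (r.id,), Category.C0) for r in reactions
    ]
    return kinetic, constraint, mapping


# --------------------------------------------------------------------------
# Branch (growth vs product) fixture
# --------------------------------------------------------------------------


def make_branch_fixture(
    uptake_max: float = 10.0,
    biomass_yield: float = 1.0,
    product_yield: float = 1.3,
    k_in: float = 0.23,
    seed: int = 0,
) -> tuple[KineticModel, ConstraintModel, list[MappingEntry]]:
    """Glucose splitting into a biomass branch and a product branch.

    Kinetic side: a constant glucose inflow ``k_in`` (default the reference
    uptake, 0.23 mM s⁻¹) splits mass-action-wise between the two branches in
    proportion ``biomass_yield : product_yield``; at the defaults the growth
    flux is 0.23·1.0/2.3 = 0.1 (read as h⁻¹, the chemostat dilution rate).
    Both branch fluxes are strictly positive at steady state.

    Constraint side: the same network with loose bounds, biomass as the
    objective, and the cytosolic citramalate precursors (acetyl-CoA,
    pyruvate, H₂O, CoA, H⁺) present so the producer-strain extension can be
    applied.  Maximising biomass alone sends the whole uptake down the
    biomass branch — the bifurcation this package exists to resolve.

    The mapping covers the uptake, both branch paths, and the product drain
    (all C0); growth is deliberately not mapped as a flux — it enters the
    constraint model through the growth-rate interval instead.
    """
    if biomass_yield <= 0 or product_yield <= 0:
        raise ValueError("yields must be positive")
    del seed  # no randomised parameters in this motif; kept for CLI symmetry
    species = [
        Species("glc__D_c", "c", 1.0),
        Species("accoa_c", "c", 1.0),
        Species("pyr_c", "c", 1.0),
        Species("coa_c", "c", 1.0, boundary=True),
        Species("h2o_c", "c", 1.0, boundary=True),
    ]
    reactions = [
        KineticReaction("EX_glc", {"glc__D_c": 1.0}, "k_in", {"k_in": k_in}),
        KineticReaction(
            "BIO_PATH",
            {"glc__D_c": -1.0, "coa_c": -1.0, "accoa_c": 1.0, "h2o_c": 1.0},
            "k_bio * glc__D_c",
            {"k_bio": biomass_yield},
        ),
        KineticReaction(
            "PROD_PATH",
            {"glc__D_c": -1.0, "pyr_c": 1.0},
            "k_prod * glc__D_c",
            {"k_prod": product_yield},
        ),
        KineticReaction(
            "BIOMASS",
            {"accoa_c": -1.0, "coa_c": 1.0},
            "k_gr * accoa_c",
            {"k_gr": 1.0},
        ),
        KineticReaction(
            "PRODUCT", {"pyr_c": -1.0}, "k_pr * pyr_c", {"k_pr": 1.0}
        ),
    ]
    kinetic = KineticModel(
        species=species,
        reactions=reactions,
        compartments=[_CYTOSOL],
        id="branch_kinetic",
    )
    kinetic.validate()

    mets = ["glc__D_c", "coa_c", "accoa_c", "h2o_c", "pyr_c", "h_c"]
    cbm_reactions = [
        ("EX_glc", {"glc__D_c": 1.0}, 0.0, uptake_max),
        (
            "BIO_PATH",
            {"glc__D_c": -1.0, "coa_c": -1.0, "accoa_c": 1.0, "h2o_c": 1.0},
            0.0,
            _DEFAULT_BOUND,
        ),
        ("PROD_PATH", {"glc__D_c": -1.0, "pyr_c": 1.0}, 0.0, _DEFAULT_BOUND),
        # biomass flux is read as a growth rate in h^-1, so its precursor
        # demand per flux unit equals the mM s^-1 -> mmol gDW^-1 h^-1 volume
        # factor; this makes the kinetic steady state exactly feasible after
        # translation.
        (
            "BIOMASS",
            {"accoa_c": -CONVERSION_FACTOR, "coa_c": CONVERSION_FACTOR},
            0.0,
            _DEFAULT_BOUND,
        ),
        ("PRODUCT", {"pyr_c": -1.0}, 0.0, _DEFAULT_BOUND),
        ("EX_h2o", {"h2o_c": -1.0}, -_DEFAULT_BOUND, _DEFAULT_BOUND),
        ("EX_h", {"h_c": -1.0}, -_DEFAULT_BOUND, _DEFAULT_BOUND),
    ]
    constraint = _constraint_model(
        cbm_reactions, mets, objective_id="BIOMASS", model_id="branch_gem"
    )
    mapping = [
        MappingEntry(("EX_glc",), ("EX_glc",), Category.C0),
        MappingEntry(("BIO_PATH",), ("BIO_PATH",), Category.C0),
        MappingEntry(("PROD_PATH",), ("PROD_PATH",), Category.C0),
        MappingEntry(("PRODUCT",), ("PRODUCT",), Category.C0),
    ]
    return kinetic, constraint, mapping


# --------------------------------------------------------------------------
# Category zoo
# --------------------------------------------------------------------------


def make_category_zoo() -> tuple[KineticModel, ConstraintModel, list[MappingEntry]]:
    """One exemplar reaction pair per mapping category C0–C5.

    The pairs are constructed to differ exactly as their category
    prescribes; the constraint model here is a classification target, not a
    flux-consistent network (its metabolite rows are not balanced).
    """
    kin_defs = [
        ("Z0", {"a0_c": -1.0, "b0_c": -1.0, "c0_c": 1.0}, False,
         "k * a0_c * b0_c"),
        ("Z1", {"fdp_c": -1.0, "f6p_c": 1.0, "pi_c": 1.0}, False, "k * fdp_c"),
        ("Z2",
         {"mal_c": -1.0, "nad_c": -1.0, "nadh_c": 1.0, "pyr_c": 1.0,
          "hco3_c": 1.0},
         False, "k * mal_c * nad_c"),
        ("Z3", {"icit_c": -1.0, "glx_c": 1.0, "succ_c": 1.0}, True,
         "k * icit_c"),
        ("Z4", {"adp_c": -1.0, "bpg_c": -1.0, "atp_c": 1.0, "pg3_c": 1.0},
         True, "k * (adp_c * bpg_c - atp_c * pg3_c)"),
        ("C5_STEP1", {"z5a_c": -1.0, "z5b_c": 1.0}, False, "k * z5a_c"),
        ("C5_STEP2", {"z5b_c": -1.0, "z5c_c": 1.0}, False, "k * z5b_c"),
    ]
    kin_species = sorted({m for _, st, _, _ in kin_defs for m in st})
    kinetic = KineticModel(
        species=[Species(sid, "c", 1.0) for sid in kin_species],
        reactions=[
            KineticReaction(rid, stoich, law, {"k": 1.0}, reversible=rev)
            for rid, stoich, rev, law in kin_defs
        ],
        compartments=[_CYTOSOL],
        id="zoo_kinetic",
    )
    kinetic.validate()

    cbm_defs = [
        ("Z0_cbm", {"a0_c": -1.0, "b0_c": -1.0, "c0_c": 1.0}, 0.0,
         _DEFAULT_BOUND),
        ("Z1_cbm", {"fdp_c": -1.0, "h2o_c": -1.0, "f6p_c": 1.0, "pi_c": 1.0},
         0.0, _DEFAULT_BOUND),
        ("Z2_cbm",
         {"mal_c": -1.0, "nad_c": -1.0, "nadh_c": 1.0, "pyr_c": 1.0,
          "co2_c": 1.0},
         0.0, _DEFAULT_BOUND),
        ("Z3_cbm", {"icit_c": -1.0, "glx_c": 1.0, "succ_c": 1.0}, 0.0,
         _DEFAULT_BOUND),
        ("Z4_cbm", {"pg3_c": -1.0, "atp_c": -1.0, "bpg_c": 1.0, "adp_c": 1.0},
         -_DEFAULT_BOUND, _DEFAULT_BOUND),
        ("C5_LUMP", {"z5a_c": -1.0, "z5c_c": 1.0}, 0.0, _DEFAULT_BOUND),
    ]
    cbm_mets = sorted({m for _, st, _, _ in cbm_defs for m in st})
    constraint = _constraint_model(
        cbm_defs, cbm_mets, objective_id="C5_LUMP", model_id="zoo_gem"
    )
    mapping = [
        MappingEntry(("Z0",), ("Z0_cbm",), Category.C0),
        MappingEntry(("Z1",), ("Z1_cbm",), Category.C1),
        MappingEntry(("Z2",), ("Z2_cbm",), Category.C2),
        MappingEntry(("Z3",), ("Z3_cbm",), Category.C3),
        MappingEntry(("Z4",), ("Z4_cbm",), Category.C4),
        MappingEntry(("C5_STEP1", "C5_STEP2"), ("C5_LUMP",), Category.C5),
    ]
    return kinetic, constraint, mapping


def write_fixture(
    kinetic: KineticModel,
    constraint: ConstraintModel,
    mapping: list[MappingEntry],
    out_dir: str,
) -> dict[str, str]:
    """Write kinetic.xml, gem.json and mapping.csv into ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "kinetic": os.path.join(out_dir, "kinetic.xml"),
        "gem": os.path.join(out_dir, "gem.json"),
        "mapping": os.path.join(out_dir, "mapping.csv"),
    }
    write_kinetic_sbml(kinetic, paths["kinetic"])
    write_constraint_json(constraint, paths["gem"])
    write_mapping_csv(mapping, paths["mapping"])
    return paths
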