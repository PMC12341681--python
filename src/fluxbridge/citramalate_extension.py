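"""Citramalate-producing strain extension of the constraint-based model.

Four reactions turn a wild-type model into a citramalate producer:

* ``CIMA`` — citramalate synthase (CimA3.7):
  acetyl-CoA + pyruvate + H₂O → CoA + H⁺ + citramalate (cytosol);
* ``CitraTransp1`` / ``CitraTransp2`` — irreversible transport
  cytosol → periplasm → extracellular;
* ``EX_Citramalate`` — exchange draining extracellular citramalate, so a
  steady state is reachable and the product flux can be maximised.

A plain FBA on this model bifurcates: the carbon source is routed entirely
to biomass or entirely to citramalate depending on the objective.  Fixing
the biomass flux to the kinetic model's growth rate interval
[μk(1−d), μk(1+d)] before maximising ``EX_Citramalate`` removes the
degeneracy and yields simultaneous growth and production.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lp_analysis import run_fba
from .mapping_translation import CONVERSION_FACTOR
from .model_io import ConstraintModel

__all__ = [
    "CIMA_ID",
    "TRANSPORT1_ID",
    "TRANSPORT2_ID",
    "EXCHANGE_ID",
    "MOLAR_MASS_CITRAMALATE",
    "MOLAR_MASS_GLUCOSE",
    "GrowthInterval",
    "extend_gem_with_citramalate",
    "fix_growth_interval",
    "find_biomass_reaction",
    "conversion_efficiency",
    "citramalate_production",
]

CIMA_ID = "CIMA"
TRANSPORT1_ID = "CitraTransp1"
TRANSPORT2_ID = "CitraTransp2"
EXCHANGE_ID = "EX_Citramalate"

#: Citramalate C5H8O5, g mol⁻¹.
MOLAR_MASS_CITRAMALATE = 148.11
#: Glucose C6H12O6, g mol⁻¹.
MOLAR_MASS_GLUCOSE = 180.16

#: Cytosolic precursors required by the synthase reaction (BiGG ids).
_DEFAULT_PRECURSORS = {
    "acetyl_coa": "accoa_c",
    "pyruvate": "pyr_c",
    "water": "h2o_c",
    "coa": "coa_c",
    "proton": "h_c",
}


@dataclass(frozen=True)
class GrowthInterval:
    """Biomass-flux interval [μk(1−d), μk(1+d)] derived from kinetics."""

    mu_k: float
    d: float

    @property
    def lower(self) -> float:
        return self.mu_k * (1 - self.d)

    @property
    def upper(self) -> float:
        return self.mu_k * (1 + self.d)


def extend_gem_with_citramalate(
    model: ConstraintModel,
    precursors: dict[str, str] | None = None,
    transport_upper: float = 1000.0,
) -> ConstraintModel:
    """Add the citramalate synthesis/secretion pathway to a model.

    Adds the citramalate metabolite in cytosol, periplasm and extracellular
    compartments and the four reactions listed in the module docstring,
    irreversible outward with bounds [0, ``transport_upper``].  The input
    model must already contain the cytosolic precursors (acetyl-CoA,
    pyruvate, H₂O, CoA, H⁺); ids can be overridden via ``precursors``.
    """
    prec = dict(_DEFAULT_PRECURSORS)
    if precursors:
        prec.update(precursors)
    missing = [pid for pid in prec.values() if pid not in model.metabolite_ids]
    if missing:
        raise ValueError(
            f"model lacks precursor metabolites {missing}; cannot add "
            "citramalate synthesis"
        )
    new_rxns = [CIMA_ID, TRANSPORT1_ID, TRANSPORT2_ID, EXCHANGE_ID]
    clash = [r for r in new_rxns if r in model.reaction_ids]
    if clash:
        raise ValueError(f"model already contains reactions {clash}")
    new_mets = ["citramalate_c", "citramalate_p", "citramalate_e"]
    met_clash = [m for m in new_mets if m in model.metabolite_ids]
    if met_clash:
        raise ValueError(f"model already contains metabolites {met_clash}")

    m_old, n_old = model.S.shape
    S = np.zeros((m_old + 3, n_old + 4))
    S[:m_old, :n_old] = model.S
    met_ids = list(model.metabolite_ids) + new_mets
    met_index = {m: i for i, m in enumerate(met_ids)}
    # CIMA: accoa + pyr + h2o -> coa + h + citramalate_c
    j = n_old
    for name, coeff in (
        ("acetyl_coa", -1.0), ("pyruvate", -1.0), ("water", -1.0),
        ("coa", 1.0), ("proton", 1.0),
    ):
        S[met_index[prec[name]], j] = coeff
    S[met_index["citramalate_c"], j] = 1.0
    # transports and exchange
    S[met_index["citramalate_c"], n_old + 1] = -1.0
    S[met_index["citramalate_p"], n_old + 1] = 1.0
    S[met_index["citramalate_p"], n_old + 2] = -1.0
    S[met_index["citramalate_e"], n_old + 2] = 1.0
    S[met_index["citramalate_e"], n_old + 3] = -1.0

    out = ConstraintModel(
        reaction_ids=list(model.reaction_ids) + new_rxns,
        metabolite_ids=met_ids,
        S=S,
        lower=np.concatenate([model.lower, np.zeros(4)]),
        upper=np.concatenate([model.upper, np.full(4, transport_upper)]),
        objective=np.concatenate([model.objective, np.zeros(4)]),
        reaction_names=list(model.reaction_names)
        + [
            "citramalate synthase (CimA3.7)",
            "citramalate transport cytosol->periplasm",
            "citramalate transport periplasm->extracellular",
            "citramalate exchange",
        ],
        metabolite_compartments=list(model.metabolite_compartments)
        + ["c", "p", "e"],
        id=model.id + "_citramalate",
    )
    out.validate()
    return out


def find_biomass_reaction(model: ConstraintModel) -> str:
    """Locate the biomass reaction by id (must be unambiguous)."""
    candidates = [r for r in model.reaction_ids if "biomass" in r.lower()]
    if len(candidates) != 1:
        raise ValueError(
            f"cannot identify a unique biomass reaction; candidates: {candidates}"
        )
    return candidates[0]


def fix_growth_interval(
    model: ConstraintModel,
    mu_k: float,
    d: float,
    biomass_id: str | None = None,
) -> ConstraintModel:
    """Pin the biomass flux into [μk(1−d), μk(1+d)].

    ``mu_k`` is the kinetic model's growth rate (h⁻¹).  The objective is
    left untouched — the caller switches it (e.g. to ``EX_Citramalate``)
    when maximising product formation.  Returns a modified copy.
    """
    if mu_k < 0:
        raise ValueError("mu_k must be nonnegative")
    if not 0 <= d < 1:
        raise ValueError("d must lie in [0, 1)")
    rid = biomass_id or find_biomass_reaction(model)
    interval = GrowthInterval(mu_k=mu_k, d=d)
    out = model.copy()
    j = out.reaction_index(rid)
    out.lower[j] = interval.lower
    out.upper[j] = interval.upper
    out.validate()
    return out


def conversion_efficiency(
    v_citramalate: float,
    v_glucose_uptake: float,
    molar_mass_citramalate: float = MOLAR_MASS_CITRAMALATE,
    molar_mass_glucose: float = MOLAR_MASS_GLUCOSE,
) -> float:
    """Grams of citramalate secreted per gram of glucose consumed.

    Defined as (v_cit · M_cit) / (v_glc · M_glc) for fluxes in mmol gDW⁻¹
    h⁻¹, with ``v_glucose_uptake`` the magnitude of the uptake flux.
    """
    if v_glucose_uptake <= 0:
        raise ValueError("glucose uptake must be positive")
    return (v_citramalate * molar_mass_citramalate) / (
        v_glucose_uptake * molar_mass_glucose
    )


def citramalate_production(
    model: ConstraintModel,
    glucose_exchange_id: str,
    mu_k: float | None = None,
    d: float | None = None,
    biomass_id: str | None = None,
) -> dict:
    """Maximise citramalate export and report fluxes and efficiency.

    The model must already contain the citramalate pathway.  If ``mu_k``
    and ``d`` are given, the biomass flux is first fixed to
    [μk(1−d), μk(1+d)] (the bifurcation-resolving constraint); otherwise
    the plain, unfixed model is analysed.  Returns a dict with the optimal
    citramalate flux, the glucose uptake magnitude, the biomass flux, and
    the g/g conversion efficiency.
    """
    work = model
    interval = None
    if mu_k is not None:
        if d is None:
            raise ValueError("d is required when mu_k is given")
        work = fix_growth_interval(work, mu_k, d, biomass_id=biomass_id)
        interval = GrowthInterval(mu_k=mu_k, d=d)
    fba = run_fba(work, objective=EXCHANGE_ID)
    if not fba.optimal:
        return {
            "status": fba.status,
            "d": d,
            "mu_interval": (interval.lower, interval.upper) if interval else None,
            "v_cit": None,
            "v_glc": None,
            "v_biomass": None,
            "efficiency_g_per_g": None,
        }
    v_cit = float(fba.fluxes[EXCHANGE_ID])
    v_glc = abs(float(fba.fluxes[glucose_exchange_id]))
    bid = biomass_id or find_biomass_reaction(model)
    return {
        "status": "optimal",
        "d": d,
        "mu_interval": (interval.lower, interval.upper) if interval else None,
        "v_cit": v_cit,
        "v_glc": v_glc,
        "v_biomass": float(fba.fluxes[bid]),
        "efficiency_g_per_g": conversion_efficiency(v_cit, v_glc),
    }
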