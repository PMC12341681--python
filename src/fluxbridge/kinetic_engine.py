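"""Steady-state simulation of kinetic models and enzyme-rate helpers.

The ODE system d[s]/dt = Σ_r S(s, r)·v_r([·]) is integrated with stiff-aware
scipy solvers until concentration derivatives vanish.  Steady-state fluxes
f(r), in mM s⁻¹, are the rate laws evaluated at the final state; they are the
raw material for constraint-model bound translation.

Also here: Vmax = kcat·[E], Vmax from per-cell enzyme activity, and the
insertion of the citramalate synthase reaction (CimA3.7, Michaelis–Menten in
acetyl-CoA with pyruvate assumed saturating).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from .model_io import (
    KineticModel,
    KineticReaction,
    Species,
    parse_rate_law,
)

__all__ = [
    "SteadyStateResult",
    "IntegrationError",
    "simulate_to_steady_state",
    "evaluate_fluxes",
    "compute_vmax_from_cell_activity",
    "vmax_from_kcat",
    "add_citramalate_synthesis",
    "extract_growth_rate",
    "CITRAMALATE_KM_MM",
    "CITRAMALATE_VMAX_MM_PER_S",
    "CITRA_SYN_ID",
]

#: Michaelis constant of CimA3.7 for acetyl-CoA, mM.
CITRAMALATE_KM_MM = 0.495
#: Maximal citramalate synthesis rate of CimA3.7, mM s⁻¹
#: (per-cell activity 24.34e-10 nmol/s over a 6e-16 L cell).
CITRAMALATE_VMAX_MM_PER_S = 4.06
#: Reaction id used for the kinetic citramalate synthesis step.
CITRA_SYN_ID = "CITRA_SYN"

#: Default simulation horizon, seconds; central-carbon models typically
#: settle within one hour of simulated time.
DEFAULT_T_END_S = 3600.0
#: Steadiness criterion: max |d[s]/dt| at the final time, mM s⁻¹.
DEFAULT_STEADY_TOL = 1e-6


class IntegrationError(RuntimeError):
    """Raised when the ODE integration fails or produces unusable state."""


@dataclass
class SteadyStateResult:
    """Concentrations and fluxes at the end of a steady-state simulation.

    ``steadiness`` is the maximum absolute concentration derivative over
    non-boundary species at ``final_time`` (mM s⁻¹); ``converged`` records
    whether it met the requested tolerance.  ``growth_rate`` (h⁻¹) is filled
    when a growth reaction id was supplied.
    """

    concentrations: dict[str, float]
    fluxes: dict[str, float]
    final_time: float
    steadiness: float
    converged: bool
    growth_rate: float | None = None
    tolerance: float = DEFAULT_STEADY_TOL


def _compile_model(model: KineticModel):
    """Compile rate laws into a vectorised callable over the full state."""
    species_ids = model.species_ids
    syms = [sp.Symbol(s) for s in species_ids]
    exprs = [parse_rate_law(model, rxn) for rxn in model.reactions]
    rate_fn = sp.lambdify(syms, sp.Matrix(exprs), modules="numpy")

    def rates(conc: np.ndarray) -> np.ndarray:
        return np.asarray(rate_fn(*conc), dtype=float).ravel()

    return species_ids, rates


def simulate_to_steady_state(
    model: KineticModel,
    t_end: float = DEFAULT_T_END_S,
    tol: float = DEFAULT_STEADY_TOL,
    growth_reaction_id: str | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    extend_once: bool = True,
) -> SteadyStateResult:
    """Integrate the ODE system to ``t_end`` and report the steady state.

    Boundary species are held constant.  If the steadiness criterion
    max |d[s]/dt| ≤ ``tol`` is not met at ``t_end``, the integration is
    extended once to 10·``t_end`` before the result is flagged unconverged.

    Raises
    ------
    IntegrationError
        if the solver fails (reporting the last successful time) or a
        concentration goes negative beyond numerical noise.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    model.validate()
    species_ids, rates = _compile_model(model)
    n_species = len(species_ids)
    dynamic = np.array([not s.boundary for s in model.species], dtype=bool)
    # stoichiometry over all species x reactions
    S = np.zeros((n_species, len(model.reactions)))
    sp_index = {s: i for i, s in enumerate(species_ids)}
    for j, rxn in enumerate(model.reactions):
        for sid, coeff in rxn.stoichiometry.items():
            S[sp_index[sid], j] = coeff
    y_full0 = np.array([s.initial_concentration for s in model.species])

    def rhs(_t: float, y_dyn: np.ndarray) -> np.ndarray:
        y = y_full0.copy()
        y[dynamic] = y_dyn
        return (S @ rates(y))[dynamic]

    y0 = y_full0[dynamic]
    t0, y_end = 0.0, y0
    horizon = t_end
    final_time = t_end
    for attempt in range(2 if extend_once else 1):
        if y0.size == 0:
            y_end = y0
            break
        sol = solve_ivp(
            rhs, (t0, horizon), y_end if attempt else y0,
            method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            last_t = sol.t[-1] if sol.t.size else t0
            raise IntegrationError(
                f"integration failed at t = {last_t:g} s: {sol.message}"
            )
        y_end = sol.y[:, -1]
        final_time = sol.t[-1]
        if np.max(np.abs(rhs(final_time, y_end)), initial=0.0) <= tol:
            break
        t0, horizon = final_time, 10.0 * t_end

    neg = y_end < 0
    if np.any(y_end < -1e3 * atol):
        worst = np.asarray(species_ids)[dynamic][neg]
        raise IntegrationError(
            f"negative concentrations beyond tolerance for {list(worst)}"
        )
    y_end = np.clip(y_end, 0.0, None)

    y_final = y_full0.copy()
    y_final[dynamic] = y_end
    flux = rates(y_final)
    if not np.all(np.isfinite(flux)):
        bad = [model.reaction_ids[j] for j in np.nonzero(~np.isfinite(flux))[0]]
        raise IntegrationError(f"non-finite fluxes for reactions {bad}")
    deriv = (S @ flux)[dynamic]
    steadiness = float(np.max(np.abs(deriv), initial=0.0))

    result = SteadyStateResult(
        concentrations=dict(zip(species_ids, y_final.tolist())),
        fluxes=dict(zip(model.reaction_ids, flux.tolist())),
        final_time=float(final_time),
        steadiness=steadiness,
        converged=steadiness <= tol,
        tolerance=tol,
    )
    if growth_reaction_id is not None:
        result.growth_rate = extract_growth_rate(result, growth_reaction_id)
    return result


def evaluate_fluxes(
    model: KineticModel, concentrations: dict[str, float]
) -> dict[str, float]:
    """Evaluate all rate laws at a given concentration state (mM s⁻¹)."""
    species_ids, rates = _compile_model(model)
    conc = np.array([concentrations[s] for s in species_ids])
    return dict(zip(model.reaction_ids, rates(conc).tolist()))


def compute_vmax_from_cell_activity(
    activity_nmol_per_s: float, cell_volume_l: float
) -> float:
    """Vmax in mM s⁻¹ from a per-cell enzyme activity and the cell volume.

    activity / volume has units nmol L⁻¹ s⁻¹; 1 nmol L⁻¹ = 10⁻⁶ mM, handled
    explicitly here.
    """
    if activity_nmol_per_s < 0:
        raise ValueError("activity must be nonnegative")
    if cell_volume_l <= 0:
        raise ValueError("cell volume must be positive")
    return activity_nmol_per_s / cell_volume_l * 1e-6


def vmax_from_kcat(kcat_per_s: float, enzyme_conc_mm: float) -> float:
    """Vmax = kcat·[E], in mM s⁻¹ for kcat in s⁻¹ and [E] in mM."""
    if kcat_per_s < 0 or enzyme_conc_mm < 0:
        raise ValueError("kcat and enzyme concentration must be nonnegative")
    return kcat_per_s * enzyme_conc_mm


def _find_species(model: KineticModel, prefixes: tuple[str, ...]) -> str | None:
    for s in model.species:
        lowered = s.id.lower()
        if any(lowered == p or lowered.startswith(p) for p in prefixes):
            return s.id
    return None


def add_citramalate_synthesis(
    model: KineticModel,
    Km: float = CITRAMALATE_KM_MM,
    Vmax: float = CITRAMALATE_VMAX_MM_PER_S,
    acetyl_coa_id: str | None = None,
    pyruvate_id: str | None = None,
) -> KineticModel:
    """Return a copy of ``model`` with the citramalate synthase reaction.

    The reaction (id ``CITRA_SYN``) is
    acetyl-CoA + pyruvate + H₂O → CoA + H⁺ + citramalate with rate
    Vmax·[AcCoA]/([AcCoA] + Km): Michaelis–Menten in acetyl-CoA, with
    pyruvate assumed saturating (pyruvate still appears in the stoichiometry
    for mass balance, just not in the rate law).  Citramalate — and any of
    H₂O/CoA/H⁺ the model lacks — are added as boundary species so a steady
    state remains reachable.
    """
    if any(r.id == CITRA_SYN_ID for r in model.reactions):
        raise ValueError(f"model already contains a reaction {CITRA_SYN_ID!r}")
    accoa = acetyl_coa_id or _find_species(model, ("accoa", "acetyl_coa", "acoa"))
    pyr = pyruvate_id or _find_species(model, ("pyr",))
    missing = []
    if accoa is None:
        missing.append("acetyl-CoA")
    if pyr is None:
        missing.append("pyruvate")
    if missing:
        raise ValueError(
            f"model lacks cytoplasmic {' and '.join(missing)}; "
            f"candidate species ids: {model.species_ids}"
        )
    compartment = model.get_species(accoa).compartment

    species = list(model.species)
    present = set(model.species_ids)

    def ensure_boundary(sid: str) -> str:
        if sid not in present:
            species.append(
                Species(
                    id=sid,
                    compartment=compartment,
                    initial_concentration=1.0,
                    boundary=True,
                )
            )
            present.add(sid)
        return sid

    h2o = _find_species(model, ("h2o",)) or ensure_boundary("h2o_c")
    coa = next(
        (s.id for s in model.species if s.id.lower() in ("coa", "coa_c")), None
    ) or ensure_boundary("coa_c")
    proton = next(
        (s.id for s in model.species if s.id.lower() in ("h", "h_c")), None
    ) or ensure_boundary("h_c")
    citramalate = ensure_boundary("citramalate_c")

    rxn = KineticReaction(
        id=CITRA_SYN_ID,
        stoichiometry={
            accoa: -1.0,
            pyr: -1.0,
            h2o: -1.0,
            coa: 1.0,
            proton: 1.0,
            citramalate: 1.0,
        },
        rate_law=f"Vmax_cs * {accoa} / ({accoa} + Km_cs)",
        parameters={"Vmax_cs": Vmax, "Km_cs": Km},
        name="citramalate synthase (CimA3.7)",
    )
    out = KineticModel(
        species=species,
        reactions=list(model.reactions) + [rxn],
        compartments=list(model.compartments),
        parameters=dict(model.parameters),
        id=model.id,
    )
    out.validate()
    return out


def extract_growth_rate(result: SteadyStateResult, growth_reaction_id: str) -> float:
    """Growth-reaction flux read as a specific growth rate in h⁻¹.

    The kinetic model's biomass "flux" is a specific growth rate rather than
    a metabolite flux, so no mM s⁻¹ → mmol gDW⁻¹ h⁻¹ conversion is applied.
    """
    try:
        return float(result.fluxes[growth_reaction_id])
    except KeyError:
        raise KeyError(
            f"unknown growth reaction {growth_reaction_id!r}; available: "
            f"{sorted(result.fluxes)}"
        ) from None
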