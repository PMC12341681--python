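"""Flux balance analysis, flux variability analysis, and dormancy metrics.

FBA solves  max cᵀv  s.t.  S·v = 0,  L ≤ v ≤ U.  FVA then minimises and
maximises each reaction flux v(r) under the additional constraint
cᵀv ≥ q·μ where μ is the FBA optimum and q ∈ [0, 1] (q = 0.999 by default:
sitting exactly on the optimal face can defeat LP solvers numerically).

FV(r) = maxF(r) − minF(r) measures a reaction's remaining flux freedom, and
a reaction is *dormant* when |minF(r)| ≤ ε and |maxF(r)| ≤ ε — its
steady-state flux is necessarily (numerically) zero.  ε defaults to 10⁻²
mmol gDW⁻¹ h⁻¹, deliberately far above LP solver accuracy.

Linear programs are solved with the HiGHS solvers behind
``scipy.optimize.linprog``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model_io import ConstraintModel

__all__ = [
    "FBAResult",
    "FVAResult",
    "LPError",
    "DEFAULT_Q",
    "DORMANCY_EPSILON",
    "run_fba",
    "run_fva",
    "is_dormant",
    "count_dormant",
]

#: Default fraction of the FBA optimum retained during FVA.
DEFAULT_Q = 0.999
#: Dormancy threshold ε, mmol gDW⁻¹ h⁻¹.
DORMANCY_EPSILON = 1e-2


class LPError(RuntimeError):
    """Raised when the LP solver fails for a reason other than infeasibility."""


@dataclass
class FBAResult:
    """Outcome of one flux balance analysis."""

    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: float | None
    fluxes: pd.Series | None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FVAResult:
    """Per-reaction flux ranges compatible with a fraction q of the optimum."""

    reaction_ids: list[str]
    min_flux: np.ndarray
    max_flux: np.ndarray
    q: float

    @property
    def fv(self) -> np.ndarray:
        """FV(r) = maxF(r) − minF(r), clipped at 0 against solver noise."""
        return np.maximum(self.max_flux - self.min_flux, 0.0)

    def to_frame(self, epsilon: float = DORMANCY_EPSILON) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reaction_id": self.reaction_ids,
                "minF": self.min_flux,
                "maxF": self.max_flux,
                "FV": self.fv,
                "dormant": [
                    is_dormant(lo, hi, epsilon)
                    for lo, hi in zip(self.min_flux, self.max_flux)
                ],
            }
        )


def _objective_vector(
    model: ConstraintModel,
    objective: "str | Mapping[str, float] | None",
) -> np.ndarray:
    if objective is None:
        c = model.objective.copy()
        if not np.any(c):
            raise ValueError("model declares no objective and none was given")
        return c
    c = np.zeros(model.n_reactions)
    if isinstance(objective, str):
        c[model.reaction_index(objective)] = 1.0
    else:
        for rid, coeff in objective.items():
            c[model.reaction_index(rid)] = coeff
    return c


def _solve(
    c_min: np.ndarray,
    model: ConstraintModel,
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
):
    return linprog(
        c_min,
        A_eq=model.S,
        b_eq=np.zeros(model.n_metabolites),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=list(zip(model.lower, model.upper)),
        method="highs",
    )


def run_fba(
    model: ConstraintModel,
    objective: "str | Mapping[str, float] | None" = None,
    sense: str = "max",
) -> FBAResult:
    """Solve the FBA linear program.

    ``objective`` is a reaction id, a weight map, or None to use the model's
    declared objective.  Infeasibility is reported in the result status,
    never masked with a zero flux vector; other solver failures raise
    :class:`LPError`.
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    c = _objective_vector(model, objective)
    sign = -1.0 if sense == "max" else 1.0
    res = _solve(sign * c, model)
    if res.status == 2:
        return FBAResult(status="infeasible", objective_value=None, fluxes=None)
    if res.status == 3:
        return FBAResult(status="unbounded", objective_value=None, fluxes=None)
    if res.status != 0:
        raise LPError(f"LP solver failed: {res.message}")
    v = np.asarray(res.x)
    return FBAResult(
        status="optimal",
        objective_value=float(c @ v),
        fluxes=pd.Series(v, index=model.reaction_ids),
    )


def run_fva(
    model: ConstraintModel,
    objective: "str | Mapping[str, float] | None" = None,
    q: float = DEFAULT_Q,
    reactions: Sequence[str] | None = None,
) -> FVAResult:
    """Flux variability analysis at optimum fraction ``q``.

    For every reaction r, minF(r) and maxF(r) solve min/max v(r) subject to
    S·v = 0, L ≤ v ≤ U and cᵀv ≥ q·μ.  The base model must be feasible.
    """
    if not 0 <= q <= 1:
        raise ValueError("q must lie in [0, 1]")
    c = _objective_vector(model, objective)
    base = run_fba(model, objective=objective)
    if not base.optimal:
        raise LPError(f"base FBA is {base.status}; FVA undefined")
    mu = base.objective_value
    A_ub = -c.reshape(1, -1)
    b_ub = np.array([-q * mu])

    rxn_ids = list(reactions) if reactions is not None else list(model.reaction_ids)
    n = len(rxn_ids)
    lo = np.empty(n)
    hi = np.empty(n)
    for k, rid in enumerate(rxn_ids):
        j = model.reaction_index(rid)
        e = np.zeros(model.n_reactions)
        e[j] = 1.0
        for sign, target in ((1.0, lo), (-1.0, hi)):
            res = _solve(sign * e, model, A_ub=A_ub, b_ub=b_ub)
            if res.status != 0:
                raise LPError(
                    f"FVA subproblem for {rid!r} failed: {res.message}"
                )
            target[k] = sign * res.fun
    # guard against sub-tolerance inversions from independent LP solves
    lo = np.minimum(lo, hi)
    return FVAResult(reaction_ids=rxn_ids, min_flux=lo, max_flux=hi, q=q)


def is_dormant(
    min_flux: float, max_flux: float, epsilon: float = DORMANCY_EPSILON
) -> bool:
    """True iff |minF| ≤ ε and |maxF| ≤ ε (inclusive on both sides)."""
    if min_flux > max_flux:
        raise ValueError("min_flux must not exceed max_flux")
    return abs(min_flux) <= epsilon and abs(max_flux) <= epsilon


def count_dormant(fva: FVAResult, epsilon: float = DORMANCY_EPSILON) -> int:
    """Number of dormant reactions in an FVA result."""
    return int(
        np.sum(
            (np.abs(fva.min_flux) <= epsilon) & (np.abs(fva.max_flux) <= epsilon)
        )
    )
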