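"""Sequential enrichment of a constraint-based model with kinetic bounds.

Kinetic bound assignments are applied one reaction at a time, in a caller
supplied order (the reference analysis follows glucose metabolism).  After
each addition, FBA and FVA are rerun and the trajectory metrics recorded:
objective (growth) value, dormant-reaction count, and the number of
reactions whose flux variability FV(r) rose or fell relative to the
original, unenriched model.  When an addition makes the LP infeasible the
step is recorded as such and the sweep stops (optionally it can skip the
offending reaction instead and continue).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lp_analysis import (
    DEFAULT_Q,
    DORMANCY_EPSILON,
    FVAResult,
    count_dormant,
    run_fba,
    run_fva,
)
from .mapping_translation import BoundAssignment, apply_bounds, CONVERSION_FACTOR
from .model_io import ConstraintModel

__all__ = [
    "SweepStep",
    "SweepTrace",
    "FVDistribution",
    "run_enrichment_sweep",
    "compare_variability",
    "cumulative_fv_distribution",
    "constrain_glucose_uptake",
    "DEFAULT_GLUCOSE_UPTAKE_MM_S",
]

#: Glucose uptake of the kinetic reference simulation, mM s⁻¹.
DEFAULT_GLUCOSE_UPTAKE_MM_S = 0.23


@dataclass(frozen=True)
class SweepStep:
    index: int
    reaction_id: str
    feasible: bool
    growth_rate: float | None
    dormant_count: int | None
    n_more_variability: int | None
    n_less_variability: int | None


@dataclass
class SweepTrace:
    """Per-step record of an enrichment sweep."""

    steps: list[SweepStep]
    d: float | None
    q: float
    epsilon: float
    baseline_fva: FVAResult | None = None
    assignments: list[BoundAssignment] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": [s.index for s in self.steps],
                "reaction_id": [s.reaction_id for s in self.steps],
                "feasible": [s.feasible for s in self.steps],
                "growth_rate": [s.growth_rate for s in self.steps],
                "dormant": [s.dormant_count for s in self.steps],
                "n_more_variability": [s.n_more_variability for s in self.steps],
                "n_less_variability": [s.n_less_variability for s in self.steps],
            }
        )


@dataclass
class FVDistribution:
    """Cumulative distribution of FV(r) values across reactions."""

    thresholds: np.ndarray
    cumulative_fraction: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fraction": self.cumulative_fraction}
        )


def run_enrichment_sweep(
    model: ConstraintModel,
    ordered_assignments: Sequence[BoundAssignment],
    d: float | None = None,
    q: float = DEFAULT_Q,
    epsilon: float = DORMANCY_EPSILON,
    objective: "str | Mapping[str, float] | None" = None,
    variability_tol: float = 1e-6,
    stop_on_infeasible: bool = True,
) -> SweepTrace:
    """Apply kinetic bounds cumulatively and record trajectory metrics.

    The baseline for the variability comparison is the FVA of the original
    model at the same ``q``.  Infeasibility is data, not an exception: the
    step is recorded with ``feasible=False`` and — unless
    ``stop_on_infeasible=False`` — the sweep ends there.
    """
    baseline = run_fva(model, objective=objective, q=q)
    steps: list[SweepStep] = []
    current = model
    applied: list[BoundAssignment] = []
    for idx, assignment in enumerate(ordered_assignments):
        candidate = apply_bounds(current, [assignment])
        fba = run_fba(candidate, objective=objective)
        if not fba.optimal:
            steps.append(
                SweepStep(idx, assignment.reaction_id, False, None, None, None, None)
            )
            if stop_on_infeasible:
                break
            continue  # leave this bound out and keep sweeping
        current = candidate
        applied.append(assignment)
        fva = run_fva(current, objective=objective, q=q)
        n_more, n_less = compare_variability(baseline, fva, tol=variability_tol)
        steps.append(
            SweepStep(
                index=idx,
                reaction_id=assignment.reaction_id,
                feasible=True,
                growth_rate=fba.objective_value,
                dormant_count=count_dormant(fva, epsilon),
                n_more_variability=n_more,
                n_less_variability=n_less,
            )
        )
    return SweepTrace(
        steps=steps, d=d, q=q, epsilon=epsilon,
        baseline_fva=baseline, assignments=applied,
    )


def compare_variability(
    reference: FVAResult, current: FVAResult, tol: float = 1e-6
) -> tuple[int, int]:
    """Count reactions whose FV(r) increased / decreased beyond ``tol``."""
    if list(reference.reaction_ids) != list(current.reaction_ids):
        raise ValueError("FVA results cover different reaction sets")
    delta = current.fv - reference.fv
    n_more = int(np.sum(delta > tol))
    n_less = int(np.sum(-delta > tol))
    return n_more, n_less


def cumulative_fv_distribution(
    fva: FVAResult, thresholds: Sequence[float]
) -> FVDistribution:
    """Fraction of reactions with FV(r) ≤ t for each threshold t.

    Thresholds are sorted ascending in the output; the fractions are
    nondecreasing accordingly.
    """
    thr = np.sort(np.asarray(thresholds, dtype=float))
    fv = fva.fv
    n = len(fv)
    if n == 0:
        frac = np.full(thr.shape, np.nan)
    else:
        frac = np.array([np.sum(fv <= t) / n for t in thr])
    return FVDistribution(thresholds=thr, cumulative_fraction=frac)


def constrain_glucose_uptake(
    model: ConstraintModel,
    exchange_id: str,
    f_mm_per_s: float = DEFAULT_GLUCOSE_UPTAKE_MM_S,
    uptake_negative: bool = True,
    conversion_factor: float = CONVERSION_FACTOR,
) -> ConstraintModel:
    """Cap glucose uptake at the kinetic model's uptake value.

    With the conventional uptake-negative exchange (export positive), the
    lower bound is set to −c·f (−1.46556 at the defaults); for models whose
    uptake reaction is written inflow-positive the upper bound is set to
    +c·f instead.  Returns a modified copy.
    """
    out = model.copy()
    j = out.reaction_index(exchange_id)
    bound = conversion_factor * f_mm_per_s
    if uptake_negative:
        out.lower[j] = -bound
    else:
        out.upper[j] = bound
    out.validate()
    return out
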