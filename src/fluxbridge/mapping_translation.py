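"""Reaction mapping between model formalisms and flux-bound translation.

A curated mapping table pairs kinetic reactions with their constraint-model
counterparts; each pair falls into one of six categories:

* C0 — identical stoichiometry and orientation;
* C1 — differ only in the small species H⁺ / H₂O;
* C2 — differ only in CO₂ being used in place of HCO₃⁻ (acid hydrolysis);
* C3 — same equation, different reversibility flag;
* C4 — reactants and products swapped between the models;
* C5 — subnetworks of different structure, no one-to-one mapping.

A steady-state kinetic flux f(r) (mM s⁻¹) is converted to the constraint
model's mmol gDW⁻¹ h⁻¹ scale with the factor c = cell volume × 3600 = 6.372
and widened into an interval by a relative uncertainty d:

    C0–C3:  [c(1−d)·f,  c(1+d)·f]
    C4:     [−c(1+d)·f, −c(1−d)·f]      (orientation inverted)

Category C5 uses a net-boundary-flux surrogate, documented in
:func:`translate_c5_subnetwork`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .kinetic_engine import SteadyStateResult
from .model_io import ConstraintModel, KineticModel

__all__ = [
    "Category",
    "MappingEntry",
    "BoundAssignment",
    "CELL_VOLUME_L_PER_GDW",
    "CONVERSION_FACTOR",
    "classify_pair",
    "convert_flux_units",
    "kinetic_bounds",
    "translate_c5_subnetwork",
    "translate_mapping",
    "apply_bounds",
    "read_mapping_csv",
    "write_mapping_csv",
    "write_bounds_csv",
    "read_bounds_csv",
]

#: Cell volume per gram dry weight, L gDW⁻¹.
CELL_VOLUME_L_PER_GDW = 1.77e-3
#: mM s⁻¹ → mmol gDW⁻¹ h⁻¹: cell volume × 3600 s h⁻¹.
CONVERSION_FACTOR = CELL_VOLUME_L_PER_GDW * 3600.0  # = 6.372

#: Small species ignored for C1 matching: protons and water, by common id.
SMALL_SPECIES = frozenset(
    {"h", "h2o", "h_c", "h_p", "h_e", "h2o_c", "h2o_p", "h2o_e",
     "proton", "water", "hplus", "h+"}
)
#: Bicarbonate/CO₂ identification for C2, by common id stem.
_HCO3_STEMS = ("hco3", "bicarbonate")
_CO2_STEMS = ("co2",)


class Category(str, enum.Enum):
    """Mapping category of a kinetic↔constraint reaction pair."""

    C0 = "C0"  # identical
    C1 = "C1"  # differ in H+/H2O
    C2 = "C2"  # HCO3- vs CO2
    C3 = "C3"  # reversibility differs
    C4 = "C4"  # reversed orientation
    C5 = "C5"  # subnetwork — not mappable one-to-one

    def __str__(self) -> str:  # so CSVs read naturally
        return self.value


@dataclass(frozen=True)
class MappingEntry:
    """One curated correspondence between the two models' reactions."""

    kinetic_ids: tuple[str, ...]
    constraint_ids: tuple[str, ...]
    category: Category
    note: str = ""

    def __post_init__(self) -> None:
        if not self.kinetic_ids or not self.constraint_ids:
            raise ValueError("mapping entry needs ids on both sides")
        if self.category is not Category.C5 and (
            len(self.kinetic_ids) != 1 or len(self.constraint_ids) != 1
        ):
            raise ValueError(
                f"category {self.category} entries must be one-to-one"
            )


@dataclass(frozen=True)
class BoundAssignment:
    """A translated flux interval for one constraint-model reaction."""

    reaction_id: str
    lower: float
    upper: float
    source: str = "kinetic"  # "kinetic" or "original"
    d: float | None = None
    f: float | None = None  # kinetic flux used, mM s⁻¹

    def __post_init__(self) -> None:
        if self.lower > self.upper + 1e-12:
            raise ValueError(
                f"assignment for {self.reaction_id!r} has L > U "
                f"({self.lower} > {self.upper})"
            )


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------


def _is_small(met_id: str) -> bool:
    return met_id.lower() in SMALL_SPECIES


def _carbon_token(met_id: str) -> str:
    """Collapse HCO3-/CO2 id variants onto a shared token for C2 matching."""
    lowered = met_id.lower()
    stem = lowered.rsplit("_", 1)[0] if "_" in lowered else lowered
    if stem in _HCO3_STEMS or stem in _CO2_STEMS:
        return "co2~" + (lowered.rsplit("_", 1)[1] if "_" in lowered else "")
    return met_id


def _normalise(
    stoich: Mapping[str, float], drop_small: bool, merge_carbon: bool
) -> dict[str, float]:
    out: dict[str, float] = {}
    for met, coeff in stoich.items():
        if coeff == 0:
            continue
        if drop_small and _is_small(met):
            continue
        key = _carbon_token(met) if merge_carbon else met
        out[key] = out.get(key, 0.0) + coeff
    return {k: v for k, v in out.items() if v != 0}


def _same(a: Mapping[str, float], b: Mapping[str, float]) -> bool:
    return dict(a) == dict(b)


def _negated(stoich: Mapping[str, float]) -> dict[str, float]:
    return {k: -v for k, v in stoich.items()}


def classify_pair(
    kin_stoich: Mapping[str, float],
    kin_reversible: bool,
    cbm_stoich: Mapping[str, float],
    cbm_reversible: bool,
) -> Category:
    """Classify one kinetic/constraint reaction pair into C0–C5.

    Stoichiometries are signed maps (reactants negative, products positive);
    metabolite ids are compared verbatim apart from the C1 small-species and
    C2 bicarbonate/CO₂ allowances.  An unmappable pair returns ``C5``
    (candidate subnetwork), never an exception.
    """
    if not kin_stoich or not cbm_stoich:
        raise ValueError("stoichiometries must be nonempty")
    same_rev = kin_reversible == cbm_reversible
    if _same(kin_stoich, cbm_stoich) and same_rev:
        return Category.C0
    kin_c1 = _normalise(kin_stoich, drop_small=True, merge_carbon=False)
    cbm_c1 = _normalise(cbm_stoich, drop_small=True, merge_carbon=False)
    if _same(kin_c1, cbm_c1) and same_rev:
        return Category.C1
    kin_c2 = _normalise(kin_stoich, drop_small=True, merge_carbon=True)
    cbm_c2 = _normalise(cbm_stoich, drop_small=True, merge_carbon=True)
    if _same(kin_c2, cbm_c2):
        return Category.C2 if same_rev else Category.C3
    if _same(kin_c2, _negated(cbm_c2)):
        return Category.C4
    return Category.C5


# --------------------------------------------------------------------------
# Unit conversion and bound translation
# --------------------------------------------------------------------------


def convert_flux_units(
    f_mm_per_s: float, cell_volume_l_per_gdw: float = CELL_VOLUME_L_PER_GDW
) -> float:
    """Convert a kinetic flux from mM s⁻¹ to mmol gDW⁻¹ h⁻¹.

    f · (cell volume, L gDW⁻¹) · (3600 s h⁻¹); at the default cell volume of
    1.77·10⁻³ L gDW⁻¹ the factor is 6.372.
    """
    if cell_volume_l_per_gdw <= 0:
        raise ValueError("cell volume must be positive")
    return f_mm_per_s * cell_volume_l_per_gdw * 3600.0


def kinetic_bounds(
    reaction_id: str,
    f: float,
    d: float,
    category: Category = Category.C0,
    conversion_factor: float = CONVERSION_FACTOR,
) -> BoundAssignment:
    """Translate a kinetic steady-state flux into a constraint-model interval.

    For categories C0–C3 the interval is [c(1−d)f, c(1+d)f]; for C4
    (orientation inverted between models) it is [−c(1+d)f, −c(1−d)f].  All
    kinetic fluxes are taken positive by convention, and d must lie in
    [0, 1) so the interval keeps a well-defined sign.
    """
    if f < 0:
        raise ValueError(
            f"kinetic flux for {reaction_id!r} is negative ({f}); kinetic "
            "fluxes are positive by convention — use category C4 for "
            "reactions whose orientation is inverted"
        )
    if not 0 <= d < 1:
        raise ValueError(f"uncertainty d must be in [0, 1), got {d}")
    if category is Category.C5:
        raise ValueError("C5 entries are translated by translate_c5_subnetwork")
    cf = conversion_factor * f
    if category is Category.C4:
        lower, upper = -(1 + d) * cf, -(1 - d) * cf
    else:
        lower, upper = (1 - d) * cf, (1 + d) * cf
    return BoundAssignment(
        reaction_id=reaction_id, lower=lower, upper=upper,
        source="kinetic", d=d, f=f,
    )


def _fluxes_of(fluxes: "SteadyStateResult | Mapping[str, float]") -> Mapping[str, float]:
    if isinstance(fluxes, SteadyStateResult):
        return fluxes.fluxes
    return fluxes


def translate_c5_subnetwork(
    entry: MappingEntry,
    fluxes: "SteadyStateResult | Mapping[str, float]",
    kinetic_model: KineticModel,
    constraint_model: ConstraintModel,
    d: float,
    conversion_factor: float = CONVERSION_FACTOR,
    tol: float = 1e-9,
) -> list[BoundAssignment]:
    """Surrogate bound translation for C5 (subnetwork) entries.

    The kinetic-side subnetwork and the constraint-side reactions share
    boundary metabolites; at steady state the net kinetic production or
    consumption across each shared metabolite equals the flux the
    constraint-side reaction must carry.  That net flux (scaled by the
    constraint reaction's own stoichiometric coefficient) is pushed through
    the standard interval formula; a net flux opposed to the constraint
    reaction's orientation is routed through the reversed-orientation (C4)
    formula.

    This is a stand-in net-flux rule for mapping structurally different
    subnetworks; it requires at least one metabolite shared between the two
    sides and errors out otherwise.
    """
    if entry.category is not Category.C5:
        raise ValueError("entry is not category C5")
    fmap = _fluxes_of(fluxes)
    kin_rxns = [kinetic_model.get_reaction(rid) for rid in entry.kinetic_ids]
    kin_species = set()
    for rxn in kin_rxns:
        kin_species.update(rxn.stoichiometry)

    assignments: list[BoundAssignment] = []
    for cbm_id in entry.constraint_ids:
        cbm_stoich = constraint_model.stoichiometry_of(cbm_id)
        shared = [m for m in cbm_stoich if m in kin_species]
        if not shared:
            raise ValueError(
                f"C5 entry {entry.kinetic_ids} -> {cbm_id!r} shares no "
                "boundary metabolite between the kinetic and constraint sides"
            )
        # net kinetic production of each shared metabolite, in units of the
        # constraint reaction's flux (divide by its stoichiometric coefficient)
        implied = []
        for met in shared:
            net = sum(
                rxn.stoichiometry.get(met, 0.0) * fmap[rxn.id] for rxn in kin_rxns
            )
            implied.append(net / cbm_stoich[met])
        net_flux = sum(implied) / len(implied)
        if abs(net_flux) <= tol:
            assignments.append(
                BoundAssignment(cbm_id, 0.0, 0.0, source="kinetic", d=d, f=0.0)
            )
        elif net_flux > 0:
            assignments.append(
                kinetic_bounds(cbm_id, net_flux, d, Category.C0, conversion_factor)
            )
        else:
            assignments.append(
                kinetic_bounds(cbm_id, -net_flux, d, Category.C4, conversion_factor)
            )
    return assignments


def translate_mapping(
    entries: Sequence[MappingEntry],
    fluxes: "SteadyStateResult | Mapping[str, float]",
    d: float,
    kinetic_model: KineticModel | None = None,
    constraint_model: ConstraintModel | None = None,
    conversion_factor: float = CONVERSION_FACTOR,
    include_c5: bool = True,
) -> list[BoundAssignment]:
    """Translate a whole mapping table into bound assignments.

    One-to-one entries (C0–C4) need only the flux map; C5 entries need both
    models for the subnetwork surrogate and are skipped when
    ``include_c5=False`` or when the models are not supplied.
    """
    fmap = _fluxes_of(fluxes)
    out: list[BoundAssignment] = []
    for entry in entries:
        if entry.category is Category.C5:
            if not include_c5:
                continue
            if kinetic_model is None or constraint_model is None:
                raise ValueError(
                    "C5 entries require kinetic_model and constraint_model"
                )
            out.extend(
                translate_c5_subnetwork(
                    entry, fmap, kinetic_model, constraint_model, d,
                    conversion_factor,
                )
            )
        else:
            (kin_id,) = entry.kinetic_ids
            (cbm_id,) = entry.constraint_ids
            out.append(
                kinetic_bounds(
                    cbm_id, fmap[kin_id], d, entry.category, conversion_factor
                )
            )
    return out


def apply_bounds(
    model: ConstraintModel, assignments: Iterable[BoundAssignment]
) -> ConstraintModel:
    """Return a copy of ``model`` with the assignments' bounds substituted.

    Translated bounds replace the original ones outright (they are normally
    far tighter than ±1000 defaults).  Unknown reaction ids and inverted
    intervals raise; the input model is never mutated.
    """
    out = model.copy()
    for a in assignments:
        j = out.reaction_index(a.reaction_id)
        if a.lower > a.upper:
            raise ValueError(
                f"assignment for {a.reaction_id!r} has L > U"
            )
        out.lower[j] = a.lower
        out.upper[j] = a.upper
    out.validate()
    return out


# --------------------------------------------------------------------------
# CSV interfaces
# --------------------------------------------------------------------------


def read_mapping_csv(path: str) -> list[MappingEntry]:
    """Read a mapping table: kinetic_ids;-separated, cbm_ids, category, note."""
    df = pd.read_csv(path, dtype=str).fillna("")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            MappingEntry(
                kinetic_ids=tuple(x for x in row["kinetic_ids"].split(";") if x),
                constraint_ids=tuple(x for x in row["cbm_ids"].split(";") if x),
                category=Category(row["category"].strip()),
                note=row.get("note", ""),
            )
        )
    return entries


def write_mapping_csv(entries: Sequence[MappingEntry], path: str) -> None:
    pd.DataFrame(
        {
            "kinetic_ids": [";".join(e.kinetic_ids) for e in entries],
            "cbm_ids": [";".join(e.constraint_ids) for e in entries],
            "category": [e.category.value for e in entries],
            "note": [e.note for e in entries],
        }
    ).to_csv(path, index=False)


def write_bounds_csv(assignments: Sequence[BoundAssignment], path: str) -> None:
    pd.DataFrame(
        {
            "reaction_id": [a.reaction_id for a in assignments],
            "L": [a.lower for a in assignments],
            "U": [a.upper for a in assignments],
            "source": [a.source for a in assignments],
            "d": [a.d for a in assignments],
            "f": [a.f for a in assignments],
        }
    ).to_csv(path, index=False)


def read_bounds_csv(path: str) -> list[BoundAssignment]:
    df = pd.read_csv(path)
    return [
        BoundAssignment(
            reaction_id=row.reaction_id,
            lower=float(row.L),
            upper=float(row.U),
            source=str(row.source),
            d=None if pd.isna(row.d) else float(row.d),
            f=None if pd.isna(row.f) else float(row.f),
        )
        for row in df.itertuples()
    ]
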