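"""Category classification, unit conversion, and bound translation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fluxbridge import (
    BoundAssignment,
    Category,
    MappingEntry,
    apply_bounds,
    classify_pair,
    convert_flux_units,
    kinetic_bounds,
    read_mapping_csv,
    run_fba,
    translate_c5_subnetwork,
    translate_mapping,
    write_mapping_csv,
)
from fluxbridge.mapping_translation import (
    CONVERSION_FACTOR,
    read_bounds_csv,
    write_bounds_csv,
)


def _pair(zoo, category):
    kinetic, constraint, mapping = zoo
    entry = next(e for e in mapping if e.category is category)
    kin = kinetic.get_reaction(entry.kinetic_ids[0])
    cbm_id = entry.constraint_ids[0]
    return (
        kin.stoichiometry,
        kin.reversible,
        constraint.stoichiometry_of(cbm_id),
        constraint.is_reversible(cbm_id),
    )


@pytest.mark.parametrize(
    "category", [Category.C0, Category.C1, Category.C2, Category.C3,
                 Category.C4, Category.C5]
)
def test_classification_of_exemplar_pairs(zoo, category):
    """Each curated exemplar pair classifies into its labelled category."""
    assert classify_pair(*_pair(zoo, category)) is category


def test_classification_symmetries(zoo):
    """Identical pairs stay C0 under swap; reversed pairs stay C4."""
    k_st, k_rev, c_st, c_rev = _pair(zoo, Category.C0)
    assert classify_pair(c_st, c_rev, k_st, k_rev) is Category.C0
    k_st, k_rev, c_st, c_rev = _pair(zoo, Category.C4)
    assert classify_pair(c_st, c_rev, k_st, k_rev) is Category.C4


def test_classify_rejects_empty_stoichiometry():
    with pytest.raises(ValueError):
        classify_pair({}, False, {"a": -1.0}, False)


@pytest.mark.parametrize(
    "f,expected",
    [(1.0, 6.372), (0.0, 0.0), (0.23, 1.46556)],
)
def test_flux_unit_conversion(f, expected):
    """mM/s x cell volume x 3600 s/h; the factor is 6.372 at 1.77e-3 L/gDW."""
    assert convert_flux_units(f) == pytest.approx(expected, abs=1e-12)


def test_forward_bounds_use_one_minus_d_factor():
    a = kinetic_bounds("r", f=1.0, d=0.1, category=Category.C0)
    assert a.lower == pytest.approx(0.9 * 6.372)
    assert a.upper == pytest.approx(1.1 * 6.372)


def test_reversed_category_flips_and_orders_the_interval():
    a = kinetic_bounds("r", f=1.0, d=0.1, category=Category.C4)
    assert a.lower == pytest.approx(-7.0092)
    assert a.upper == pytest.approx(-5.7348)
    assert a.lower <= a.upper


def test_zero_flux_pins_to_zero():
    a = kinetic_bounds("r", f=0.0, d=0.5)
    assert (a.lower, a.upper) == (0.0, 0.0)


def test_bound_translation_contract_errors():
    with pytest.raises(ValueError, match="negative"):
        kinetic_bounds("r", f=-1.0, d=0.1)
    with pytest.raises(ValueError, match="d must"):
        kinetic_bounds("r", f=1.0, d=1.0)
    with pytest.raises(ValueError, match="C5"):
        kinetic_bounds("r", f=1.0, d=0.1, category=Category.C5)


@given(
    f=st.floats(min_value=0, max_value=100),
    d1=st.floats(min_value=0, max_value=0.99),
    d2=st.floats(min_value=0, max_value=0.99),
    category=st.sampled_from([Category.C0, Category.C4]),
)
def test_intervals_nest_and_centre_on_the_converted_flux(f, d1, d2, category):
    """Smaller uncertainty gives a nested interval; the midpoint is +-c*f."""
    lo, hi = sorted((d1, d2))
    inner = kinetic_bounds("r", f, lo, category)
    outer = kinetic_bounds("r", f, hi, category)
    assert outer.lower <= inner.lower + 1e-12
    assert inner.upper <= outer.upper + 1e-12
    mid = (inner.lower + inner.upper) / 2
    sign = -1.0 if category is Category.C4 else 1.0
    assert mid == pytest.approx(sign * CONVERSION_FACTOR * f, abs=1e-9)


def test_c5_chain_surrogate_uses_net_boundary_flux(zoo):
    """A -> B -> C at flux 2 lumped into A -> C translates to the 2c interval."""
    kinetic, constraint, mapping = zoo
    entry = next(e for e in mapping if e.category is Category.C5)
    fluxes = {"C5_STEP1": 2.0, "C5_STEP2": 2.0}
    (a,) = translate_c5_subnetwork(entry, fluxes, kinetic, constraint, d=0.1)
    assert a.reaction_id == "C5_LUMP"
    assert a.lower == pytest.approx(2 * CONVERSION_FACTOR * 0.9)
    assert a.upper == pytest.approx(2 * CONVERSION_FACTOR * 1.1)


def test_c5_zero_net_flux_pins_to_zero(zoo):
    kinetic, constraint, mapping = zoo
    entry = next(e for e in mapping if e.category is Category.C5)
    (a,) = translate_c5_subnetwork(
        entry, {"C5_STEP1": 0.0, "C5_STEP2": 0.0}, kinetic, constraint, d=0.3
    )
    assert (a.lower, a.upper) == (0.0, 0.0)


def test_c5_disconnected_subnetwork_is_an_error(zoo):
    kinetic, constraint, _ = zoo
    entry = MappingEntry(
        ("C5_STEP1", "C5_STEP2"), ("Z0_cbm",), Category.C5
    )  # Z0_cbm shares no metabolite with the chain
    with pytest.raises(ValueError, match="shares no"):
        translate_c5_subnetwork(
            entry, {"C5_STEP1": 1.0, "C5_STEP2": 1.0}, kinetic, constraint, d=0.1
        )


def test_apply_bounds_empty_list_is_identity(branch):
    _, model, _ = branch
    out = apply_bounds(model, [])
    np.testing.assert_array_equal(out.lower, model.lower)
    np.testing.assert_array_equal(out.upper, model.upper)


def test_apply_bounds_does_not_mutate_the_input(branch):
    _, model, _ = branch
    before = model.upper.copy()
    apply_bounds(model, [BoundAssignment("EX_glc", 0.0, 1.0)])
    np.testing.assert_array_equal(model.upper, before)


def test_apply_bounds_unknown_reaction_errors(branch):
    _, model, _ = branch
    with pytest.raises(KeyError):
        apply_bounds(model, [BoundAssignment("GHOST", 0.0, 1.0)])


def test_pinned_glucose_forces_the_fba_uptake(branch):
    """L = U on the glucose exchange pins its FBA flux exactly."""
    _, model, _ = branch
    pinned = apply_bounds(
        model, [BoundAssignment("EX_glc", 1.46556, 1.46556)]
    )
    result = run_fba(pinned)
    assert result.optimal
    assert result.fluxes["EX_glc"] == pytest.approx(1.46556)


def test_translate_mapping_covers_all_one_to_one_entries(branch, branch_steady):
    _, model, mapping = branch
    assignments = translate_mapping(mapping, branch_steady, d=0.1)
    assert {a.reaction_id for a in assignments} == {
        e.constraint_ids[0] for e in mapping
    }
    assert all(a.source == "kinetic" for a in assignments)


def test_mapping_and_bounds_csv_round_trips(zoo, tmp_path):
    _, _, mapping = zoo
    map_path = tmp_path / "mapping.csv"
    write_mapping_csv(mapping, map_path)
    assert read_mapping_csv(map_path) == mapping

    assignments = [
        kinetic_bounds("rA", 1.5, 0.1),
        kinetic_bounds("rB", 0.2, 0.3, Category.C4),
    ]
    bounds_path = tmp_path / "bounds.csv"
    write_bounds_csv(assignments, bounds_path)
    back = read_bounds_csv(bounds_path)
    assert [a.reaction_id for a in back] == ["rA", "rB"]
    assert back[0].lower == pytest.approx(assignments[0].lower)
    assert back[1].upper == pytest.approx(assignments[1].upper)


def test_translated_bounds_are_tighter_than_loose_defaults():
    """Any interval with c(1+d)f < 1000 is narrower than a +-1000 default."""
    a = kinetic_bounds("r", f=10.0, d=0.5)
    assert a.upper - a.lower < 2000.0
    assert -1000.0 < a.lower and a.upper < 1000.0
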