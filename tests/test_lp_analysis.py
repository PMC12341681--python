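"""FBA/FVA correctness against brute-force and COBRApy oracles; dormancy."""

import numpy as np
import pytest

from fluxbridge import (
    BoundAssignment,
    ConstraintModel,
    apply_bounds,
    count_dormant,
    is_dormant,
    run_fba,
    run_fva,
)
from lp_oracle import brute_force_fba, brute_force_fva


def _two_reaction_chain(cap=10.0):
    return ConstraintModel(
        reaction_ids=["IN", "OUT"],
        metabolite_ids=["A_c"],
        S=np.array([[1.0, -1.0]]),
        lower=np.zeros(2),
        upper=np.array([cap, 1000.0]),
        objective=np.array([0.0, 1.0]),
    )


def test_fba_single_bottleneck_sets_the_optimum():
    """Mass balance forces the objective through the capped inflow."""
    result = run_fba(_two_reaction_chain(cap=10.0))
    assert result.optimal
    assert result.objective_value == pytest.approx(10.0)


def test_fba_routes_everything_to_the_objective_branch(branch):
    """Maximising biomass starves the product branch completely."""
    _, model, _ = branch
    result = run_fba(model)
    assert result.optimal
    assert result.fluxes["EX_glc"] == pytest.approx(10.0)
    assert result.fluxes["PRODUCT"] == pytest.approx(0.0, abs=1e-9)
    # biomass precursor demand scales uptake into growth units
    assert result.objective_value == pytest.approx(10.0 / 6.372)


def test_fba_without_carbon_gives_zero_growth(branch):
    _, model, _ = branch
    starved = apply_bounds(model, [BoundAssignment("EX_glc", 0.0, 0.0)])
    result = run_fba(starved)
    assert result.optimal
    assert result.objective_value == pytest.approx(0.0, abs=1e-9)


def test_fba_reports_infeasibility_not_zeros(branch):
    _, model, _ = branch
    impossible = apply_bounds(
        model,
        [BoundAssignment("EX_glc", 0.0, 0.0), BoundAssignment("BIOMASS", 1.0, 2.0)],
    )
    result = run_fba(impossible)
    assert result.status == "infeasible"
    assert result.fluxes is None and result.objective_value is None


def test_fva_pinned_reaction_has_zero_variability(branch):
    _, model, _ = branch
    pinned = apply_bounds(model, [BoundAssignment("EX_glc", 5.0, 5.0)])
    fva = run_fva(pinned, q=0.999)
    j = fva.reaction_ids.index("EX_glc")
    assert fva.min_flux[j] == pytest.approx(5.0)
    assert fva.max_flux[j] == pytest.approx(5.0)
    assert fva.fv[j] == pytest.approx(0.0, abs=1e-9)


def test_fva_at_full_optimum_blocks_the_product_branch(branch):
    """At q = 1 any product flux would cut biomass below the optimum."""
    _, model, _ = branch
    fva = run_fva(model, q=1.0)
    j = fva.reaction_ids.index("PRODUCT")
    assert fva.min_flux[j] == pytest.approx(0.0, abs=1e-8)
    assert fva.max_flux[j] == pytest.approx(0.0, abs=1e-8)


def test_fva_slack_frees_exactly_the_optimum_fraction(branch):
    """At q = 0.999 the product branch may carry (1-q) of the uptake cap."""
    _, model, _ = branch
    fva = run_fva(model, q=0.999)
    j = fva.reaction_ids.index("PRODUCT")
    assert fva.max_flux[j] == pytest.approx(0.001 * 10.0, rel=1e-6)


@pytest.mark.parametrize(
    "lo,hi,expected",
    [(0.005, 0.009, True), (-0.5, 0.2, False), (0.01, 0.01, True),
     (-0.010000001, 0.0, False)],
)
def test_dormancy_thresholding_is_inclusive(lo, hi, expected):
    assert is_dormant(lo, hi, epsilon=1e-2) is expected


def test_dormant_counts_on_fixtures(chain, branch):
    _, chain_model, _ = chain
    fva = run_fva(chain_model, q=1.0)
    frame = fva.to_frame()
    dead = frame[frame.reaction_id.isin(["DEAD1", "DEAD2"])]
    assert dead.dormant.all()
    # chain reactions all carry the full optimum flux: only dead-ends dormant
    assert count_dormant(fva) == 2

    _, branch_model, _ = branch
    assert count_dormant(run_fva(branch_model, q=1.0)) == 3  # product path + H+


def test_count_dormant_ignores_active_reactions(branch):
    _, model, _ = branch
    pinned = apply_bounds(
        model,
        [BoundAssignment(r, 5.0, 5.0) for r in ("EX_glc", "BIO_PATH")],
    )
    fva = run_fva(pinned, q=0.999)
    ids = fva.reaction_ids
    assert not is_dormant(
        fva.min_flux[ids.index("EX_glc")], fva.max_flux[ids.index("EX_glc")]
    )


@pytest.mark.parametrize("fixture_name", ["chain", "branch"])
def test_fba_matches_vertex_enumeration(fixture_name, chain, branch):
    """LP optimum equals the best vertex of the flux polytope."""
    _, model, _ = {"chain": chain, "branch": branch}[fixture_name]
    result = run_fba(model)
    oracle = brute_force_fba(model, model.objective)
    assert result.objective_value == pytest.approx(oracle, rel=1e-8, abs=1e-8)


@pytest.mark.parametrize("q", [1.0, 0.999, 0.9])
def test_fva_matches_vertex_enumeration(branch, q):
    _, model, _ = branch
    fva = run_fva(model, q=q)
    mu = run_fba(model).objective_value
    lo, hi = brute_force_fva(model, model.objective, q, mu)
    np.testing.assert_allclose(fva.min_flux, lo, rtol=1e-8, atol=1e-7)
    np.testing.assert_allclose(fva.max_flux, hi, rtol=1e-8, atol=1e-7)


def test_fva_agrees_with_cobrapy(branch):
    """Independent solver route: COBRApy/GLPK versus scipy/HiGHS."""
    from cobra.flux_analysis import flux_variability_analysis

    _, model, _ = branch
    cobra_model = model.to_cobra()
    ref = flux_variability_analysis(
        cobra_model, fraction_of_optimum=0.999, processes=1
    )
    fva = run_fva(model, q=0.999)
    for k, rid in enumerate(fva.reaction_ids):
        assert fva.min_flux[k] == pytest.approx(
            ref.loc[rid, "minimum"], abs=1e-6
        )
        assert fva.max_flux[k] == pytest.approx(
            ref.loc[rid, "maximum"], abs=1e-6
        )


def test_fva_sandwich_around_the_optimal_flux_vector(branch):
    """L <= minF <= v* <= maxF <= U for any optimal vector at q = 1."""
    _, model, _ = branch
    fba = run_fba(model)
    fva = run_fva(model, q=1.0)
    v = fba.fluxes.to_numpy()
    tol = 1e-6
    assert np.all(model.lower - tol <= fva.min_flux)
    assert np.all(fva.min_flux <= v + tol)
    assert np.all(v - tol <= fva.max_flux)
    assert np.all(fva.max_flux <= model.upper + tol)


def test_variability_shrinks_as_q_rises(branch):
    _, model, _ = branch
    fvs = [run_fva(model, q=q).fv for q in (0.9, 0.99, 0.999, 1.0)]
    for looser, tighter in zip(fvs, fvs[1:]):
        assert np.all(tighter <= looser + 1e-7)


def test_fva_requires_a_feasible_base_model(branch):
    from fluxbridge.lp_analysis import LPError

    _, model, _ = branch
    impossible = apply_bounds(
        model,
        [BoundAssignment("EX_glc", 0.0, 0.0), BoundAssignment("BIOMASS", 1.0, 2.0)],
    )
    with pytest.raises(LPError, match="infeasible"):
        run_fva(impossible)
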