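"""Rate laws, mass balance, simulation and steady states."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metsim.model import (
    DIET_HFD,
    DIET_HFDC,
    DIET_LFD,
    DietInput,
    MetabolicState,
    Model,
    NegativePoolError,
    ObservationMap,
    PARAM_NAMES,
    ParameterSet,
    SimOptions,
    default_parameters,
    dietary_inflow,
    reference_state,
)
from metsim.network import POOLS, SPECIES_CLASSES, build_flux_table

from conftest import random_params, random_positive_state


# ----------------------------------------------------------------------
# dietary inflows

def test_zero_intake_gives_zero_inflows():
    diet = DietInput(0.0, 5.2, 0.6, 0.2, 0.0025)
    assert dietary_inflow(diet) == {"carb": 0.0, "fat": 0.0, "chol": 0.0}


def test_cholesterol_inflow_hand_arithmetic():
    # 2.5 g/day * 0.25% w/w / 386.65 g/mol -> 16.16 umol/day
    diet = DietInput(2.5, 5.2, 0.6, 0.2, 0.0025)
    assert dietary_inflow(diet)["chol"] == pytest.approx(
        2.5 * 0.0025 / 386.65 * 1e6, rel=1e-12)
    assert dietary_inflow(diet)["chol"] == pytest.approx(16.16, abs=0.01)


def test_fat_inflow_hand_arithmetic():
    # 2.5 g/day * 5.2 kcal/g * 60% / 9 kcal/g / 885.4 g/mol
    diet = DietInput(2.5, 5.2, 0.6, 0.2, 0.0025)
    assert dietary_inflow(diet)["fat"] == pytest.approx(979.0, abs=1.0)


def test_negative_intake_rejected():
    with pytest.raises(ValueError, match="food_intake"):
        DietInput(-1.0, 5.2, 0.6, 0.2, 0.0)


def test_energy_fractions_must_sum_below_one():
    with pytest.raises(ValueError, match="exceed 1"):
        DietInput(2.0, 5.0, 0.7, 0.5, 0.0)


# ----------------------------------------------------------------------
# flux evaluation against an independent per-flux oracle

def _oracle_fluxes(model, x, theta, diet):
    """Independent re-implementation: every rate law written out
    separately from a dictionary state, no vectorization."""
    s = {p: max(float(v), 0.0) for p, v in zip(POOLS, x)}
    th = {n: float(v) for n, v in zip(PARAM_NAMES, theta)}
    inflow = dietary_inflow(diet)
    ihat = s["pI"] / model.insulin_ref
    up_dnl = 1.0 + th["a_dnl"] * ihat
    up_upt = 1.0 + th["a_uptake"] * ihat
    dn_lip = 1.0 / (1.0 + th["a_lipolysis"] * ihat)
    dn_gng = 1.0 / (1.0 + th["a_gng"] * ihat)
    first_order = {
        "glc_absorption": "lG", "tg_absorption": "lTG",
        "chol_absorption": "lFC", "fecal_chol": "lFC", "fecal_ba": "lBA",
        "tice": "pCv", "biliary_chol": "hFC", "biliary_ba": "hBA",
        "ba_reuptake": "lBA", "ba_synthesis": "hFC",
        "hep_glc_uptake": "pG", "hep_glc_output": "hG6P",
        "glycolysis": "hG6P", "hep_beta_ox": "hTG",
        "chol_synthesis": "hACoA", "acat": "hFC", "ceh": "hCE",
        "hep_fa_uptake": "pFFA", "vldl_tg_secretion": "hTG",
        "vldl_c_secretion": "hFC", "lpl_vldl": "pTGv",
        "lpl_chylo": "pTGc", "remnant_uptake": "pTGc",
        "vldl_tg_uptake": "pTGv", "ldl_c_uptake": "pCv", "cetp": "pCh",
        "hdl_production": "hFC", "hdl_uptake": "pCh",
        "per_ffa_uptake": "pFFA", "per_beta_ox": "aTG",
        "acoa_ox_hep": "hACoA", "acoa_ox_per": "aACoA",
        "ins_clearance": "pI",
    }
    v = {name: th[f"k_{name}"] * s[sub]
         for name, sub in first_order.items()}
    v["dnl"] = th["k_dnl"] * s["hACoA"] * up_dnl
    v["per_glc_uptake"] = th["k_per_glc_uptake"] * s["pG"] * up_upt
    v["per_lipolysis"] = th["k_per_lipolysis"] * s["aTG"] * dn_lip
    v["gng"] = th["k_gng"] * dn_gng
    v["diet_carb"] = inflow["carb"]
    v["diet_fat"] = inflow["fat"]
    v["diet_chol"] = inflow["chol"]
    pG = s["pG"]
    h = th["i_hill"]
    v["ins_secretion"] = th["i_vmax"] * pG**h / (th["i_kg"]**h + pG**h)
    return v


def test_first_order_flux_is_k_times_pool(model, theta):
    x = reference_state()
    params = theta.replace(k_cetp=1.0)
    fluxes = model.fluxes_dict(x, params)
    assert fluxes["cetp"] == pytest.approx(x["pCh"], rel=1e-12)


def test_flux_vector_matches_per_flux_oracle(model, rng):
    for _ in range(100):
        x = random_positive_state(rng)
        theta = random_params(rng)
        got = dict(zip(model.flux_names,
                       model.compute_fluxes(x, ParameterSet(theta))))
        want = _oracle_fluxes(model, x, theta, model.diet)
        assert set(got) == set(want)
        for name in want:
            assert got[name] == pytest.approx(want[name], rel=1e-12), name


def test_negative_pool_raises_with_pool_name(model, theta):
    x = reference_state().values.copy()
    x[POOLS.index("pFFA")] = -0.5
    with pytest.raises(NegativePoolError, match="pFFA"):
        model.compute_fluxes(x, theta)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10**6))
def test_fluxes_are_nonnegative_for_any_nonnegative_state(seed):
    model = Model()
    r = np.random.default_rng(seed)
    x = random_positive_state(r, scale=2.0)
    x[r.integers(0, len(x), size=3)] = 0.0  # some empty pools
    theta = random_params(r, scale=1.0)
    v = model.compute_fluxes(x, ParameterSet(theta))
    assert np.all(v >= 0)


# ----------------------------------------------------------------------
# derivatives: class-wise mass balance

def _class_sum(dx, class_name):
    weights = SPECIES_CLASSES[class_name]
    return sum(dx[POOLS.index(p)] * w for p, w in weights.items())


def test_cholesterol_class_balance_identity(model, rng):
    """d(all cholesterol pools + sinks)/dt equals dietary inflow plus
    1/18 of the acetyl-CoA drained into cholesterol synthesis."""
    for _ in range(20):
        x = random_positive_state(rng)
        theta = ParameterSet(random_params(rng))
        dx = model.derivatives(x, theta)
        v = dict(zip(model.flux_names, model.compute_fluxes(x, theta)))
        inflow = dietary_inflow(model.diet)["chol"]
        expected = inflow + v["chol_synthesis"] / 18.0
        assert _class_sum(dx, "cholesterol") == pytest.approx(
            expected, rel=1e-10)


def test_all_class_balances_close(model, rng):
    x = random_positive_state(rng)
    theta = ParameterSet(random_params(rng))
    dx = model.derivatives(x, theta)
    v = dict(zip(model.flux_names, model.compute_fluxes(x, theta)))
    inflow = dietary_inflow(model.diet)
    assert _class_sum(dx, "glucose") == pytest.approx(
        inflow["carb"] + v["gng"] - v["glycolysis"] - v["per_glc_uptake"],
        rel=1e-10)
    assert _class_sum(dx, "tg") == pytest.approx(
        inflow["fat"] + v["dnl"] / 24.0 - v["hep_beta_ox"]
        - v["per_beta_ox"], rel=1e-10)
    assert _class_sum(dx, "acoa") == pytest.approx(
        2.0 * (v["glycolysis"] + v["per_glc_uptake"])
        + 24.0 * (v["hep_beta_ox"] + v["per_beta_ox"])
        - v["dnl"] - v["chol_synthesis"], rel=1e-10)
    assert _class_sum(dx, "insulin") == pytest.approx(
        v["ins_secretion"] - v["ins_clearance"], rel=1e-10)


def test_derivatives_match_flux_summing_oracle(model, rng):
    """dx/dt equals an independent loop over fluxes applying signed
    stoichiometry, and the analytic Jacobian matches finite differences
    of that oracle."""
    table = build_flux_table()
    x = random_positive_state(rng)
    theta = random_params(rng)
    params = ParameterSet(theta)
    v = _oracle_fluxes(model, x, theta, model.diet)
    dx_oracle = np.zeros(len(POOLS))
    for f in table:
        for pool, coef in f.stoich.items():
            dx_oracle[POOLS.index(pool)] += coef * v[f.name]
    np.testing.assert_allclose(model.derivatives(x, params), dx_oracle,
                               rtol=1e-10)
    # finite differences of the oracle vs the analytic Jacobian
    J = model._jac_raw(x, theta)
    for i in [0, 5, 9, 13, 17]:
        eps = 1e-7 * max(1.0, abs(x[i]))
        xp = x.copy()
        xp[i] += eps
        vp = _oracle_fluxes(model, xp, theta, model.diet)
        dxp = np.zeros(len(POOLS))
        for f in table:
            for pool, coef in f.stoich.items():
                dxp[POOLS.index(pool)] += coef * vp[f.name]
        fd = (dxp - dx_oracle) / eps
        np.testing.assert_allclose(J[:, i], fd, rtol=1e-4, atol=1e-6)


# ----------------------------------------------------------------------
# simulation

def test_simulation_from_steady_state_is_constant(model, theta, steady):
    sim = model.simulate(steady, theta, (0.0, 30.0))
    nonsink = [POOLS.index(p) for p in POOLS if p not in
               ("fecC", "fecBA", "oxC")]
    drift = np.abs(sim.states[-1, nonsink] - sim.states[0, nonsink])
    assert np.all(drift <= 1e-3 * (1.0 + np.abs(sim.states[0, nonsink])))


def test_simulation_semigroup_property(model, rng):
    theta = ParameterSet(random_params(rng, scale=0.2))
    x0 = random_positive_state(rng, scale=0.3)
    full = model.simulate(x0, theta, (0.0, 20.0),
                          t_eval=np.array([0.0, 10.0, 20.0]))
    second = model.simulate(full.states[1], theta, (10.0, 20.0),
                            t_eval=np.array([10.0, 20.0]))
    np.testing.assert_allclose(second.states[-1], full.states[-1],
                               rtol=1e-3, atol=1e-6)


def test_simulation_keeps_pools_nonnegative_and_sinks_monotone(
        model, theta, steady):
    x0 = steady.values.copy()
    x0[POOLS.index("pFFA")] *= 5  # perturb a fast pool
    sim = model.simulate(x0, theta, (0.0, 90.0))
    assert sim.states.min() >= -1e-9
    for sink in ("fecC", "fecBA", "oxC"):
        col = sim.states[:, POOLS.index(sink)]
        assert np.all(np.diff(col) >= -1e-9)


# ----------------------------------------------------------------------
# steady state

def test_steady_state_has_small_residual(model, theta, steady):
    nonsink = [i for i, p in enumerate(POOLS)
               if p not in ("fecC", "fecBA", "oxC")]
    dx = model.derivatives(steady, theta)
    x = steady.values[nonsink]
    assert np.linalg.norm(dx[nonsink]) < 1e-6 * (1 + np.linalg.norm(x))


def test_steady_state_is_fixed_point_of_simulate(model, theta, steady):
    sim = model.simulate(steady, theta, (0.0, 30.0))
    nonsink = [i for i, p in enumerate(POOLS)
               if p not in ("fecC", "fecBA", "oxC")]
    rel = np.abs(sim.states[-1, nonsink] / steady.values[nonsink] - 1.0)
    assert rel.max() < 1e-3


def test_steady_state_fecal_output_balances_cholesterol_input(
        model, theta, steady):
    v = model.fluxes_dict(steady, theta)
    output = v["fecal_chol"] + v["fecal_ba"]
    inflow = dietary_inflow(model.diet)["chol"]
    synthesis = v["chol_synthesis"] / 18.0
    assert output == pytest.approx(inflow + synthesis, rel=1e-5)


def test_steady_state_converges_from_distant_guess(model, theta, steady):
    far = MetabolicState(reference_state().values * 7.0)
    ss = model.steady_state(theta, guess=far)
    np.testing.assert_allclose(ss.values, steady.values, rtol=1e-4,
                               atol=1e-8)


# ----------------------------------------------------------------------
# observation map

def test_observe_plasma_concentrations(model, theta):
    x = MetabolicState.from_dict({"pCh": 2.0, "pCv": 3.0}, default=0.0)
    y = model.observe(x, params=theta)
    assert y["plasma_hdl_c"] == pytest.approx(2.0)
    assert y["plasma_tc"] == pytest.approx(5.0)
    # non-HDL = TC - HDL
    assert y["plasma_tc"] - y["plasma_hdl_c"] == pytest.approx(3.0)


def test_observe_body_weight_without_fat_equals_lean_mass(model, theta):
    x = MetabolicState.from_dict({}, default=0.0)
    y = model.observe(x, params=theta)
    assert y["body_weight"] == pytest.approx(model.obs_map.lean_mass_g)


def test_observation_map_rejects_nonpositive_volume():
    with pytest.raises(ValueError):
        ObservationMap(plasma_volume_ml=0.0)


def test_default_diets_are_the_study_formulations():
    assert DIET_LFD.energy_density == 3.8
    assert DIET_LFD.frac_energy_fat == 0.20
    assert DIET_HFD.energy_density == 5.2
    assert DIET_HFD.frac_energy_fat == 0.60
    assert DIET_HFDC.chol_w_frac == 0.0025
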