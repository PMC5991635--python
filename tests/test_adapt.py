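"""Monte-Carlo resampling, spline targets and the per-day estimation."""

import numpy as np
import pytest

from metsim.adapt import (
    AdaptConfig,
    adapt_cost,
    adapt_step,
    fit_spline_set,
    initialize_t0,
    resample_dataset,
    run_ensemble,
    run_trajectory,
)
from metsim.data import GroupData, ObservationSeries, StudyDataset
from metsim.model import DIET_HFDC, Model, PARAM_NAMES, default_parameters
from metsim.synthetic import (
    StudyDesign,
    generate_model_ground_truth,
    linear_ramp_schedule,
)

FREE = ("k_chol_absorption", "k_dnl", "k_hdl_production")


def _series(days, mean, sd=None, n=8):
    days = np.asarray(days, dtype=float)
    mean = np.asarray(mean, dtype=float)
    sd = np.full_like(mean, 0.0) if sd is None else np.asarray(sd, float)
    return ObservationSeries(days, mean, sd, np.full(len(days), n))


def _dataset(observables, group="g"):
    return StudyDataset({group: GroupData(group, observables)})


@pytest.fixture(scope="module")
def truth_data():
    """Noise-free dataset generated by the model at constant θ."""
    model = Model(diet=DIET_HFDC)
    schedule = linear_ramp_schedule(default_parameters(),
                                    "k_chol_absorption", 1.0, 90.0)
    data, truth = generate_model_ground_truth(
        model, schedule, group="const", n_individuals=4, noise_frac=0.0,
        seed=1, design=StudyDesign.with_span(12.0))
    return model, data, truth


# ----------------------------------------------------------------------
# resampling

def test_resample_with_zero_sd_returns_original():
    data = _dataset({"plasma_tg": _series([0, 30], [1.0, 2.0])})
    sampled = resample_dataset(data, seed=3)
    np.testing.assert_array_equal(
        sampled.group("g").observables["plasma_tg"].mean, [1.0, 2.0])


def test_resample_deterministic_under_seed():
    data = _dataset({"plasma_tg": _series([0, 30], [1.0, 2.0],
                                          [0.3, 0.4])})
    a = resample_dataset(data, seed=7).group("g").observables["plasma_tg"]
    b = resample_dataset(data, seed=7).group("g").observables["plasma_tg"]
    np.testing.assert_array_equal(a.mean, b.mean)


def test_resample_distribution_matches_mean_and_sd():
    data = _dataset({"x": _series([0.0], [5.0], [0.8])})
    rng = np.random.default_rng(42)
    draws = np.array([
        resample_dataset(data, rng).group("g").observables["x"].mean[0]
        for _ in range(10_000)])
    assert np.mean(draws) == pytest.approx(5.0, rel=0.03)
    assert np.std(draws) == pytest.approx(0.8, rel=0.03)


def test_resample_keeps_sds_and_counts():
    data = _dataset({"x": _series([0, 30], [1.0, 2.0], [0.3, 0.4], n=5)})
    s = resample_dataset(data, seed=0).group("g").observables["x"]
    np.testing.assert_array_equal(s.sd, [0.3, 0.4])
    np.testing.assert_array_equal(s.n, [5, 5])


# ----------------------------------------------------------------------
# spline targets

def test_splines_reproduce_linear_data_exactly():
    days = np.array([0.0, 18.0, 36.0, 54.0, 72.0, 90.0])
    group = GroupData("g", {"x": _series(days, 2.0 + 0.1 * days,
                                         np.full(6, 0.5))})
    for smoothing in (None, 0.0, 10.0):
        curve = fit_spline_set(group, smoothing)["x"]
        for t in np.linspace(0, 90, 31):
            assert curve.value(t) == pytest.approx(2.0 + 0.1 * t,
                                                   rel=1e-6)


def test_interpolation_limit_passes_through_sampled_points():
    days = [0.0, 30.0, 60.0, 90.0]
    vals = [1.0, 2.5, 1.7, 3.2]
    group = GroupData("g", {"x": _series(days, vals, [0.2] * 4)})
    curve = fit_spline_set(group, smoothing=0.0)["x"]
    for d, v in zip(days, vals):
        assert curve.value(d) == pytest.approx(v, rel=1e-9)


def test_spline_evaluation_is_finite_and_bounded():
    rng = np.random.default_rng(0)
    days = [0.0, 30.0, 60.0, 90.0]
    vals = rng.uniform(1.0, 5.0, 4)
    group = GroupData("g", {"x": _series(days, vals, [0.3] * 4)})
    curve = fit_spline_set(group)["x"]
    lo, hi = vals.min(), vals.max()
    span = hi - lo
    ts = np.linspace(-10, 100, 200)  # beyond data range: constant
    ys = np.array([curve.value(t) for t in ts])
    assert np.all(np.isfinite(ys))
    assert np.all(ys >= lo - 10 * span) and np.all(ys <= hi + 10 * span)


def test_single_point_series_becomes_anchor(caplog):
    group = GroupData("g", {"liver_tg": _series([90.0], [40.0], [4.0])})
    with caplog.at_level("WARNING"):
        curves = fit_spline_set(group)
    assert "anchor" in caplog.text
    curve = curves["liver_tg"]
    assert curve.terminal_only
    assert curve.active_at(90.0) and not curve.active_at(45.0)
    assert curve.value(90.0) == 40.0


def test_sigma_interpolates_between_observation_days():
    group = GroupData("g", {"x": _series([0.0, 30.0], [1.0, 1.0],
                                         [0.2, 0.4])})
    curve = fit_spline_set(group)["x"]
    assert curve.sigma(15.0) == pytest.approx(0.3)


# ----------------------------------------------------------------------
# the per-day cost

def test_cost_with_lambda_zero_equals_wsse_identity(rng):
    for _ in range(100):
        names = [f"v{i}" for i in range(rng.integers(1, 8))]
        y = {n: float(rng.normal()) for n in names}
        targets = {n: (float(rng.normal()), float(abs(rng.normal()) + .1))
                   for n in names}
        m = rng.integers(1, 6)
        th_k = np.abs(rng.normal(1, 0.2, m)) + 0.1
        th_p = np.abs(rng.normal(1, 0.2, m)) + 0.1
        ref = np.abs(rng.normal(1, 0.2, m)) + 0.1
        got = adapt_cost(y, targets, th_k, th_p, ref, dt=1.0, lam=0.0)
        want = sum(((y[n] - t) / s) ** 2 for n, (t, s) in targets.items())
        assert got == want  # exact identity, no penalty term residue


def test_cost_matches_brute_force_summation(rng):
    for _ in range(100):
        names = [f"v{i}" for i in range(rng.integers(1, 8))]
        y = {n: float(rng.normal()) for n in names}
        targets = {n: (float(rng.normal()), float(abs(rng.normal()) + .1))
                   for n in names}
        m = rng.integers(1, 6)
        th_k = np.abs(rng.normal(1, 0.2, m)) + 0.1
        th_p = np.abs(rng.normal(1, 0.2, m)) + 0.1
        ref = np.abs(rng.normal(1, 0.2, m)) + 0.1
        dt, lam = float(abs(rng.normal()) + 0.5), float(abs(rng.normal()))
        got = adapt_cost(y, targets, th_k, th_p, ref, dt, lam)
        want = 0.0
        for n, (t, s) in targets.items():
            want += ((y[n] - t) / s) ** 2
        for j in range(m):
            want += lam * ((th_k[j] / ref[j] - th_p[j] / ref[j]) / dt) ** 2
        assert got == pytest.approx(want, rel=1e-10)


def test_cost_zero_for_stationary_exact_fit():
    y = {"a": 2.0}
    targets = {"a": (2.0, 0.5)}
    th = np.array([1.0, 3.0])
    assert adapt_cost(y, targets, th, th, th, 1.0, 0.1) == 0.0


def test_penalty_of_one_doubling_per_day_is_lambda():
    # one parameter doubles in one day, ref = day-0 value, dt=1, λ=0.1:
    # penalty contribution λ·((2θ−θ)/θ)² = 0.1
    ref = np.array([4.0])
    got = adapt_cost({}, {}, np.array([8.0]), np.array([4.0]), ref,
                     dt=1.0, lam=0.1)
    assert got == pytest.approx(0.1, rel=1e-14)


def test_cost_rejects_nonpositive_dt():
    with pytest.raises(ValueError):
        adapt_cost({}, {}, np.ones(1), np.ones(1), np.ones(1), 0.0, 0.1)


# ----------------------------------------------------------------------
# per-day estimation steps

def test_t0_initialization_recovers_generating_outputs(truth_data):
    model, data, _ = truth_data
    config = AdaptConfig(n_days=12, n_starts_t0=4, free_parameters=FREE)
    theta0, state0, fit_wsse = initialize_t0(
        model, data.group("const"), config, seed=3)
    assert fit_wsse <= 1e-3
    y = model.observe(state0, params=theta0)
    for name, series in data.group("const").observables.items():
        assert y[name] == pytest.approx(series.mean[0], rel=0.01)
    # steady state within model tolerance
    dx = model.derivatives(state0, theta0)
    assert np.linalg.norm(dx[:19]) < 1e-5 * (1 + np.linalg.norm(
        state0.values[:19]))


def test_adapt_step_stationary_when_targets_match_steady_state(truth_data):
    model, data, _ = truth_data
    config = AdaptConfig(n_days=12, n_starts_t0=4, free_parameters=FREE)
    sampled = resample_dataset(data, seed=0)  # zero noise -> identity
    splines = fit_spline_set(sampled.group("const"))
    theta0, state0, _ = initialize_t0(model, sampled.group("const"),
                                      config, seed=3)
    theta1, _, _, _, pen, ok = adapt_step(
        model, state0, theta0, splines, 1.0, config, theta0.values)
    assert ok
    np.testing.assert_allclose(theta1.values, theta0.values, rtol=5e-3)
    assert pen < 1e-4


def test_adapt_step_with_huge_lambda_freezes_parameters(truth_data):
    model, data, _ = truth_data
    config = AdaptConfig(n_days=12, n_starts_t0=4, free_parameters=FREE,
                         lam=1e8)
    sampled = resample_dataset(data, seed=1)
    splines = fit_spline_set(sampled.group("const"))
    theta0 = default_parameters().replace(k_chol_absorption=60.0)
    state0 = model.steady_state(theta0)
    theta1, _, _, _, _, _ = adapt_step(
        model, state0, theta0, splines, 1.0, config, theta0.values)
    np.testing.assert_allclose(theta1.values, theta0.values, rtol=1e-4)


# ----------------------------------------------------------------------
# full trajectories and ensembles

def test_constant_truth_recovered_flat(truth_data):
    """Noise-free data from constant parameters: the estimated
    trajectory stays flat within 5% for every free parameter."""
    model, data, _ = truth_data
    config = AdaptConfig(n_days=12, n_starts_t0=4, free_parameters=FREE,
                         seed=0)
    traj = run_trajectory(model, data, config, seed=21)
    for name in FREE:
        series = traj.series(f"param:{name}")
        assert np.max(np.abs(series / series[0] - 1.0)) < 0.05, name


def test_trajectory_length_and_determinism(truth_data):
    model, data, _ = truth_data
    config = AdaptConfig(n_days=5, n_starts_t0=2, free_parameters=FREE)
    a = run_trajectory(model, data, config, seed=9)
    assert len(a.days) == 6 and a.params.shape[0] == 6
    b = run_trajectory(model, data, config, seed=9)
    np.testing.assert_array_equal(a.params, b.params)
    np.testing.assert_array_equal(a.states, b.states)
    assert a.wsse_total == b.wsse_total


def test_warm_start_continuity(truth_data):
    model, data, _ = truth_data
    config = AdaptConfig(n_days=8, n_starts_t0=2, free_parameters=FREE)
    traj = run_trajectory(model, data, config, seed=4)
    ratios = traj.params[1:] / traj.params[:-1]
    assert np.all(ratios < 10.0) and np.all(ratios > 0.1)


def test_trajectory_series_rejects_unknown_quantity(truth_data):
    model, data, _ = truth_data
    config = AdaptConfig(n_days=2, n_starts_t0=2, free_parameters=FREE)
    traj = run_trajectory(model, data, config, seed=1)
    with pytest.raises(KeyError, match="valid names"):
        traj.series("flux:nope")
    with pytest.raises(KeyError):
        traj.series("bogus")


def test_ensemble_members_have_distinct_resamples():
    model = Model(diet=DIET_HFDC)
    schedule = linear_ramp_schedule(default_parameters(),
                                    "k_chol_absorption", 1.0, 6.0)
    data, _ = generate_model_ground_truth(
        model, schedule, group="g", n_individuals=4, noise_frac=0.05,
        seed=2, design=StudyDesign(plasma_days=(0.0, 6.0),
                                   bw_days=(0.0, 6.0), terminal_day=6.0))
    config = AdaptConfig(n_days=2, n_ensemble=3, n_starts_t0=1,
                         free_parameters=("k_chol_absorption",), seed=5)
    ens = run_ensemble(model, data, config)
    assert len(ens) == 3
    seeds = {m.seed for m in ens.members}
    assert len(seeds) == 3
    t0_params = [m.params[0].tolist() for m in ens.members]
    assert not (t0_params[0] == t0_params[1] == t0_params[2])


def test_ensemble_on_zero_sd_data_gives_identical_members(truth_data):
    model, data, _ = truth_data
    config = AdaptConfig(n_days=2, n_ensemble=3, n_starts_t0=1,
                         free_parameters=("k_chol_absorption",), seed=5)
    ens = run_ensemble(model, data, config)
    assert len(ens) == 3
    # zero-SD data: every resample is the original dataset; the t0
    # multi-start draws still differ, but the fitted observables agree
    for m in ens.members[1:]:
        np.testing.assert_allclose(m.states, ens.members[0].states,
                                   rtol=1e-3, atol=1e-8)


def test_config_validation():
    with pytest.raises(ValueError):
        AdaptConfig(n_days=0)
    with pytest.raises(ValueError):
        AdaptConfig(lam=-0.1)
    with pytest.raises(ValueError):
        AdaptConfig(free_parameters=("k_nope",))
    assert AdaptConfig(n_days=90).n_segments == 90
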