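"""ADAPT: analysis of dynamic adaptations in parameter trajectories.

Longitudinal phenotype data are discrete (monthly plasma snapshots,
weekly body weight, terminal liver lipids) while disease progression is
continuous and slow.  ADAPT bridges the two by (i) drawing Monte-Carlo
samples of the data from Gaussian distributions with the observed means
and SDs, (ii) interpolating each sample with cubic smoothing splines to
obtain continuous target curves, and (iii) discretizing the study into
one-day segments and re-estimating the model parameters for each day,
warm-started from the previous day and penalized for parameter motion.

The per-day objective is

    cost(θ_k) = Σ_i ((ŷ_i(t_k) − s_i(t_k)) / σ_i(t_k))²
              + λ · Σ_j ((θ_{k,j}/θ_ref,j − θ_{k−1,j}/θ_ref,j) / Δt)²

where ŷ is the model output after simulating one day from the previous
day's end state, s_i are the spline targets, and the second term is the
squared derivative of the normalized parameter values (λ = 0.1 by
default).  Repeating the whole procedure for many data resamples yields
an ensemble of trajectory solutions — a virtual population.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline, make_interp_spline, \
    make_smoothing_spline
from scipy.optimize import least_squares

from .calibration import (
    DEFAULT_SD_FRACTION,
    fit_snapshot,
    snapshot_from_group,
)
from .data import GroupData, ObservationSeries, StudyDataset
from .network import POOLS
from .model import (
    MetabolicState,
    Model,
    ParameterSet,
    PARAM_NAMES,
    SimOptions,
)

__all__ = [
    "AdaptConfig",
    "TargetCurve",
    "SplineSet",
    "ParameterTrajectory",
    "Ensemble",
    "resample_dataset",
    "fit_spline_set",
    "adapt_cost",
    "initialize_t0",
    "adapt_step",
    "run_trajectory",
    "run_ensemble",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AdaptConfig:
    """Settings of one ADAPT run.

    ``n_days`` one-day segments cover the study (90 for a three-month
    study); ``n_ensemble`` Monte-Carlo resamples are fitted; ``lam`` is
    the regularization strength; ``smoothing`` is the spline smoothing
    parameter (``None`` = generalized cross-validation where the series
    is long enough).  ``free_parameters`` restricts estimation to a
    subset of θ (``None`` = all); ``normalization`` chooses the θ_ref
    of the penalty term ("t0": the day-0 estimate, "previous": the
    running θ_{k−1}).
    """

    n_days: int = 90
    n_ensemble: int = 1000
    lam: float = 0.1
    smoothing: float | None = None
    seed: int = 0
    n_starts_t0: int = 10
    free_parameters: tuple[str, ...] | None = None
    normalization: str = "t0"
    max_nfev_step: int = 100
    max_nfev_t0: int = 300
    t0_init_range: tuple[float, float] = (1e-1, 1e1)
    inner_tol: float = 1e-6
    #: finite-difference step of the inner optimizer on log-parameters;
    #: must stay well above the integrator tolerance noise floor
    inner_diff_step: float = 1e-3
    sd_fraction: float = DEFAULT_SD_FRACTION
    sim_options: SimOptions = field(default_factory=SimOptions)
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.n_ensemble < 1:
            raise ValueError("n_ensemble must be >= 1")
        if self.normalization not in ("t0", "previous"):
            raise ValueError("normalization must be 't0' or 'previous'")
        if self.free_parameters is not None:
            unknown = set(self.free_parameters) - set(PARAM_NAMES)
            if unknown:
                raise ValueError(f"unknown parameters: {sorted(unknown)}")

    @property
    def n_segments(self) -> int:
        """Number of one-day segments the study is discretized into."""
        return self.n_days


# ----------------------------------------------------------------------
# Monte-Carlo resampling

def resample_dataset(data: StudyDataset,
                     seed: int | np.random.Generator | None = None
                     ) -> StudyDataset:
    """Gaussian resample of every (group, observable, day) mean.

    Each mean is replaced by a draw from Normal(mean, SD); SDs and
    replicate counts are retained.  Deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    groups = {}
    for gname, g in data.groups.items():
        observables = {}
        for oname, s in g.observables.items():
            sampled = rng.normal(s.mean, s.sd)
            observables[oname] = ObservationSeries(
                s.days.copy(), sampled, s.sd.copy(), s.n.copy())
        groups[gname] = GroupData(gname, observables)
    return StudyDataset(groups)


# ----------------------------------------------------------------------
# spline interpolation of one resampled dataset

@dataclass
class TargetCurve:
    """Continuous target for one observable: value and SD over time.

    Series with a single time point cannot be interpolated and become
    *anchors*: they enter the cost only at (near) that time point.
    """

    name: str
    days: np.ndarray
    _value: object  # callable t -> value
    _sigma: object  # callable t -> sd
    terminal_only: bool = False

    def value(self, t: float) -> float:
        t = float(np.clip(t, self.days[0], self.days[-1]))
        return float(self._value(t))

    def sigma(self, t: float) -> float:
        t = float(np.clip(t, self.days[0], self.days[-1]))
        return float(self._sigma(t))

    def active_at(self, t: float, atol: float = 0.5) -> bool:
        if not self.terminal_only:
            return True
        return bool(np.min(np.abs(self.days - t)) <= atol)


class SplineSet(dict):
    """Mapping observable name -> :class:`TargetCurve`."""

    def targets_at(self, t: float) -> dict[str, tuple[float, float]]:
        """(target value, sigma) of every curve active at time ``t``."""
        return {name: (c.value(t), c.sigma(t))
                for name, c in self.items() if c.active_at(t)}


def _effective_sd(sd: np.ndarray, mean: np.ndarray,
                  sd_fraction: float) -> np.ndarray:
    out = np.where(sd > 0, sd, sd_fraction * np.abs(mean))
    return np.where(out > 0, out, 1.0)


def fit_spline_set(sampled: GroupData | StudyDataset,
                   smoothing: float | None = None,
                   sd_fraction: float = DEFAULT_SD_FRACTION,
                   group: str | None = None) -> SplineSet:
    """Cubic smoothing spline per observable of one (resampled) group.

    Series with ≥5 points use a smoothing spline (``smoothing=None``
    selects the penalty by generalized cross-validation; ``0`` is the
    interpolation limit).  Short series (2–4 points) use an
    interpolating spline of the highest supported odd degree, which for
    ``smoothing→0`` coincides with the interpolation limit.  Outside the
    observed time range curves extend as constants.  SD curves are
    linear interpolations of the per-day SDs.
    """
    if isinstance(sampled, StudyDataset):
        sampled = sampled.group(group)
    curves = SplineSet()
    for name, s in sampled.observables.items():
        sd = _effective_sd(s.sd, s.mean, sd_fraction)
        if len(s) == 1:
            v0, s0 = float(s.mean[0]), float(sd[0])
            curves[name] = TargetCurve(
                name, s.days.copy(), lambda t, v=v0: v,
                lambda t, v=s0: v, terminal_only=True)
            logger.warning("observable %r has a single time point; "
                           "using it as an anchor only", name)
            continue
        if len(s) >= 5:
            # weighting by 1/SD² makes the smoothing penalty act on
            # standardized residuals, so one value serves all observables
            spl = make_smoothing_spline(s.days, s.mean, w=1.0 / sd**2,
                                        lam=smoothing)
        elif len(s) >= 4:
            spl = CubicSpline(s.days, s.mean, bc_type="natural")
        else:
            spl = make_interp_spline(s.days, s.mean, k=len(s) - 1)
        sig = lambda t, d=s.days, v=sd: float(np.interp(t, d, v))
        curves[name] = TargetCurve(name, s.days.copy(), spl, sig)
    return curves


# ----------------------------------------------------------------------
# the per-day cost

def adapt_cost(y_hat: dict[str, float],
               targets: dict[str, tuple[float, float]],
               theta_k: np.ndarray, theta_km1: np.ndarray,
               theta_ref: np.ndarray,
               dt: float = 1.0, lam: float = 0.1) -> float:
    """One-day ADAPT objective: data-fit WSSE against the spline targets
    plus λ times the squared time-derivative of normalized parameters.

    With ``lam=0`` this reduces exactly to the snapshot-style WSSE.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    cost = 0.0
    for name, (target, sigma) in targets.items():
        cost += ((y_hat[name] - target) / sigma) ** 2
    dnorm = (np.asarray(theta_k, dtype=float)
             - np.asarray(theta_km1, dtype=float)) / np.asarray(
                 theta_ref, dtype=float)
    cost += lam * float(np.sum((dnorm / dt) ** 2))
    return cost


# ----------------------------------------------------------------------
# trajectory containers

@dataclass(eq=False)
class ParameterTrajectory:
    """One ADAPT solution: per-day θ, states, fluxes and fit errors."""

    days: np.ndarray                  # (n_days+1,)
    params: np.ndarray                # (n_days+1, n_params)
    states: np.ndarray                # (n_days+1, n_pools)
    fluxes: np.ndarray                # (n_days+1, n_fluxes)
    data_error: np.ndarray            # per-day WSSE against spline targets
    penalty: float                    # Σ squared normalized derivatives
    wsse_total: float                 # WSSE against the original data
    seed: int
    param_names: tuple[str, ...]
    pool_names: tuple[str, ...]
    flux_names: tuple[str, ...]
    warnings: list[str] = field(default_factory=list)

    def series(self, quantity: str) -> np.ndarray:
        """Per-day values of ``"state:<pool>"``, ``"flux:<name>"`` or
        ``"param:<name>"``."""
        kind, _, name = quantity.partition(":")
        pools = {"state": (self.states, self.pool_names),
                 "flux": (self.fluxes, self.flux_names),
                 "param": (self.params, self.param_names)}
        if kind not in pools or not name:
            raise KeyError(
                f"quantity must be 'state:<name>', 'flux:<name>' or "
                f"'param:<name>', got {quantity!r}")
        arr, names = pools[kind]
        if name not in names:
            raise KeyError(
                f"unknown {kind} {name!r}; valid names: {sorted(names)}")
        return arr[:, names.index(name)]


@dataclass(eq=False)
class Ensemble:
    """Monte-Carlo collection of trajectory solutions."""

    members: list[ParameterTrajectory]
    failures: list[tuple[int, str]] = field(default_factory=list)
    config: AdaptConfig | None = None

    def __len__(self) -> int:
        return len(self.members)

    @property
    def wsse(self) -> np.ndarray:
        return np.array([m.wsse_total for m in self.members])


# ----------------------------------------------------------------------
# estimation steps

def initialize_t0(model: Model, data: GroupData | SplineSet | StudyDataset,
                  config: AdaptConfig, seed: int | None = None,
                  group: str | None = None):
    """Steady-state calibration to the t = 0 snapshot.

    Returns ``(θ₀, steady state, t0 fit WSSE)`` of the best multi-start
    fit.  Accepts a (resampled) group, dataset or spline set; with a
    spline set the targets are the curve values at t = 0.
    """
    from .calibration import SnapshotData

    if isinstance(data, StudyDataset):
        data = data.group(group)
    if isinstance(data, SplineSet):
        obs = {name: (c.value(0.0), c.sigma(0.0), 1)
               for name, c in data.items() if c.active_at(0.0)}
        snapshot = SnapshotData(obs, day=0.0,
                                sd_fraction=config.sd_fraction)
    else:
        snapshot = snapshot_from_group(data, 0.0)
        snapshot = replace(snapshot, sd_fraction=config.sd_fraction)
    fits = fit_snapshot(
        model, snapshot, n_starts=config.n_starts_t0, seed=seed,
        init_range=config.t0_init_range,
        free_parameters=list(config.free_parameters)
        if config.free_parameters else None,
        max_nfev=config.max_nfev_t0)
    best = next((f for f in fits if f.steady_state is not None), None)
    if best is None or not math.isfinite(best.wsse):
        raise RuntimeError("no acceptable t=0 fit found")
    return best.params, best.steady_state, best.wsse


def adapt_step(model: Model, prev_state, theta_prev: ParameterSet,
               splines: SplineSet, t_k: float, config: AdaptConfig,
               theta_ref: np.ndarray | None = None):
    """Re-estimate θ for the segment ending at ``t_k``.

    Simulates one day from the previous end state inside the residual
    and minimizes the ADAPT cost over the free parameters (on a log
    scale, warm-started at θ_{k−1}).  Returns ``(θ_k, end state, fluxes
    at t_k, data-fit WSSE, penalty contribution, ok flag)``; on
    optimizer failure θ_{k−1} is carried over with ``ok=False``.
    """
    dt = 1.0
    x_prev = prev_state.values if isinstance(prev_state, MetabolicState) \
        else np.asarray(prev_state, dtype=float)
    free = list(config.free_parameters) if config.free_parameters \
        else list(PARAM_NAMES)
    free_idx = np.array([PARAM_NAMES.index(n) for n in free])
    base_log = np.log(theta_prev.values)
    if theta_ref is None:
        theta_ref = theta_prev.values
    ref_free = np.asarray(theta_ref, dtype=float)[free_idx]
    prev_free = theta_prev.values[free_idx]
    targets = splines.targets_at(t_k)
    names = list(targets)
    t_vals = np.array([targets[n][0] for n in names])
    t_sds = np.array([targets[n][1] for n in names])
    sqrt_lam = math.sqrt(config.lam)
    diet_v = model._inflow_vector(model.diet)
    opts = config.sim_options

    def simulate_day(theta_vec):
        sim = model.simulate(
            x_prev, ParameterSet(theta_vec), (t_k - dt, t_k),
            options=opts, t_eval=np.array([t_k - dt, t_k]))
        return sim.final_state()

    state_cache: dict = {}

    def residual(u):
        log_theta = base_log.copy()
        log_theta[free_idx] = u
        theta_vec = np.exp(log_theta)
        try:
            x_end = simulate_day(theta_vec)
        except Exception:
            return np.full(len(names) + len(free_idx), 1e6)
        v_end = model._fluxes_raw(x_end, theta_vec, diet_v)
        y = model.observe(x_end, fluxes=v_end)
        r_data = np.array([(y[n] - tv) / ts
                           for n, tv, ts in zip(names, t_vals, t_sds)])
        r_reg = sqrt_lam * (theta_vec[free_idx] / ref_free
                            - prev_free / ref_free) / dt
        state_cache["x_end"] = x_end
        state_cache["v_end"] = v_end
        state_cache["r_data"] = r_data
        return np.concatenate([r_data, r_reg])

    u0 = base_log[free_idx]
    ok = True
    try:
        sol = least_squares(residual, u0, method="trf",
                            max_nfev=config.max_nfev_step,
                            diff_step=config.inner_diff_step,
                            ftol=config.inner_tol, xtol=config.inner_tol,
                            gtol=config.inner_tol)
        u_opt = sol.x
    except Exception as exc:
        logger.warning("inner optimization failed at t=%g: %s", t_k, exc)
        u_opt, ok = u0, False
    residual(u_opt)  # refresh cache at the optimum
    log_theta = base_log.copy()
    log_theta[free_idx] = u_opt
    theta_k = ParameterSet(np.exp(log_theta))
    r_data = state_cache["r_data"]
    data_wsse = float(r_data @ r_data)
    dnorm = (theta_k.values[free_idx] - prev_free) / ref_free
    penalty_k = float(np.sum((dnorm / dt) ** 2))
    return (theta_k, MetabolicState(state_cache["x_end"]),
            state_cache["v_end"], data_wsse, penalty_k, ok)


# ----------------------------------------------------------------------
# full trajectory and ensemble

def _total_wsse(model: Model, original: GroupData, days: np.ndarray,
                states: np.ndarray, fluxes: np.ndarray,
                sd_fraction: float) -> float:
    """WSSE of the trajectory against the original (unsampled) data at
    all observation days."""
    total = 0.0
    for name, s in original.observables.items():
        sd = _effective_sd(s.sd, s.mean, sd_fraction)
        for d, mean, sigma in zip(s.days, s.mean, sd):
            k = int(np.argmin(np.abs(days - d)))
            if abs(days[k] - d) > 0.5:
                continue
            y = model.observe(states[k], fluxes=fluxes[k])
            total += ((y[name] - mean) / sigma) ** 2
    return total


def run_trajectory(model: Model, data: StudyDataset, config: AdaptConfig,
                   seed: int, group: str | None = None
                   ) -> ParameterTrajectory:
    """One complete ADAPT solution for one Monte-Carlo resample.

    resample → splines → t=0 steady-state calibration → ``n_days``
    sequential one-day re-estimations.  Deterministic under ``seed``.
    """
    original = data.group(group)
    rng = np.random.default_rng(seed)
    sampled = resample_dataset(StudyDataset({original.name: original}),
                               rng).group(original.name)
    splines = fit_spline_set(sampled, config.smoothing, config.sd_fraction)
    t0_seed = int(rng.integers(0, 2**31 - 1))
    theta0, state0, _ = initialize_t0(model, sampled, config, seed=t0_seed)

    n = config.n_days
    n_par, n_pool = len(PARAM_NAMES), len(state0.values)
    days = np.arange(n + 1, dtype=float)
    params = np.empty((n + 1, n_par))
    states = np.empty((n + 1, n_pool))
    fluxes = np.empty((n + 1, model.n_fluxes))
    data_error = np.empty(n + 1)
    warnings: list[str] = []

    params[0] = theta0.values
    states[0] = state0.values
    fluxes[0] = model.compute_fluxes(state0, theta0)
    y0 = model.observe(state0, fluxes=fluxes[0])
    t0_targets = splines.targets_at(0.0)
    data_error[0] = sum(((y0[nm] - tv) / ts) ** 2
                        for nm, (tv, ts) in t0_targets.items())

    theta_ref = theta0.values.copy()
    theta_prev, x_prev = theta0, state0
    penalty = 0.0
    for k in range(1, n + 1):
        ref = theta_ref if config.normalization == "t0" \
            else theta_prev.values
        theta_k, x_k, v_k, err_k, pen_k, ok = adapt_step(
            model, x_prev, theta_prev, splines, float(k), config, ref)
        if not ok:
            warnings.append(f"day {k}: optimizer failure, carried theta")
        params[k] = theta_k.values
        states[k] = x_k.values
        fluxes[k] = v_k
        data_error[k] = err_k
        penalty += pen_k
        theta_prev, x_prev = theta_k, x_k

    wsse_total = _total_wsse(model, original, days, states, fluxes,
                             config.sd_fraction)
    return ParameterTrajectory(
        days, params, states, fluxes, data_error, penalty, wsse_total,
        int(seed), tuple(PARAM_NAMES), POOLS,
        tuple(model.flux_names), warnings)


def run_ensemble(model: Model, data: StudyDataset, config: AdaptConfig,
                 group: str | None = None) -> Ensemble:
    """Independent :func:`run_trajectory` calls on distinct resamples.

    Member seeds derive from ``config.seed``; failing members are
    excluded and logged with their seed.  With ``n_jobs > 1`` members
    run in parallel via joblib.
    """
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
             for s in np.random.SeedSequence(config.seed).spawn(
                 config.n_ensemble)]

    def one(seed):
        return run_trajectory(model, data, config, seed, group)

    members: list[ParameterTrajectory] = []
    failures: list[tuple[int, str]] = []
    if config.n_jobs > 1:
        from joblib import Parallel, delayed
        outcomes = Parallel(n_jobs=config.n_jobs)(
            delayed(_safe_run)(model, data, config, s, group) for s in seeds)
        for s, (traj, err) in zip(seeds, outcomes):
            (members.append(traj) if traj is not None
             else failures.append((s, err)))
    else:
        for s in seeds:
            traj, err = _safe_run(model, data, config, s, group)
            if traj is not None:
                members.append(traj)
            else:
                failures.append((s, err))
    if failures:
        logger.warning("%d/%d ensemble members failed",
                       len(failures), config.n_ensemble)
    return Ensemble(members, failures, config)


def _safe_run(model, data, config, seed, group):
    try:
        return run_trajectory(model, data, config, seed, group), ""
    except Exception as exc:
        logger.warning("member seed=%d failed: %s", seed, exc)
        return None, str(exc)
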