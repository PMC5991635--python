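"""Steady-state calibration of the model to phenotype snapshots.

A *snapshot* is the per-group mean ± SD of the measured phenotype
variables at one time point.  The model's steady state is fitted to it
by weighted least squares (WSSE = Σ((ŷ−mean)/SD)²) with multi-start
optimization: each start draws initial parameters log-uniformly from a
wide range (by default 10⁻¹–10¹ times the reference values) and runs a
bound-constrained trust-region-reflective least-squares solve on
log-parameters, which keeps θ positive by construction.  Fits with
WSSE below an acceptance threshold (default 100) are retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .data import GroupData
from .model import (
    MetabolicState,
    Model,
    ParameterSet,
    PARAM_NAMES,
    SteadyStateError,
    default_parameters,
    reference_state,
)

__all__ = [
    "SnapshotData",
    "FitResult",
    "wsse",
    "wsse_terms",
    "fit_snapshot",
    "filter_acceptable",
    "snapshot_from_group",
]

logger = logging.getLogger(__name__)

#: WSSE acceptance threshold for a model fit (strict upper bound)
WSSE_THRESHOLD = 100.0

#: fallback weight when a snapshot SD is zero or missing: fraction of |mean|
DEFAULT_SD_FRACTION = 0.10


@dataclass(frozen=True)
class SnapshotData:
    """Mean ± SD of each observable at one time point of one group."""

    observables: dict[str, tuple[float, float, int]]  # name -> (mean, sd, n)
    group: str = ""
    day: float = 0.0
    sd_fraction: float = DEFAULT_SD_FRACTION

    def weights(self) -> dict[str, tuple[float, float]]:
        """(mean, effective SD) per observable; zero SDs are replaced by
        ``sd_fraction·|mean|`` (or 1.0 if the mean is zero too)."""
        out = {}
        for name, (mean, sd, _n) in self.observables.items():
            if sd <= 0:
                sd = self.sd_fraction * abs(mean)
                if sd == 0:
                    sd = 1.0
            out[name] = (mean, sd)
        return out


def snapshot_from_group(group: GroupData, day: float,
                        atol: float = 0.5) -> SnapshotData:
    """Extract the snapshot at ``day`` from longitudinal group data,
    keeping only observables actually measured at that day."""
    obs: dict[str, tuple[float, float, int]] = {}
    for name, series in group.observables.items():
        try:
            mean, sd = series.at_day(day, atol)
        except KeyError:
            continue
        i = int(np.argmin(np.abs(series.days - day)))
        obs[name] = (mean, sd, int(series.n[i]))
    if not obs:
        raise KeyError(f"group {group.name!r} has no data at day {day}")
    return SnapshotData(obs, group.name, day)


@dataclass
class FitResult:
    """Outcome of one optimization start."""

    params: ParameterSet
    wsse: float
    steady_state: MetabolicState | None
    converged: bool
    start_index: int
    n_evals: int = 0

    def __post_init__(self) -> None:
        if self.wsse < 0:
            raise ValueError("WSSE must be non-negative")


def wsse_terms(predicted: dict[str, float],
               targets: dict[str, tuple[float, float]]) -> np.ndarray:
    """Standardized residuals (ŷ−mean)/SD over the target observables."""
    return np.array([(predicted[name] - mean) / sd
                     for name, (mean, sd) in targets.items()])


def wsse(model: Model, params: ParameterSet, snapshot: SnapshotData,
         guess=None) -> float:
    """Weighted sum of squared errors of the steady state against a
    snapshot; returns ``inf`` when no steady state is obtained."""
    try:
        ss = model.steady_state(params, guess=guess)
    except (SteadyStateError, RuntimeError) as exc:
        logger.debug("steady state failed in wsse: %s", exc)
        return math.inf
    predicted = model.observe(ss, params=params)
    r = wsse_terms(predicted, snapshot.weights())
    return float(r @ r)


_BAD_RESIDUAL = 1e6


def _make_residual(model: Model, targets, free_idx, base_log):
    """Residual function over log-parameters with a warm steady-state
    cache (the previous successful steady state seeds the next solve)."""
    cache = {"guess": reference_state()}

    def residual(u):
        log_theta = base_log.copy()
        log_theta[free_idx] = u
        params = ParameterSet(np.exp(log_theta))
        try:
            ss = model.steady_state(params, guess=cache["guess"])
        except (SteadyStateError, RuntimeError):
            return np.full(len(targets), _BAD_RESIDUAL)
        cache["guess"] = ss
        predicted = model.observe(ss, params=params)
        r = wsse_terms(predicted, targets)
        cache["ss"] = ss
        return r

    return residual, cache


def fit_snapshot(model: Model, snapshot: SnapshotData,
                 n_starts: int = 500,
                 init_range: tuple[float, float] = (1e-1, 1e1),
                 seed: int | None = None,
                 free_parameters: list[str] | None = None,
                 base_params: ParameterSet | None = None,
                 max_nfev: int = 500,
                 log_bounds: tuple[float, float] = (-9.0, 12.0),
                 ) -> list[FitResult]:
    """Multi-start weighted least-squares calibration to one snapshot.

    Each start samples initial values for the free parameters
    log-uniformly over ``init_range`` (relative to ``base_params``) and
    minimizes the standardized residuals over log-parameters with the
    trust-region-reflective solver.  Results are returned sorted by
    ascending WSSE.  Deterministic for a fixed ``seed``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    base = base_params or default_parameters()
    free = list(free_parameters) if free_parameters is not None \
        else list(PARAM_NAMES)
    unknown = set(free) - set(PARAM_NAMES)
    if unknown:
        raise KeyError(f"unknown parameters: {sorted(unknown)}")
    free_idx = np.array([PARAM_NAMES.index(n) for n in free])
    base_log = np.log(base.values)
    targets = snapshot.weights()
    rng = np.random.default_rng(seed)
    lo, hi = math.log(init_range[0]), math.log(init_range[1])

    results: list[FitResult] = []
    for start in range(n_starts):
        u0 = base_log[free_idx] + rng.uniform(lo, hi, size=len(free_idx))
        residual, cache = _make_residual(model, targets, free_idx, base_log)
        try:
            sol = least_squares(residual, u0, method="trf",
                                bounds=log_bounds, max_nfev=max_nfev,
                                diff_step=1e-4)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("start %d failed: %s", start, exc)
            continue
        log_theta = base_log.copy()
        log_theta[free_idx] = sol.x
        params = ParameterSet(np.exp(log_theta))
        r = residual(sol.x)
        fit_wsse = float(r @ r)
        if fit_wsse >= _BAD_RESIDUAL**2:
            fit_wsse = math.inf
        results.append(FitResult(params, fit_wsse, cache.get("ss"),
                                 bool(sol.success), start, int(sol.nfev)))
    if not results:
        raise RuntimeError("all optimization starts failed")
    results.sort(key=lambda r: (r.wsse, r.start_index))
    return results


def filter_acceptable(results: list[FitResult],
                      threshold: float = WSSE_THRESHOLD) -> list[FitResult]:
    """Keep fits with WSSE strictly below the acceptance threshold."""
    kept = [r for r in results if r.wsse < threshold]
    if not kept:
        logger.info("no fits below WSSE threshold %g (best %g)",
                    threshold, min((r.wsse for r in results), default=math.nan))
    return kept
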