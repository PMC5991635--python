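"""Synthetic study data.

Two generators:

* :func:`generate_phenomenological_study` emulates the *structure and
  qualitative patterns* of a three-month diet-induction study in mice:
  four groups (LFD n=8, HFD n=12, and a high-fat/high-cholesterol
  cohort of 8 split into 5 non-dyslipidemic and 3 dyslipidemic
  individuals), monthly plasma sampling, weekly body weight, terminal
  liver lipids and de novo lipogenesis, and a bimodal plasma TG/TC
  split that emerges after the second month in the dyslipidemic
  subgroup.  All magnitudes are synthetic defaults chosen to be
  physiologically plausible for the mouse; they are not measurements.

* :func:`generate_model_ground_truth` simulates the whole-body model
  itself under a prescribed time-varying parameter schedule and samples
  noisy observations from it, returning the hidden truth alongside —
  the standard scaffold for parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import StudyDataset, dataset_from_individuals
from .model import (
    Model,
    OBSERVABLE_UNITS,
    ParameterSet,
    PARAM_NAMES,
    SimOptions,
)

__all__ = [
    "StudyDesign",
    "GroundTruth",
    "generate_phenomenological_study",
    "generate_model_ground_truth",
    "linear_ramp_schedule",
    "DEFAULT_GROUP_SIZES",
]

PLASMA_DAYS = (0.0, 30.0, 60.0, 90.0)
BW_DAYS = tuple(float(d) for d in range(0, 91, 7)) + (90.0,)
BW_DAYS = tuple(sorted(set(BW_DAYS)))
TERMINAL_DAY = 90.0

DEFAULT_GROUP_SIZES = {
    "LFD": 8, "HFD": 12, "MetS_non-DLP": 5, "MetS_DLP": 3,
}

# measurement-noise SD per observable (units of the observable); the
# individual random effect uses the same scale.  Chosen so that the
# dyslipidemic split at day 90 is cleanly bimodal at default noise.
_NOISE_SD = {
    "plasma_glucose": 0.35,
    "plasma_insulin": 0.02,
    "plasma_ffa": 0.08,
    "plasma_tg": 0.15,
    "plasma_tc": 0.40,
    "plasma_hdl_c": 0.15,
    "body_weight": 0.8,
    "liver_tg": 3.0,
    "liver_fc": 1.0,
    "liver_ce": 2.0,
    "dnl_flux": 150.0,
}


@dataclass(frozen=True)
class StudyDesign:
    """Layout of the synthetic three-month feeding study."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    plasma_days: tuple[float, ...] = PLASMA_DAYS
    bw_days: tuple[float, ...] = BW_DAYS
    terminal_day: float = TERMINAL_DAY
    noise_scale: float = 1.0  # multiplies all noise SDs (0 = noise free)
    noise_sd: dict[str, float] = field(
        default_factory=lambda: dict(_NOISE_SD))
    #: also report liver lipids / DNL at day 0 (baseline sacrifice group,
    #: mirroring the use of control-group values as initial anchors)
    baseline_liver: bool = True

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        days = list(self.plasma_days) + list(self.bw_days)
        if any(d < 0 or d > self.terminal_day for d in days):
            raise ValueError("sampling days must lie within the study span")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")

    @classmethod
    def with_span(cls, t_end: float, n_plasma: int = 4,
                  **kwargs) -> "StudyDesign":
        """Design with the standard layout compressed to ``t_end`` days:
        ``n_plasma`` evenly spaced plasma samplings and weekly body
        weight (or the span endpoints, if shorter than a week)."""
        plasma = tuple(np.linspace(0.0, t_end, n_plasma))
        bw = tuple(sorted({float(d) for d in
                           list(np.arange(0.0, t_end, 7.0)) + [t_end]}))
        return cls(plasma_days=plasma, bw_days=bw, terminal_day=t_end,
                   **kwargs)


def _smoothstep(t: np.ndarray | float, t0: float, t1: float):
    u = np.clip((np.asarray(t, dtype=float) - t0) / (t1 - t0), 0.0, 1.0)
    return 3 * u**2 - 2 * u**3


def _late_rise(t, onset: float = 60.0, end: float = 90.0):
    u = np.clip((np.asarray(t, dtype=float) - onset) / (end - onset), 0, 1)
    return u**2


# group-level latent curves (units as in OBSERVABLE_UNITS)
def _group_curve(group: str, observable: str, t):
    t = np.asarray(t, dtype=float)
    ramp = _smoothstep(t, 0.0, 90.0)
    hdl_ramp = _smoothstep(t, 0.0, 60.0)  # HDL-C rises over months 1-2
    late = _late_rise(t)                  # dyslipidemia appears after day 60
    hf = group in ("HFD", "MetS_non-DLP", "MetS_DLP")
    curves = {
        "body_weight": {
            "LFD": 25 + 3 * ramp, "HFD": 25 + 15 * ramp,
            "MetS_non-DLP": 25 + 17 * ramp, "MetS_DLP": 25 + 18 * ramp},
        "plasma_glucose": {
            "LFD": 7.0 + 0 * t, "HFD": 7.0 + 2.5 * ramp,
            "MetS_non-DLP": 7.0 + 2.5 * ramp,
            "MetS_DLP": 7.0 + 2.5 * ramp},
        "plasma_insulin": {
            "LFD": 0.15 + 0 * t, "HFD": 0.15 + 0.20 * ramp,
            "MetS_non-DLP": 0.15 + 0.20 * ramp,
            "MetS_DLP": 0.15 + 0.20 * ramp + 0.25 * late},
        "plasma_ffa": {
            "LFD": 1.0 + 0 * t, "HFD": 1.0 + 0.2 * ramp,
            "MetS_non-DLP": 1.0 + 0.2 * ramp,
            "MetS_DLP": 1.0 + 0.25 * ramp},
        "plasma_tg": {
            "LFD": 1.0 + 0 * t, "HFD": 1.2 + 0.1 * ramp,
            "MetS_non-DLP": 1.3 + 0.1 * ramp,
            "MetS_DLP": 1.3 + 0.1 * ramp + 3.2 * late},
        "plasma_tc": {
            "LFD": 2.5 + 0 * t, "HFD": 2.8 + 0.4 * ramp,
            "MetS_non-DLP": 3.2 + 0.8 * ramp,
            "MetS_DLP": 3.2 + 0.8 * ramp + 8.0 * late},
        "plasma_hdl_c": {
            "LFD": 1.8 + 0 * t,
            "HFD": 1.8 + 1.2 * hdl_ramp,
            "MetS_non-DLP": 1.8 + 1.2 * hdl_ramp,
            "MetS_DLP": 1.8 + 1.2 * hdl_ramp},
        "liver_tg": {
            "LFD": 15 + 0 * t, "HFD": 15 + 20 * ramp,
            "MetS_non-DLP": 15 + 35 * ramp, "MetS_DLP": 15 + 50 * ramp},
        "liver_fc": {
            "LFD": 7 + 0 * t, "HFD": 7 + 2 * ramp,
            "MetS_non-DLP": 7 + 5 * ramp, "MetS_DLP": 7 + 11 * ramp},
        "liver_ce": {
            "LFD": 3 + 0 * t, "HFD": 3 + 3 * ramp,
            "MetS_non-DLP": 3 + 12 * ramp, "MetS_DLP": 3 + 27 * ramp},
        "dnl_flux": {
            "LFD": 2400 + 0 * t, "HFD": 1800 + 0 * t,
            "MetS_non-DLP": 2000 + 0 * t, "MetS_DLP": 2600 + 0 * t},
    }
    del hf
    return curves[observable][group]


def generate_phenomenological_study(design: StudyDesign | None = None,
                                    seed: int | None = None
                                    ) -> StudyDataset:
    """Per-individual synthetic study data with group aggregation.

    Each animal's value is the group latent curve plus a per-animal
    random offset (constant in time) plus independent measurement
    noise, both Gaussian with the design's noise SDs.  With
    ``noise_scale=0`` every individual lies exactly on its group curve.
    """
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    rows = []
    plasma_obs = ("plasma_glucose", "plasma_insulin", "plasma_ffa",
                  "plasma_tg", "plasma_tc", "plasma_hdl_c")
    terminal_obs = ("liver_tg", "liver_fc", "liver_ce", "dnl_flux")
    for group, size in design.group_sizes.items():
        for i in range(size):
            animal = f"{group}_{i + 1:02d}"
            offsets = {obs: design.noise_scale * design.noise_sd[obs]
                       * rng.normal()
                       for obs in list(plasma_obs) + ["body_weight"]
                       + list(terminal_obs)}

            def record(obs, day):
                latent = float(_group_curve(group, obs, day))
                noise = design.noise_scale * design.noise_sd[obs] \
                    * rng.normal()
                rows.append({
                    "group": group, "animal_id": animal, "day": day,
                    "observable": obs,
                    "value": latent + offsets[obs] + noise,
                    "unit": OBSERVABLE_UNITS[obs]})

            for day in design.plasma_days:
                for obs in plasma_obs:
                    record(obs, day)
            for day in design.bw_days:
                record("body_weight", day)
            terminal_days = ((0.0, design.terminal_day)
                             if design.baseline_liver
                             else (design.terminal_day,))
            for obs in terminal_obs:
                for day in terminal_days:
                    record(obs, day)
    return dataset_from_individuals(pd.DataFrame(rows))


# ----------------------------------------------------------------------
# model-generated ground truth for recovery experiments

@dataclass(eq=False)
class GroundTruth:
    """Hidden truth behind a model-generated dataset."""

    t: np.ndarray                     # daily grid
    params: np.ndarray                # (nt, n_params)
    states: np.ndarray                # (nt, n_pools)
    fluxes: np.ndarray                # (nt, n_fluxes)
    param_names: tuple[str, ...]
    flux_names: tuple[str, ...]

    def flux_series(self, name: str) -> np.ndarray:
        return self.fluxes[:, self.flux_names.index(name)]

    def param_series(self, name: str) -> np.ndarray:
        return self.params[:, self.param_names.index(name)]


def linear_ramp_schedule(base: ParameterSet, name: str, factor: float,
                         t_end: float = 90.0):
    """θ(t) with one parameter ramping linearly from its base value to
    ``factor`` times it over [0, t_end]; all others constant."""
    idx = PARAM_NAMES.index(name)
    base_vec = base.values.copy()

    def schedule(t: float) -> np.ndarray:
        theta = base_vec.copy()
        frac = np.clip(t / t_end, 0.0, 1.0)
        theta[idx] = base_vec[idx] * (1.0 + (factor - 1.0) * frac)
        return theta

    return schedule


def generate_model_ground_truth(model: Model, schedule,
                                group: str = "synthetic",
                                n_individuals: int = 8,
                                noise_frac: float = 0.05,
                                seed: int | None = None,
                                design: StudyDesign | None = None,
                                ) -> tuple[StudyDataset, GroundTruth]:
    """Simulate the model under a time-varying parameter schedule and
    sample noisy observations with the study's sampling layout.

    ``schedule`` maps a time (day) to a full θ vector (see
    :func:`linear_ramp_schedule`).  Observations are Gaussian with SD
    equal to ``noise_frac`` times the true value; ``noise_frac=0``
    reproduces the model outputs exactly.  Returns the dataset and the
    hidden daily truth (states, fluxes, parameters).
    """
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    theta0 = ParameterSet(np.asarray(schedule(0.0), dtype=float))
    x0 = model.steady_state(theta0)
    t_end = design.terminal_day
    t_eval = np.arange(0.0, t_end + 0.5)
    sim = model.simulate(x0, theta0, (0.0, t_end),
                         options=SimOptions(rtol=1e-8, atol=1e-11),
                         t_eval=t_eval, params_fn=schedule)
    truth = GroundTruth(
        sim.t, np.array([schedule(t) for t in sim.t]),
        sim.states, sim.fluxes, tuple(PARAM_NAMES),
        tuple(model.flux_names))

    def observed(day: float) -> dict[str, float]:
        k = int(np.argmin(np.abs(sim.t - day)))
        return model.observe(sim.states[k], fluxes=sim.fluxes[k])

    plasma_obs = ("plasma_glucose", "plasma_insulin", "plasma_ffa",
                  "plasma_tg", "plasma_tc", "plasma_hdl_c")
    terminal_obs = ("liver_tg", "liver_fc", "liver_ce", "dnl_flux")
    rows = []
    for i in range(n_individuals):
        animal = f"{group}_{i + 1:02d}"

        def record(obs, day, y):
            true = y[obs]
            val = true + noise_frac * abs(true) * rng.normal() \
                if noise_frac > 0 else true
            rows.append({"group": group, "animal_id": animal,
                         "day": float(day), "observable": obs,
                         "value": val, "unit": OBSERVABLE_UNITS[obs]})

        for day in design.plasma_days:
            y = observed(day)
            for obs in plasma_obs:
                record(obs, day, y)
        for day in design.bw_days:
            record("body_weight", day, observed(day))
        terminal_days = ((0.0, design.terminal_day)
                         if design.baseline_liver
                         else (design.terminal_day,))
        for obs in terminal_obs:
            for day in terminal_days:
                record(obs, day, observed(day))
    return dataset_from_individuals(pd.DataFrame(rows)), truth
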