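"""Rate laws, simulation and steady states of the whole-body model.

All pools are in µmol per animal (insulin in pmol), time is in days, so
fluxes are µmol/day.  The model describes the *average* daily behaviour
of the metabolic system; no sub-day (postprandial/fasting) dynamics are
represented.  Rate laws are deliberately simple: transport and
conversion steps are first-order mass action ``v = k·S``, dietary
inflows and gluconeogenesis are zero order, and insulin secretion is a
Hill function of plasma glucose.  Insulin action enters as
multiplicative modifiers ``(1 + a·Î)`` (de novo lipogenesis, peripheral
glucose uptake) or ``1/(1 + a·Î)`` (peripheral lipolysis,
gluconeogenesis), with ``Î`` the insulin pool normalized by a reference
pool size.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import (
    POOLS,
    SINKS,
    FluxTable,
    build_flux_table,
)

__all__ = [
    "MetabolicState",
    "ParameterSet",
    "DietInput",
    "ObservationMap",
    "SimOptions",
    "SimResult",
    "Model",
    "NegativePoolError",
    "SimulationError",
    "SteadyStateError",
    "dietary_inflow",
    "default_parameters",
    "reference_state",
    "OBSERVABLE_UNITS",
    "KCAL_PER_G_FAT",
    "KCAL_PER_G_CARB",
    "MW_GLUCOSE",
    "MW_TG",
    "MW_FFA",
    "MW_CHOL",
    "DIET_LFD",
    "DIET_HFD",
    "DIET_HFDC",
]

N_POOLS = len(POOLS)
_POOL_INDEX = {p: i for i, p in enumerate(POOLS)}
_SINK_IDX = np.array([_POOL_INDEX[s] for s in SINKS])
_NONSINK_IDX = np.array([i for i, p in enumerate(POOLS) if p not in SINKS])

# molar masses (g/mol) and macronutrient energy densities (kcal/g)
MW_GLUCOSE = 180.16
MW_TG = 885.4
MW_FFA = 282.5
MW_CHOL = 386.65
KCAL_PER_G_FAT = 9.0
KCAL_PER_G_CARB = 4.0

#: canonical observable names and the units produced by :meth:`Model.observe`
OBSERVABLE_UNITS = {
    "plasma_glucose": "mM",
    "plasma_insulin": "nM",
    "plasma_ffa": "mM",
    "plasma_tg": "mM",
    "plasma_tc": "mM",
    "plasma_hdl_c": "mM",
    "body_weight": "g",
    "liver_tg": "umol/g",
    "liver_fc": "umol/g",
    "liver_ce": "umol/g",
    "dnl_flux": "umol/day",
}


class NegativePoolError(ValueError):
    """A pool size is negative where non-negativity is required."""


class SimulationError(RuntimeError):
    """ODE integration failed; carries the time reached."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(message)
        self.t_fail = t_fail


class SteadyStateError(RuntimeError):
    """Steady-state search did not converge; carries the residual norm."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class MetabolicState:
    """Named view over the pool-size vector (µmol; insulin in pmol)."""

    __slots__ = ("values",)

    def __init__(self, values):
        arr = np.asarray(values, dtype=float)
        if arr.shape != (N_POOLS,):
            raise ValueError(f"expected {N_POOLS} pools, got {arr.shape}")
        self.values = arr

    @classmethod
    def from_dict(cls, pools: dict[str, float],
                  default: float = 0.0) -> "MetabolicState":
        unknown = set(pools) - set(POOLS)
        if unknown:
            raise KeyError(f"unknown pools: {sorted(unknown)}")
        vec = np.full(N_POOLS, default)
        for name, val in pools.items():
            vec[_POOL_INDEX[name]] = val
        return cls(vec)

    def __getitem__(self, pool: str) -> float:
        return float(self.values[_POOL_INDEX[pool]])

    def to_dict(self) -> dict[str, float]:
        return {p: float(v) for p, v in zip(POOLS, self.values)}

    def __repr__(self) -> str:  # pragma: no cover
        body = ", ".join(f"{p}={v:.4g}" for p, v in zip(POOLS, self.values))
        return f"MetabolicState({body})"


def _parameter_names(table: FluxTable) -> tuple[str, ...]:
    names: list[str] = []
    for f in table:
        if f.kind == "mass_action":
            names.append(f"k_{f.name}")
        elif f.kind == "zero_order" and f.diet_key is None:
            names.append(f"k_{f.name}")
    names += ["a_dnl", "a_uptake", "a_lipolysis", "a_gng",
              "i_vmax", "i_kg", "i_hill"]
    return tuple(names)


_CANONICAL_TABLE = build_flux_table()
PARAM_NAMES: tuple[str, ...] = _parameter_names(_CANONICAL_TABLE)
_PARAM_INDEX = {n: i for i, n in enumerate(PARAM_NAMES)}


class ParameterSet:
    """Strictly positive named parameter vector θ.

    Contains one rate constant per parameterized flux (per day, or
    µmol/day for the zero-order gluconeogenesis inflow), the four
    dimensionless insulin-action coefficients and the insulin-secretion
    parameters.  The ordering is fixed (:data:`PARAM_NAMES`) so θ can be
    serialized as a flat vector.
    """

    __slots__ = ("values",)

    names: tuple[str, ...] = PARAM_NAMES

    def __init__(self, values):
        arr = np.asarray(values, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ValueError(
                f"expected {len(PARAM_NAMES)} parameters, got {arr.shape}")
        if not np.all(arr > 0):
            bad = [n for n, v in zip(PARAM_NAMES, arr) if v <= 0]
            raise ValueError(f"parameters must be strictly positive: {bad}")
        self.values = arr

    @classmethod
    def from_dict(cls, params: dict[str, float]) -> "ParameterSet":
        missing = set(PARAM_NAMES) - set(params)
        unknown = set(params) - set(PARAM_NAMES)
        if missing or unknown:
            raise KeyError(
                f"missing parameters: {sorted(missing)}; "
                f"unknown parameters: {sorted(unknown)}")
        return cls([params[n] for n in PARAM_NAMES])

    def __getitem__(self, name: str) -> float:
        return float(self.values[_PARAM_INDEX[name]])

    def to_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(PARAM_NAMES, self.values)}

    def replace(self, **updates: float) -> "ParameterSet":
        d = self.to_dict()
        for k, v in updates.items():
            if k not in d:
                raise KeyError(k)
            d[k] = v
        return ParameterSet.from_dict(d)

    def copy(self) -> "ParameterSet":
        return ParameterSet(self.values.copy())

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ParameterSet":
        return cls.from_dict(json.loads(text))

    def __repr__(self) -> str:  # pragma: no cover
        return f"ParameterSet({self.to_dict()!r})"


@dataclass(frozen=True)
class DietInput:
    """Diet composition driving the zero-order dietary inflows.

    frac_energy_fat/frac_energy_carb are energy fractions; the remainder
    is protein, modeled only as a constant gluconeogenic precursor
    supply (implicit in the gluconeogenesis rate constant).
    """

    food_intake: float  # g/day
    energy_density: float  # kcal/g
    frac_energy_fat: float
    frac_energy_carb: float
    chol_w_frac: float  # g cholesterol per g diet

    def __post_init__(self) -> None:
        if self.food_intake < 0:
            raise ValueError("food_intake must be non-negative")
        if self.energy_density < 0:
            raise ValueError("energy_density must be non-negative")
        for name in ("frac_energy_fat", "frac_energy_carb", "chol_w_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_energy_fat + self.frac_energy_carb > 1.0 + 1e-12:
            raise ValueError("fat + carbohydrate energy fractions exceed 1")


def dietary_inflow(diet: DietInput) -> dict[str, float]:
    """Zero-order dietary inflow rates (µmol/day).

    Fat: ``intake·energy_density·frac_fat/9`` g fat/day converted at
    885.4 g/mol (triglyceride equivalents); carbohydrate analogous with
    4 kcal/g and 180.16 g/mol (glucose equivalents); cholesterol from
    the w/w fraction at 386.65 g/mol.
    """
    fat_g = diet.food_intake * diet.energy_density * diet.frac_energy_fat \
        / KCAL_PER_G_FAT
    carb_g = diet.food_intake * diet.energy_density * diet.frac_energy_carb \
        / KCAL_PER_G_CARB
    chol_g = diet.food_intake * diet.chol_w_frac
    return {
        "carb": carb_g / MW_GLUCOSE * 1e6,
        "fat": fat_g / MW_TG * 1e6,
        "chol": chol_g / MW_CHOL * 1e6,
    }


# default diets of the three-month feeding study: a low-fat diet
# (20% of energy from fat, 3.8 kcal/g) and high-fat diets (60% energy
# from fat, 5.2 kcal/g), the second with 0.25% w/w added cholesterol.
DIET_LFD = DietInput(food_intake=2.5, energy_density=3.8,
                     frac_energy_fat=0.20, frac_energy_carb=0.60,
                     chol_w_frac=0.0001)
DIET_HFD = DietInput(food_intake=2.3, energy_density=5.2,
                     frac_energy_fat=0.60, frac_energy_carb=0.20,
                     chol_w_frac=0.0002)
DIET_HFDC = DietInput(food_intake=2.3, energy_density=5.2,
                      frac_energy_fat=0.60, frac_energy_carb=0.20,
                      chol_w_frac=0.0025)


@dataclass(frozen=True)
class ObservationMap:
    """Maps the model state/fluxes onto the measured phenotype variables.

    With the plasma distribution volume in mL and pools in µmol,
    plasma concentrations come out in µmol/mL = mM (insulin: pmol/mL =
    nM).  Body weight is lean mass plus the adipose TG pool converted
    to gram of fat tissue via the TG mass fraction ``f_tg``.
    """

    plasma_volume_ml: float = 1.0
    liver_weight_g: float = 1.0
    lean_mass_g: float = 22.0
    f_tg: float = 0.8  # mass fraction of TG in adipose tissue

    def __post_init__(self) -> None:
        for name in ("plasma_volume_ml", "liver_weight_g",
                     "lean_mass_g", "f_tg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SimOptions:
    """Integrator settings (stiff-capable LSODA by default)."""

    rtol: float = 1e-6
    atol: float = 1e-9
    method: str = "LSODA"
    max_step: float = math.inf


@dataclass(eq=False)
class SimResult:
    """Sampled solution: states and fluxes on a common time grid."""

    t: np.ndarray                 # (nt,) days
    states: np.ndarray            # (nt, n_pools)
    fluxes: np.ndarray            # (nt, n_fluxes)
    pool_names: tuple[str, ...] = POOLS
    flux_names: tuple[str, ...] = ()

    def state_at(self, t: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.t - t)))
        return self.states[i]

    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()


class Model:
    """The compiled network: evaluates fluxes, derivatives, simulations,
    steady states and the observation map.

    Parameters
    ----------
    flux_table
        Network topology; defaults to :func:`build_flux_table`.
    diet
        Diet driving the zero-order inflows (can be overridden per call).
    obs_map
        Observation map for :meth:`observe`.
    insulin_ref
        Reference insulin pool (pmol) normalizing the insulin signal Î.
    """

    def __init__(self, flux_table: FluxTable | None = None,
                 diet: DietInput = DIET_LFD,
                 obs_map: ObservationMap | None = None,
                 insulin_ref: float = 0.15):
        self.flux_table = flux_table or build_flux_table()
        self.diet = diet
        self.obs_map = obs_map or ObservationMap()
        if insulin_ref <= 0:
            raise ValueError("insulin_ref must be positive")
        self.insulin_ref = insulin_ref
        self._compile()

    # ------------------------------------------------------------------
    def _compile(self) -> None:
        table = self.flux_table
        nf = len(table)
        self.flux_names = table.names
        self.n_fluxes = nf
        # stoichiometry matrix S (pools x fluxes): dx/dt = S @ v
        S = np.zeros((N_POOLS, nf))
        for j, f in enumerate(table):
            for pool, coef in f.stoich.items():
                S[_POOL_INDEX[pool], j] += coef
        self._S = S

        ma_idx, ma_sub, ma_k = [], [], []
        self._diet_idx: dict[str, int] = {}
        self._zero_param: list[tuple[int, int, str | None]] = []
        self._hill_idx = None
        self._mod_idx: dict[str, int] = {}
        for j, f in enumerate(table):
            if f.kind == "mass_action":
                ma_idx.append(j)
                ma_sub.append(_POOL_INDEX[f.substrate])
                ma_k.append(_PARAM_INDEX[f"k_{f.name}"])
                if f.modifier is not None:
                    self._mod_idx[f.modifier] = j
            elif f.kind == "zero_order":
                if f.diet_key is not None:
                    self._diet_idx[f.diet_key] = j
                else:
                    self._zero_param.append(
                        (j, _PARAM_INDEX[f"k_{f.name}"], f.modifier))
            elif f.kind == "hill":
                self._hill_idx = j
        self._ma_idx = np.array(ma_idx)
        self._ma_sub = np.array(ma_sub)
        self._ma_k = np.array(ma_k)
        self._i_pG = _POOL_INDEX["pG"]
        self._i_pI = _POOL_INDEX["pI"]
        self._dnl_j = table.index("dnl")

    # ------------------------------------------------------------------
    def _inflow_vector(self, diet: DietInput) -> np.ndarray:
        v = np.zeros(self.n_fluxes)
        inflows = dietary_inflow(diet)
        for key, j in self._diet_idx.items():
            v[j] = inflows[key]
        return v

    def _fluxes_raw(self, x: np.ndarray, theta: np.ndarray,
                    diet_v: np.ndarray) -> np.ndarray:
        """Flux vector without sign checks; x is clipped at zero."""
        s = np.maximum(x, 0.0)
        v = diet_v.copy()
        v[self._ma_idx] = theta[self._ma_k] * s[self._ma_sub]
        ihat = s[self._i_pI] / self.insulin_ref
        up_dnl = 1.0 + theta[_PARAM_INDEX["a_dnl"]] * ihat
        up_upt = 1.0 + theta[_PARAM_INDEX["a_uptake"]] * ihat
        dn_lip = 1.0 / (1.0 + theta[_PARAM_INDEX["a_lipolysis"]] * ihat)
        dn_gng = 1.0 / (1.0 + theta[_PARAM_INDEX["a_gng"]] * ihat)
        v[self._mod_idx["dnl"]] *= up_dnl
        v[self._mod_idx["uptake"]] *= up_upt
        v[self._mod_idx["lipolysis"]] *= dn_lip
        for j, kidx, modifier in self._zero_param:
            v[j] = theta[kidx]
            if modifier == "gng":
                v[j] *= dn_gng
        pG = s[self._i_pG]
        h = theta[_PARAM_INDEX["i_hill"]]
        kg = theta[_PARAM_INDEX["i_kg"]]
        vmax = theta[_PARAM_INDEX["i_vmax"]]
        v[self._hill_idx] = vmax * pG**h / (kg**h + pG**h)
        return v

    def _jac_raw(self, x: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Analytic Jacobian d(S·v)/dx at a (clipped) state.

        Rate laws are linear in their substrate except for the insulin
        modifiers (which add a pI column) and the Hill secretion term
        (pG column); clipped coordinates contribute zero columns.
        """
        s = np.maximum(x, 0.0)
        active = (x > 0).astype(float)
        Jv = np.zeros((self.n_fluxes, N_POOLS))
        k = theta[self._ma_k]
        Jv[self._ma_idx, self._ma_sub] = k
        i_pI = self._i_pI
        ihat = s[i_pI] / self.insulin_ref
        a_dnl = theta[_PARAM_INDEX["a_dnl"]]
        a_upt = theta[_PARAM_INDEX["a_uptake"]]
        a_lip = theta[_PARAM_INDEX["a_lipolysis"]]
        a_gng = theta[_PARAM_INDEX["a_gng"]]
        table = self.flux_table
        for mod, a in (("dnl", a_dnl), ("uptake", a_upt)):
            j = self._mod_idx[mod]
            f = table.fluxes[j]
            sub = _POOL_INDEX[f.substrate]
            kj = theta[_PARAM_INDEX[f"k_{f.name}"]]
            Jv[j, sub] = kj * (1.0 + a * ihat)
            Jv[j, i_pI] = kj * s[sub] * a / self.insulin_ref
        j = self._mod_idx["lipolysis"]
        f = table.fluxes[j]
        sub = _POOL_INDEX[f.substrate]
        kj = theta[_PARAM_INDEX[f"k_{f.name}"]]
        denom = 1.0 + a_lip * ihat
        Jv[j, sub] = kj / denom
        Jv[j, i_pI] = -kj * s[sub] * a_lip / (self.insulin_ref * denom**2)
        for jz, kidx, modifier in self._zero_param:
            if modifier == "gng":
                kj = theta[kidx]
                dg = 1.0 + a_gng * ihat
                Jv[jz, i_pI] = -kj * a_gng / (self.insulin_ref * dg**2)
        # insulin secretion: Hill in plasma glucose
        pG = s[self._i_pG]
        h = theta[_PARAM_INDEX["i_hill"]]
        kg = theta[_PARAM_INDEX["i_kg"]]
        vmax = theta[_PARAM_INDEX["i_vmax"]]
        if pG > 0:
            num = vmax * h * kg**h * pG**(h - 1.0)
            Jv[self._hill_idx, self._i_pG] = num / (kg**h + pG**h) ** 2
        Jv *= active[np.newaxis, :]
        return self._S @ Jv

    def compute_fluxes(self, state, params: ParameterSet,
                       diet: DietInput | None = None) -> np.ndarray:
        """Flux vector (µmol/day) at a non-negative state.

        Raises :class:`NegativePoolError` naming the first negative pool.
        """
        x = state.values if isinstance(state, MetabolicState) \
            else np.asarray(state, dtype=float)
        if np.any(x < 0):
            bad = POOLS[int(np.argmax(x < 0))]
            raise NegativePoolError(f"negative pool size: {bad}")
        diet = diet or self.diet
        return self._fluxes_raw(x, params.values, self._inflow_vector(diet))

    def fluxes_dict(self, state, params: ParameterSet,
                    diet: DietInput | None = None) -> dict[str, float]:
        v = self.compute_fluxes(state, params, diet)
        return {n: float(val) for n, val in zip(self.flux_names, v)}

    def derivatives(self, state, params: ParameterSet,
                    diet: DietInput | None = None) -> np.ndarray:
        """dState/dt (µmol/day) = stoichiometry · fluxes."""
        return self._S @ self.compute_fluxes(state, params, diet)

    # ------------------------------------------------------------------
    def simulate(self, state0, params: ParameterSet,
                 t_span: tuple[float, float],
                 options: SimOptions | None = None,
                 t_eval: np.ndarray | None = None,
                 diet: DietInput | None = None,
                 params_fn=None) -> SimResult:
        """Integrate the ODE system over ``t_span``.

        ``params_fn(t) -> theta vector`` makes the system non-autonomous
        (time-varying parameters); otherwise ``params`` is used
        throughout.  Inside the integrator the state is clipped at zero
        before evaluating rate laws, so small negative excursions of
        order ``atol`` cannot destabilize the dynamics.
        """
        opts = options or SimOptions()
        diet = diet or self.diet
        diet_v = self._inflow_vector(diet)
        x0 = state0.values if isinstance(state0, MetabolicState) \
            else np.asarray(state0, dtype=float)
        S = self._S
        if params_fn is None:
            theta = params.values

            def rhs(t, x):
                return S @ self._fluxes_raw(x, theta, diet_v)

            def jac(t, x):
                return self._jac_raw(x, theta)
        else:
            def rhs(t, x):
                return S @ self._fluxes_raw(
                    x, np.asarray(params_fn(t), dtype=float), diet_v)

            def jac(t, x):
                return self._jac_raw(
                    x, np.asarray(params_fn(t), dtype=float))

        if t_eval is None:
            t0, t1 = t_span
            n = max(2, int(round(abs(t1 - t0))) + 1)
            t_eval = np.linspace(t0, t1, n)
        sol = solve_ivp(rhs, t_span, x0, method=opts.method,
                        rtol=opts.rtol, atol=opts.atol,
                        max_step=opts.max_step, t_eval=t_eval, jac=jac)
        if not sol.success:
            raise SimulationError(
                f"integration failed at t={sol.t[-1] if len(sol.t) else t_span[0]:.4g}: "
                f"{sol.message}", float(sol.t[-1] if len(sol.t) else t_span[0]))
        states = sol.y.T
        nt = states.shape[0]
        fluxes = np.empty((nt, self.n_fluxes))
        for i in range(nt):
            if params_fn is None:
                th = params.values
            else:
                th = np.asarray(params_fn(sol.t[i]), dtype=float)
            fluxes[i] = self._fluxes_raw(states[i], th, diet_v)
        return SimResult(sol.t, states, fluxes, POOLS, self.flux_names)

    # ------------------------------------------------------------------
    def steady_state(self, params: ParameterSet,
                     diet: DietInput | None = None,
                     guess=None,
                     tol: float = 1e-6,
                     relax_days: float = 1000.0,
                     polish_first: bool = True) -> MetabolicState:
        """Steady state of the non-sink pools.

        The cumulative sinks grow without bound by construction, so the
        steady-state condition applies to the 19 physiological pools
        (sinks are reported as zero).  A Newton polish from ``guess`` is
        attempted first; on failure the system is relaxed by
        ``relax_days`` of integration and polished again.  Convergence
        requires ``‖dx/dt‖₂ < tol·(1 + ‖x‖₂)`` over non-sink pools.
        """
        diet = diet or self.diet
        diet_v = self._inflow_vector(diet)
        theta = params.values
        S_red = self._S[_NONSINK_IDX]

        def f_red(x_red):
            x = np.zeros(N_POOLS)
            x[_NONSINK_IDX] = x_red
            return S_red @ self._fluxes_raw(x, theta, diet_v)

        def jac_red(x_red):
            x = np.zeros(N_POOLS)
            x[_NONSINK_IDX] = x_red
            return self._jac_raw(x, theta)[
                np.ix_(_NONSINK_IDX, _NONSINK_IDX)]

        if guess is None:
            guess = reference_state()
        g = guess.values if isinstance(guess, MetabolicState) \
            else np.asarray(guess, dtype=float)
        if np.any(g[_NONSINK_IDX] <= 0):
            raise ValueError("steady-state guess must be positive")

        def _accept(x_red):
            if np.any(x_red < -1e-9):
                return None
            x_red = np.maximum(x_red, 0.0)
            res = np.linalg.norm(f_red(x_red))
            if res < tol * (1.0 + np.linalg.norm(x_red)):
                full = np.zeros(N_POOLS)
                full[_NONSINK_IDX] = x_red
                return MetabolicState(full)
            return None

        x_red = g[_NONSINK_IDX].copy()
        if polish_first:
            sol = root(f_red, x_red, jac=jac_red, method="hybr")
            out = _accept(sol.x) if sol.success else None
            if out is not None:
                return out
        # relax by integration, then polish
        x_full = np.zeros(N_POOLS)
        x_full[_NONSINK_IDX] = x_red
        sim = self.simulate(x_full, params, (0.0, relax_days),
                            SimOptions(rtol=1e-8, atol=1e-10),
                            t_eval=np.array([0.0, relax_days]), diet=diet)
        x_red = np.maximum(sim.final_state()[_NONSINK_IDX], 1e-12)
        sol = root(f_red, x_red, jac=jac_red, method="hybr")
        out = _accept(sol.x)
        if out is None:
            res = float(np.linalg.norm(f_red(np.maximum(sol.x, 0.0))))
            raise SteadyStateError(
                f"steady state did not converge (residual {res:.3e})", res)
        return out

    # ------------------------------------------------------------------
    def observe(self, state, fluxes=None,
                obs_map: ObservationMap | None = None,
                params: ParameterSet | None = None,
                diet: DietInput | None = None) -> dict[str, float]:
        """Map a state (and fluxes) to the measured phenotype variables.

        ``fluxes`` may be omitted if ``params`` is given, in which case
        they are computed on the fly (needed for ``dnl_flux``).
        """
        m = obs_map or self.obs_map
        x = state.values if isinstance(state, MetabolicState) \
            else np.asarray(state, dtype=float)
        if fluxes is None:
            if params is None:
                raise ValueError("need fluxes or params to observe dnl_flux")
            fluxes = self.compute_fluxes(x, params, diet)
        fluxes = np.asarray(fluxes, dtype=float)
        vp = m.plasma_volume_ml
        lw = m.liver_weight_g
        g = _POOL_INDEX
        fat_g = x[g["aTG"]] * MW_TG * 1e-6 / m.f_tg
        return {
            "plasma_glucose": x[g["pG"]] / vp,
            "plasma_insulin": x[g["pI"]] / vp,
            "plasma_ffa": x[g["pFFA"]] / vp,
            "plasma_tg": (x[g["pTGc"]] + x[g["pTGv"]]) / vp,
            "plasma_tc": (x[g["pCv"]] + x[g["pCh"]]) / vp,
            "plasma_hdl_c": x[g["pCh"]] / vp,
            "body_weight": m.lean_mass_g + fat_g,
            "liver_tg": x[g["hTG"]] / lw,
            "liver_fc": x[g["hFC"]] / lw,
            "liver_ce": x[g["hCE"]] / lw,
            "dnl_flux": float(fluxes[self._dnl_j]),
        }

    def with_diet(self, diet: DietInput) -> "Model":
        return Model(self.flux_table, diet, self.obs_map, self.insulin_ref)

    def with_obs_map(self, obs_map: ObservationMap) -> "Model":
        return Model(self.flux_table, self.diet, obs_map, self.insulin_ref)


# ----------------------------------------------------------------------
# reference parameterization: an approximately balanced healthy state
# under the low-fat diet, constructed so that every pool's inflow equals
# its outflow at the reference pool sizes below.

_REF_POOLS = {
    "lG": 50.0, "lTG": 2.0, "lFC": 1.0, "lBA": 0.5,
    "pG": 8.0, "pI": 0.15, "pFFA": 1.0, "pTGc": 0.2, "pTGv": 0.8,
    "pCv": 0.8, "pCh": 1.8,
    "hG6P": 1.0, "hACoA": 2.0, "hTG": 15.0, "hFC": 7.0, "hCE": 3.0,
    "hBA": 2.0,
    "aTG": 2711.0, "aACoA": 2.0,
    "fecC": 0.0, "fecBA": 0.0, "oxC": 0.0,
}

_DEFAULT_PARAMS = {
    "k_glc_absorption": 158.2,
    "k_tg_absorption": 119.0,
    "k_chol_absorption": 45.0,
    "k_fecal_chol": 5.65,
    "k_fecal_ba": 10.0,
    "k_tice": 12.5,
    "k_biliary_chol": 5.714,
    "k_biliary_ba": 50.0,
    "k_ba_reuptake": 190.0,
    "k_ba_synthesis": 0.7143,
    "k_hep_glc_uptake": 500.0,
    "k_hep_glc_output": 2000.0,
    "k_gng": 3000.0,
    "k_glycolysis": 3500.0,
    "k_dnl": 600.0,
    "k_hep_beta_ox": 3.333,
    "k_chol_synthesis": 90.0,
    "k_acat": 4.286,
    "k_ceh": 10.0,
    "k_hep_fa_uptake": 300.0,
    "k_vldl_tg_secretion": 26.67,
    "k_vldl_c_secretion": 4.286,
    "k_lpl_vldl": 375.0,
    "k_lpl_chylo": 440.0,
    "k_remnant_uptake": 750.0,
    "k_vldl_tg_uptake": 125.0,
    "k_ldl_c_uptake": 50.0,
    "k_cetp": 11.11,
    "k_hdl_production": 7.143,
    "k_hdl_uptake": 16.67,
    "k_per_ffa_uptake": 1464.0,
    "k_per_lipolysis": 0.1476,
    "k_per_beta_ox": 0.10624,
    "k_per_glc_uptake": 369.4,
    "k_acoa_ox_hep": 2810.0,
    "k_acoa_ox_per": 9366.0,
    "k_ins_clearance": 50.0,
    "a_dnl": 1.0,
    "a_uptake": 1.0,
    "a_lipolysis": 1.0,
    "a_gng": 1.0,
    "i_vmax": 15.0,
    "i_kg": 8.0,
    "i_hill": 2.0,
}


def default_parameters() -> ParameterSet:
    """Reference θ, approximately stationary under the low-fat diet."""
    return ParameterSet.from_dict(_DEFAULT_PARAMS)


def reference_state() -> MetabolicState:
    """Reference pool sizes used as steady-state guess."""
    return MetabolicState.from_dict(_REF_POOLS)
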