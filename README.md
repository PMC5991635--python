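# metsim

Whole-body kinetic modeling of glucose, lipid and cholesterol
metabolism, coupled to time-varying parameter estimation (ADAPT) for
longitudinal phenotype data.

## The problem

Metabolic Syndrome develops slowly: a mouse fed a high-fat,
high-cholesterol diet for three months gains weight, becomes glucose
intolerant, and may or may not develop dyslipidemia — and the data
documenting that transition are sparse (monthly plasma samples, weekly
body weights, liver lipids only at sacrifice).  A classical kinetic
model with fixed rate constants can describe a *snapshot* of such a
system but not its slow drift, because the drift lives in the
regulation (gene expression, protein activity) that the rate constants
summarize.  `metsim` is for modelers who want to turn such sparse
longitudinal data into continuous, uncertainty-aware trajectories of
metabolite pools, fluxes and effective rate constants — and to ask
which fluxes must have changed for a phenotype to emerge.

## The model and the method

The model is a set of coupled, nonlinear ODEs over 19 metabolite pools
in four compartments (intestinal lumen, plasma, liver, periphery) plus
cumulative fecal/oxidative sinks, with ~36 fluxes covering dietary
uptake, glycolysis, gluconeogenesis, de novo lipogenesis (DNL),
β-oxidation, cholesterol synthesis and esterification (ACAT/CEH),
lipoprotein assembly and uptake, CETP transfer, trans-intestinal
cholesterol excretion (TICE), biliary secretion and the enterohepatic
bile-acid cycle.  Transport and conversion steps are first-order mass
action v = k·S; insulin is secreted by a Hill function of plasma
glucose and modulates DNL, peripheral glucose uptake, lipolysis and
gluconeogenesis.  The steady state of the ODE system is a metabolic
snapshot; snapshots are fitted by multi-start weighted least squares,

    WSSE = Σᵢ ((ŷᵢ − meanᵢ)/SDᵢ)² ,

with fits below WSSE = 100 considered acceptable.

Slow progression is estimated by re-optimizing the parameters day by
day (ADAPT): the study is discretized into 90 one-day segments, the
data are Monte-Carlo resampled from Normal(mean, SD) and interpolated
with cubic smoothing splines, and each day k solves

    min_θ Σᵢ ((ŷᵢ(t_k) − sᵢ(t_k))/σᵢ(t_k))²
          + λ Σⱼ ((θ_{k,j} − θ_{k−1,j})/θ_ref,j / Δt)² ,    λ = 0.1

warm-started from the previous day, with the one-day simulation of the
model embedded in ŷ.  Repeating this over many resamples yields an
ensemble of trajectory solutions — a virtual population — from which
the best-fitting fraction is selected and summarized (per-day median,
central band, mean), and groups are compared flux by flux.

See `docs/methods.md` for assumptions, parameters, units and numerical
choices.

## Worked example

Recover a known change in dietary cholesterol absorption from noisy
synthetic data.  Ground truth: the absorption rate constant ramps
linearly to 2× over 90 days under a high-cholesterol diet; everything
else is constant.  Observations carry 5% noise at the standard study
layout.

```python
from metsim import Model, default_parameters
from metsim.model import DIET_HFDC
from metsim.adapt import AdaptConfig, run_ensemble
from metsim.analysis import select_top_fraction, summarize
from metsim.synthetic import (StudyDesign, generate_model_ground_truth,
                              linear_ramp_schedule)

model = Model(diet=DIET_HFDC)
theta = default_parameters()
obs = model.observe(model.steady_state(theta), params=theta)
print(f"steady state under HFD+C: glucose {obs['plasma_glucose']:.2f} mM, "
      f"TC {obs['plasma_tc']:.2f} mM, liver TG {obs['liver_tg']:.1f} umol/g")

schedule = linear_ramp_schedule(theta, "k_chol_absorption", 2.0, 90.0)
data, truth = generate_model_ground_truth(
    model, schedule, group="DLP-like", n_individuals=8,
    noise_frac=0.05, seed=1, design=StudyDesign.with_span(90.0))

config = AdaptConfig(
    n_days=90, n_ensemble=10, lam=0.1, seed=0, n_starts_t0=6,
    free_parameters=("k_chol_absorption", "k_dnl", "k_vldl_tg_secretion",
                     "k_ins_clearance", "k_per_glc_uptake",
                     "k_hdl_production"),
    inner_tol=1e-4, max_nfev_step=60)
ensemble = run_ensemble(model, data, config)
summary = summarize(select_top_fraction(ensemble, 0.5),
                    "flux:chol_absorption")
true_flux = truth.flux_series("chol_absorption")
for day in (0, 45, 90):
    print(f"day {day:2d}: median absorption flux "
          f"{summary['median'][day]:7.1f} umol/day "
          f"(truth {true_flux[day]:7.1f})")
```

Output (about a minute on one core):

```
steady state under HFD+C: glucose 4.63 mM, TC 6.12 mM, liver TG 42.4 umol/g
day  0: median absorption flux   117.0 umol/day (truth   117.8)
day 45: median absorption flux   142.6 umol/day (truth   145.4)
day 90: median absorption flux   165.1 umol/day (truth   165.4)
```

The ensemble-median absorption flux tracks the hidden 40% rise to
within a few µmol/day while the non-ramped rate constants stay flat —
the method attributes the plasma-cholesterol rise to the right flux.

The same pipeline is available from the shell:

```sh
metsim synth --seed 3 --out study.csv
metsim calibrate --data study.csv --group HFD --month 2 --starts 500 \
    --seed 7 --out fits.json
metsim adapt --data study.csv --group MetS_DLP --days 90 \
    --ensemble 1000 --lambda 0.1 --seed 11 --out ensemble.csv
metsim analyze --ensemble ensemble.csv --top 0.1 \
    --quantity flux:chol_absorption --out report.csv
```

Every command writes a `*.manifest.json` with the settings, seed and
package version.

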