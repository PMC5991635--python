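# Methods

## The model

`metsim` implements a whole-body kinetic model of glucose, lipid,
cholesterol and bile-acid metabolism for a single animal (a mouse, by
default), together with a trajectory-estimation scheme for slowly
progressing phenotypes.  The model tracks 19 metabolite pools across
four compartments — intestinal lumen (`lG`, `lTG`, `lFC`, `lBA`),
plasma (`pG`, `pI`, `pFFA`, chylomicron TG `pTGc`, (V)LDL TG `pTGv`,
(V)LDL cholesterol `pCv`, HDL cholesterol `pCh`), liver (`hG6P`,
`hACoA`, `hTG`, `hFC`, `hCE`, `hBA`) and periphery (`aTG`, `aACoA`) —
plus three cumulative bookkeeping sinks (fecal cholesterol, fecal bile
acids, oxidized acetyl-CoA).  Pools are in µmol per animal (insulin in
pmol); time is in days.  The ~36 fluxes connecting them cover dietary
uptake, glycolysis, gluconeogenesis, de novo lipogenesis, β-oxidation,
cholesterol synthesis, ACAT/CEH esterification, lipoprotein assembly,
LPL lipolysis, remnant/LDL/HDL uptake, CETP transfer, TICE, biliary
secretion, the enterohepatic bile-acid cycle and fecal excretion.

The model deliberately describes the *average daily* behaviour of the
system: no postprandial or fasting sub-day dynamics exist, which is the
right granularity for a 90-day study with monthly sampling.

### Rate laws

Every transport/conversion step is first-order mass action `v = k·S`.
Dietary inflows and gluconeogenesis are zero order; insulin secretion
is a Hill function of plasma glucose, `Vmax·pG^h/(K_G^h + pG^h)` with
`h = 2` by default.  Insulin action enters through a normalized signal
`Î = pI/pI_ref` as `×(1 + a·Î)` on de novo lipogenesis and peripheral
glucose uptake and `×1/(1 + a·Î)` on peripheral lipolysis and
gluconeogenesis.  This family preserves the network topology and the
character of the estimation problem while remaining fully specified;
it makes no claim to mechanistic saturation kinetics.

Stoichiometric conversions use textbook values at palmitate scale:
3 fatty acids per triglyceride, 8 acetyl-CoA per fatty acid (hence 24
per TG), 18 acetyl-CoA per cholesterol, 2 acetyl-CoA per glucose
through glycolysis.  These fixed factors make class-wise mass balance
an exactly testable identity: e.g. the total cholesterol class
(lumen + liver FC/CE + plasma lipoprotein cholesterol + bile acids +
fecal sinks) changes only through dietary inflow and 1/18 of the
acetyl-CoA drained into synthesis.

### Default parameters and units

The default parameter set was hand-balanced so that a chosen reference
state (plasma glucose 8 mM, TG 1 mM, TC 2.6 mM, HDL-C 1.8 mM, liver TG
15 µmol/g, body weight 25 g, …) is an exact steady state under the
low-fat diet (2.5 g/day at 3.8 kcal/g, 20% energy from fat).  The
plasma distribution volume is 1.0 mL, liver weight 1.0 g, lean mass
22 g, adipose TG mass fraction 0.8 — all configurable through
`ObservationMap`.  Dietary inflows convert intake to µmol/day using
9 kcal/g fat (molar mass 885.4), 4 kcal/g carbohydrate (180.16) and
the w/w cholesterol fraction (386.65).  These defaults are synthetic
reference values in physiologically plausible ranges, not measurements.

### Numerics

The ODE system is stiff (plasma FFA turns over in minutes, adipose TG
in months), so integration uses LSODA with an analytic Jacobian
(rel/abs tolerances 1e-6/1e-9 by default; the Jacobian is exact for
the rate-law family and verified against finite differences).  Inside
the integrator the state is clipped at zero before evaluating rate
laws, so negative excursions of order `atol` cannot destabilize the
dynamics; the public flux evaluation rejects negative pools with an
error naming the pool.  Steady states apply to the 19 physiological
pools (the sinks grow without bound by construction): a Newton polish
from the supplied guess is tried first, falling back to 1,000 days of
relaxation plus a second polish; convergence requires
`‖dx/dt‖ < 1e-6·(1 + ‖x‖)`.

## Snapshot calibration

A phenotype snapshot is the per-group mean ± SD of the measured
variables at one time point.  The model's steady state is fitted by
weighted least squares, `WSSE = Σ((ŷ−mean)/SD)²`, with multi-start
optimization: initial parameters are drawn log-uniformly over
10⁻¹–10¹ times the reference values (500 starts by default) and each
start runs trust-region-reflective least squares on log-parameters,
which enforces positivity by construction.  Fits with WSSE strictly
below 100 count as acceptable.  Observables with zero or missing SD
receive an effective SD of 10% of the mean (configurable); replicate
counts do not enter the weights.

## Trajectory estimation (ADAPT)

Long-term progression is estimated with ADAPT-style time-varying
parameters.  The study span is discretized into `n_days` one-day
segments (90 for the three-month study).  For each Monte-Carlo
replicate:

1. every (group, observable, day) mean is resampled from
   Normal(mean, SD);
2. each resampled series is interpolated with a cubic smoothing spline
   (weighted by 1/SD² so one smoothing parameter acts on standardized
   residuals; `None` selects it by generalized cross-validation, which
   requires ≥5 points — 4-point monthly series fall back to the natural
   interpolating cubic, i.e. the interpolation limit, and 2–3-point
   series to lower-degree interpolants).  Outside the observed range
   curves extend as constants, and per-day SD curves are linear
   interpolations of the data SDs;
3. the day-0 state is obtained by snapshot calibration to the resampled
   t = 0 data;
4. for each day k the parameters minimize

       Σ_i ((ŷ_i(t_k) − s_i(t_k))/σ_i(t_k))²
       + λ·Σ_j ((θ_{k,j} − θ_{k−1,j})/θ_ref,j / Δt)²

   where ŷ is the model output after simulating one day from the
   previous day's end state (the data term is evaluated at the segment
   endpoint), θ_ref is the day-0 estimate (a running-θ alternative is
   available), Δt = 1 day, and λ = 0.1 by default.  The optimizer is
   warm-started at θ_{k−1}; on failure θ_{k−1} is carried with a
   warning flag.

Repeating this for `n_ensemble` resamples (1,000 by default) yields a
virtual population of trajectory solutions.  Members are ranked by
their total WSSE against the *original* data at the observation days;
the analysis layer keeps the best fraction (top 10% by default) and
summarizes quantities by the per-day median with a central 10%
inter-quantile band (45th–55th percentiles — one reasonable reading of
"10% range around the median"; configurable) plus the mean curve.

Observables measured at a single time point cannot be interpolated;
they act as anchors that enter the cost only at that day.  Because an
anchor switching on at the terminal day would kick the parameters, the
synthetic study designs report liver lipids and DNL at baseline as
well (the standard device of using control-group values as the initial
liver state), making them two-point linear targets.

### Inner-optimizer details that matter

The per-day problems are solved by trust-region-reflective least
squares on log-parameters with an explicit finite-difference step of
1e-3.  The explicit step is load-bearing: the default (~1e-8 relative)
perturbations fall below the ODE integrator's tolerance noise floor,
which turns numerical Jacobians into noise — symptoms were randomly
frozen days followed by catch-up jumps and tiny non-monotonicities in
the λ-sweep.  Tolerances of 1e-4 on the inner solves are enough for
ensemble work; the regularization sweep uses 1e-9 because it compares
penalties across λ directly.

## Synthetic data

`generate_phenomenological_study` emulates the structure of the
three-month feeding study: LFD (n=8), HFD (n=12) and a
high-fat/high-cholesterol cohort of 8 that splits into 5
non-dyslipidemic and 3 dyslipidemic individuals; monthly plasma
sampling, weekly body weight, terminal (and baseline) liver lipids and
DNL.  Group-level latent curves encode the qualitative patterns —
logistic-like weight gain on high-fat diets, HDL-C rising over the
first two months, and a TG/TC surge beginning after day 60 only in the
dyslipidemic subgroup, with elevated terminal insulin.  Individuals
get a constant random offset plus independent measurement noise; the
default noise SDs keep the day-90 TG/TC split cleanly bimodal.  What
these data do *not* contain: real measurement values, within-animal
autocorrelated noise, dropout, or diet-composition effects beyond
those the curves encode — so passing tests demonstrates correct
machinery and recoverability, not biological validity.

`generate_model_ground_truth` simulates the model itself under a
prescribed time-varying parameter schedule, samples noisy observations
at the study layout, and returns the hidden daily truth (states,
fluxes, parameters) for scoring.

## Canned experiments

The validation experiments (`metsim.experiments`) estimate a reduced
free set of six rate constants — cholesterol absorption, DNL, VLDL-TG
secretion, insulin clearance, peripheral glucose uptake, HDL
production — one per subsystem with a directly informative observable;
all other parameters are held at their generating values.  This keeps
the scaled-down problems identifiable: an earlier draft freed LDL-C
uptake instead, which is nearly collinear with absorption in
explaining a plasma-cholesterol rise and drifted accordingly.

* **Recovery**: 2× linear ramp in the absorption rate constant under
  the high-cholesterol diet, 5% observation noise, 50-member ensemble
  over 90 days.  Scored on monotonicity and endpoint accuracy of the
  ensemble-median absorption flux and flatness of the non-ramped
  parameter medians.
* **Phenotype contrast**: dyslipidemic-like (ramped absorption) vs
  non-dyslipidemic-like (constant) synthetic groups, compared on their
  day-90 median absorption flux.
* **Regularization sweep**: one fixed resample of a *stationary*
  dataset (constant true parameters, 30 days, 6 plasma samplings, 25%
  CV noise — the large inter-animal variability typical of plasma
  lipids and insulin in high-fat cohorts — and strong standardized
  spline smoothing, lam=1000) fitted at
  λ ∈ {0, 0.01, 0.1, 1, 10, 10³} with identical resampling draws.  The
  total squared-derivative penalty decreases with λ, and at λ = 10³
  daily parameter motion is pinned below 1%.  A stationary truth is
  used because the sweep characterizes the regularizer's response to
  sampling noise; ramped truths belong to the recovery experiment.
  Note the freeze threshold scales like
  elasticity·(residual/σ)/σ_frac/(2λ): under tight noise (a few percent
  CV) the data term legitimately overpowers λ = 10³ for parameters
  with elasticity near one, and daily motion settles around 1–2%.

## Known limitations

- The rate-law family is intentionally minimal; saturation and
  allosteric effects are absorbed into the time-varying parameters.
- Insulin kinetics are a phenomenological secretion/clearance submodel;
  its pools are fitted, not mechanistically derived.
- Plasma (V)LDL cholesterol is one lumped pool (free + esterified);
  hepatic FC and CE are separate because ACAT/CEH are explicit.
- The per-day data term uses segment endpoints only; sub-day target
  tracking is not attempted.
- Full-θ estimation (44 parameters) works but is slow and weakly
  identified from seven plasma/weight observables; the provided
  experiments use the reduced free set above.
- Ensemble members are independent; no cross-member shrinkage or
  hierarchical pooling is applied.
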