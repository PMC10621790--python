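# Methods

This note documents the models, numerical choices and known limitations of
`warfarin_mipd`. It is the package's own account of its science; every number
quoted here is either a configured default or something the test suite and
`scripts/acceptance.py` recompute.

## The clinical-trial model

Simulated trials are generated by a five-component clinical-trial (CT) model.
The components are deliberately modular: each can be replaced without touching
the others.

### 1. Mechanistic core (`dynamics`, `engine`)

A reduced warfarin PKPD model stands in for a full coagulation-network
description, with the same interface and qualitative behaviour (nonlinearity,
a multi-day response delay, vitamin-K coupling):

* **PK** — one-compartment disposition with first-order absorption:
  `da_d/dt = -ka a_d + r(t)`, `da_c/dt = ka a_d - ke a_c`, concentration
  `C = a_c / V`. Doses are instantaneous boluses into the dose compartment.
* **PD** — C inhibits the production input of a transit chain of clotting
  activity via `E(C) = 1 - C^g / (EC50^g + C^g)`:
  `dA_1/dt = ktr (eta E(C) - A_1)`, `dA_i/dt = ktr (A_{i-1} - A_i)`,
  `ktr = n_transit / MTT`. The daily multiplier `eta` is the vitamin-K
  input analogue.
* **Readout** — `INR = inr_base + inr_max * max(0, 1 - A_n)^lam`.

Defaults (hours, mg, L): `ka=1.0/h`, `ke=0.018/h`, `V=14 L`, `gamma=1.2`,
`n_transit=3`, `MTT=40 h`, `inr_base=1`, `inr_max=19`, `lam=2`,
`EC50=1.8083 mg/L`.

Two calibration choices deserve comment:

* **EC50** is set by a one-dimensional root solve so that the reference
  patient (CYP2C9 \*1\*1, VKORC1 GG, age 71) reaches a steady-state trough
  INR of 2.5 at 5 mg/day — the conventional average maintenance dose.
* **`lam=2` (quadratic response shape).** With a linear readout (`lam=1`)
  the INR is proportional to the depletion of the activity chain, so the
  configured 10% day-to-day variation of the vitamin-K input would swing the
  drug-free INR up to ~3 — drug-free INR must stay near 1 under ordinary
  dietary variation. The quadratic shape suppresses small baseline
  excursions (INR stays within a few percent of baseline without drug)
  while leaving the treated dose-response curve steep and nonlinear
  (1 mg→1.06, 3 mg→1.6, 5 mg→2.5, 8 mg→4.1, 12 mg→6.3 at steady state).

Even with `lam=2` the reduced core transmits inter-occasion variability to
the INR more strongly than a buffered coagulation network would: at the
therapeutic target a 10% vitamin-K day moves the INR by roughly ±0.5. All
dosing agents face identical conditions, so agent *comparisons* are
meaningful, but absolute success rates sit below what a stiffer mechanistic
core would produce, and no quantitative agreement with any specific
coagulation-network model is claimed.

**Integration.** `simulate_response` is the reference path: scipy's LSODA
with event-aware segmentation at dose times and day boundaries
(rtol 1e-6, atol 1e-8 by default). All cohort-scale work (trial protocols,
fit likelihood, RL emulator, regimen optimisation) runs on a vectorised
fixed-step RK4 engine (`engine.CohortEngine`, default step 0.5 h; the fit
and the dosing agents use 1–2 h). The system is non-stiff — the fastest
rate is `ka = 1/h` — and the two paths agree to ≤2e-4 INR in the tests. The
engine supports per-patient clock times, so execution delays are integrated
exactly, not interpolated.

### 2. Population model (`population`)

Nonlinear mixed effects. Covariates act multiplicatively on the typical
values: CYP2C9 scales `ke` (\*1\*1 1.0 … \*3\*3 0.20), VKORC1 scales `EC50`
(GG 1.0, GA 0.60, AA 0.35), and age scales `ke` linearly by −1%/year around
age 71. Unexplained IIV is lognormal with `omega` 0.25 on `ke`, 0.30 on
`EC50`, 0.20 on `MTT`, 0.10 on `V`. Default demographics: VKORC1 in
Hardy–Weinberg proportions with A-allele frequency 0.40; CYP2C9 \*1\*1 0.65
down to \*3\*3 0.02; age ~ round(Normal(65, 10)) truncated to [18, 100].
The multipliers preserve the qualitative covariate structure (variant
alleles increase sensitivity / decrease clearance); they are configuration,
not literature claims.

### 3–5. Stochastic layers (`stochastic`)

* **Inter-occasion variability** — one `eta ~ Normal(1, 0.1^2)` per
  simulation day, floored at 0.05 to keep the input positive. The floor is
  a numerical guard; at the default parameters it is hit with negligible
  probability.
* **Execution variability** — exponential delays with mean 30 min added to
  every nominal dosing and monitoring time. A dose and a measurement
  sharing a nominal time share one delay draw. Dose *amounts* are not
  perturbed. Datasets record nominal times by default
  (`trials.report_actual_times` flips this), mirroring how clinical data
  are usually recorded; simulation always uses the actual times.
* **Measurement noise** — lognormal with median equal to the model output
  and scale 0.1, i.e. ~10% proportional error.

Missed doses/measurements and covariate measurement error are not modelled.

## Trial protocols (`protocols`)

Day `k` spans `[24k, 24(k+1))` h; dose `j` is nominally at `24(j-1)` h; the
INR "just before" a dose shares its nominal (and actual) time and is
processed first.

* **Phase I** — 60 patients, one 10 mg dose, concentration samples at
  nominal 10/35/60 h.
* **Phase II** — 100 patients, 21 daily doses. Induction 10/7.5/5 mg;
  the 4th dose (day 3) and the doses on days 5, 7 and 13 are reset by the
  linear heuristic `d_j = d_{j-1} y*/y_j` from the same-day measurement;
  between adjustments the last dose repeats (adjustments are not continued
  after day 13). INR measured on days 0,1,2,3,5,7,13,20 (day 0 pre-dose).
  Three consecutive measurements above INR 5 discontinue a patient.
* **Phase III** — 1000 patients, 56 days; phase-II schedule plus
  adjustments on days 27 and 34, constant dose for the last three weeks.
  The recorded dataset keeps only the day-55 INR and the maintenance dose.
* **MIPD trial** — 19 days, daily INR before each dose, target
  `y* = 2.5`, no safety stop. A dosing agent receives covariates and the
  recorded monitoring data (never the patient's true parameters), and may
  keep per-patient state within a trial (used for warm starts).

Doses are rounded to 0.5 mg and capped at 30 mg/day throughout.

## The three dosing agents

### Regression (`regression`)

A fully connected network (11 features → 1024 → 1024 → 1; ReLU; sigmoid
output scaled to [0, 30] mg) regresses the phase-III maintenance dose on
one-hot genotypes, standardised age and the achieved day-55 INR; at
prediction time the target INR is substituted. Trained with Adam
(lr 1e-3, batch 64, ≤500 epochs, 90/10 split, early-stopping patience 50)
on mean squared error of the dose normalised by the cap. The output layer
is initialised with small weights and a bias at the logit of the mean
normalised dose; a wide He-initialised sigmoid head otherwise saturates and
stops learning. The policy is static: every trial day gets the same dose.

### Deep RL (`deeprl`)

Double DQN over 58 discrete doses (0–28.5 mg in 0.5 mg steps). State =
latest INR + covariate features (Markov assumption). Network
11 → 256 → 128 → 64 → 58, ReLU. Reward `-|INR_{t+1} - y*|`, maximal on
target. Trained online against an emulator — the fitted population PKPD
model with measurement noise but without execution delays or IOV (the
fitted model carries neither) — using an experience-replay buffer (50k),
epsilon decaying 1.0→0.05 over the first 80% of episodes, target-network
sync every 500 updates, Adam lr 1e-4. Episodes run in vectorised batches of
32 patients.

The delayed INR response (mean transit time 40 h against a 24 h
action–reward interval) leaves many doses with near-identical value, so a
plain one-step DQN produces greedy dose functions with small seed-dependent
wiggles. Three standard variance-reduction devices address this: 3-step
returns credit each dose with the discounted rewards of the following days;
the returned policy reads a Polyak-averaged (EMA, tau 0.999) copy of the
online network; and the final agent averages the Q-surfaces of three
independently trained runs. With these, 3 × 6000 episodes (~4 min on one
CPU) yield dose functions that are non-increasing in the measured INR
across the therapeutic region for the common genotypes. Under-exploration
artefacts can still appear above the region a genotype's patients actually
visit during training — the same failure mode that makes value-based RL
risky for strong responders. Trial evaluation always uses the full CT
model.

### Bayesian PKPD (`pkpd`)

The MIPD-internal model is the same reduced PKPD structure (an optional
`misspecify` switch is reserved for robustness studies). Three stages:

1. **Population fit** — hierarchical Bayesian inference for
   `(tv_ke, tv_EC50, omega_ke, omega_EC50, sigma)` with per-patient
   standard-normal random effects (non-centred parameterisation); covariate
   multipliers and the remaining structural parameters are conditioned on
   at their configured values, which keeps the reduced phase-I/II designs
   identifiable. Priors are weakly informative lognormals centred on the
   configured values (SD 0.5 in log space; omegas centred at 0.2, sigma at
   0.1). The sampler alternates (a) an adaptive-covariance Metropolis
   update of the population block, (b) elementwise Metropolis updates of
   all patients' random effects in one vectorised pass, and (c)
   likelihood-invariant interweaving moves that translate a typical value
   (or rescale an omega) while adjusting the random effects to keep every
   individual's parameters fixed — these break the funnel correlation
   between levels of the hierarchy and cost no likelihood evaluations.
   Split-R-hat and ESS come from arviz; R-hat ≥ 1.05 flags the posterior
   and warns rather than failing silently.
2. **Individual MAP fit** — the posterior-mean population model plus the
   patient's covariates form the prior; the two random effects are
   optimised gradient-free (a 7×7 coarse grid over ±1.5 prior SDs followed
   by shrinking 5×5 refinement grids, all evaluated as vectorised batches;
   warm starts skip the coarse stage). With no data the MAP equals the
   subpopulation typical value.
3. **Regimen optimisation** — a self-contained minimal CMA-ES (rank-one +
   rank-mu updates, candidates projected onto [0, 30] mg) minimises
   `sum_t (INR_pred(t) - y*)^2` over the remaining daily doses, with the
   already-administered regimen fixed. The state after the administered
   regimen is integrated once and cached; candidates only simulate the
   future horizon. Degenerate objectives (no achievable drug effect) fall
   back to an all-zero regimen. Inside the daily trial loop the optimiser
   warm-starts from the previous day's solution shifted by one day and uses
   a reduced iteration budget (15 iterations, population 8); stand-alone
   calls default to 200 iterations.

## Outcome metrics (`metrics`, `dataset`)

Per patient: maintenance INR (last-day measurement — the noisy measurement,
since that is what a trial records), peak INR (largest measurement), TTR
(fraction of scheduled measurements inside the therapeutic range, default
[2, 3] with target 2.5). Cohort success rate = fraction of patients whose
maintenance INR lies in the range. Datasets are directories of three CSV
tables (covariates / measurements / doses, fixed column orders) plus JSON
metadata recording trial name, seed and config hash.

## Problem sizes and runtime

The defaults are chosen for a single CPU. The acceptance pipeline simulates
phases I/II at protocol size (60/100), phase III at 300 patients, fits the
population model with 2 chains × (250 warmup + 500 draws), trains the DQN
for 6000 episodes, and compares the three agents on one 100-patient cohort;
the whole pipeline completes in roughly a quarter hour. The test suite uses
a 30-patient fit (3 chains × 1000 draws) and a 50-patient three-agent
trial. Protocol-size phase-III cohorts (N=1000) simulate in seconds; only
the Bayesian fit and the PKPD agent's daily re-optimisation are expensive.

## What passing tests do and do not show

The synthetic cohorts emulate genotype-driven sensitivity differences,
unexplained lognormal IIV, daily vitamin-K fluctuation, schedule slippage
and proportional measurement error. They do not emulate adherence failures,
drug–drug interactions, time-varying covariates, genotyping error, or the
buffering of a full coagulation network. Passing tests therefore
demonstrate that each component implements its stated contract, that every
agent outperforms the untreated stub, and that the Bayesian PKPD agent
attains the highest success rate and TTR — not that any specific clinical
percentage would be reproduced in practice. Notably, in this model the deep
RL agent's success rate falls below the regression agent's: the strong
transmission of daily vitamin-K variation into the INR makes the
latest-measurement state very noisy, so the feedback policy dithers between
doses while the regression agent's constant covariate-based dose averages
through the noise. Which monitoring-based strategy wins is therefore a
property of the variability regime, not of the method per se.

## Known limitations

* The hierarchical fit treats IOV and execution variability as extra
  measurement noise (its sigma estimate inflates accordingly on realistic
  data); parameters whose random effects are not modelled (MTT, V) are
  conditioned on their typical values.
* MAP-based dosing inherits the usual bias of plug-in predictions for
  nonlinear responses; a full posterior-predictive dosing mode is exposed
  as a flag idea but not implemented.
* CMA-ES inside the trial loop runs on a small budget; its stand-alone
  optimum is verified against brute force only on low-dimensional toys.
* The SBML import hook validates the dependency and interface but does not
  yet translate SBML models.
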