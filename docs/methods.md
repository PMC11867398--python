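# Methods

`leadchel` implements an early health-economic evaluation of screening
kidney transplant recipients (KTR) for high-normal plasma lead and treating
the high-tertile patients with oral DMSA chelation, compared against
standard of care. This note documents the model, its assumptions, the
synthetic data conditions, and the numerical and design choices.

## Decision problem and model structure

The core is a five-state, time-inhomogeneous Markov cohort model with
one-year cycles over a 40-year (lifetime) horizon:

* **FG1** — first functioning graft (all 10,000 hypothetical KTR enter here);
* **GF1** — first graft failure: dialysis, retransplantation still possible;
* **FG2** — second functioning graft (after retransplantation);
* **GF2** — second graft failure: dialysis until death (at most two
  transplants; a third is rare enough to exclude);
* **Death** — absorbing; reached from every living state.

Three survival endpoints drive the transitions: graft failure (GF, fitted
per lead tertile), death with functioning graft (DWFG) and death with graft
failure (DwGF), both fitted on the whole cohort. Annual transition
probabilities come from the fitted survival curves via

    tp_i = 1 − S(i) / S(i−1),  i = 1 … 40 (years).

Retransplantation from GF1 occurs with annual probability 0.15 up to age
65, declining linearly to zero at age 80 (both ages configurable); each
retransplant has a 0.7% chance of primary non-function (GF1→GF2).
Trapezoidal half-cycle correction is applied to state-membership quantities
(upkeep costs, dialysis costs, QALYs); one-off event costs (graft-failure
initiation, transplantation, death) are counted at the event cycle,
uncorrected — the standard trapezoidal convention.

### Numerical choices in the engine

* **Competing transitions within a cycle**: the death probability is applied
  first; the remaining transitions are scaled by the survival complement so
  every row of the implicit transition matrix sums to one exactly. The model
  is silent otherwise; proportional scaling is the least-informative choice.
* **Second-graft clock**: FG2 occupancy is tracked per retransplantation
  cycle (tunnel bookkeeping) and its failure probability is indexed on years
  since the second transplant — a reset clock, consistent with
  transplant-vintage logic. DWFG/DwGF remain indexed on time since model
  start, because they were fitted on the whole cohort from baseline.
* **Tail exhaustion**: if a survival curve underflows to zero before the
  horizon, the conditional transition probability is set to 1 with a logged
  warning; past the tabulated grid the last value is reused.
* **Cohort age** is `baseline_age + cycle`; baseline 53 years (configurable;
  the source cohort's exact age structure is not public).
* The engine is validated against an individual-level microsimulation with
  identical per-cycle probabilities (tests only; the production model is the
  cohort model).

## Survival estimation

Seven candidate families — exponential, Weibull, Gompertz, gamma,
lognormal, log-logistic, generalized gamma — are fitted to right-censored
data by maximum likelihood (scipy optimizers on transformed parameters; log
transform enforces positivity). Confidence intervals come from the
observed-information Hessian on the transformed scale and are mapped back.
Ranking is by AIC with BIC reported alongside; a configurable override maps
endpoints to families, standing in for the expert-informed, visual-inspection
part of model selection (GF: lognormal; DWFG and DwGF: gamma, shape/rate
parameterization). The generalized gamma uses the three-parameter
(mu, sigma, Q) form; |Q| < 1e−6 is treated as the lognormal limit.
Unadjusted, group-stratified fits only: covariate adjustment is out of
scope, and externally estimated parameters can be injected through the
`survival_params` config block, which bypasses fitting entirely.

## Synthetic cohort

The generator emulates a single-centre cohort of 670 KTR:

* **Plasma lead** is lognormal, moment-matched so the theoretical median is
  0.31 µg/L and the quartile ratio matches the 0.22–0.45 µg/L IQR
  (sdlog = ln(q75/q25) / (2·Φ⁻¹(0.75)) ≈ 0.53). Tertile boundaries default
  to the distribution's theoretical tertiles; the upper one lands at
  ≈0.38 µg/L — exactly the clinical eligibility threshold. The matched
  lognormal reproduces the low/medium tertile means (≈0.19 and 0.31 µg/L)
  but its upper tail is lighter than the source cohort's (high-tertile mean
  ≈0.58 rather than 0.65 µg/L); none of the economics depends on the lead
  values beyond the tertile assignment.
* **Event times**: graft failure is lognormal per tertile with synthetic
  truth meanlog 4.2 / 3.8 / 3.0 (low / medium / high) and common sdlog 1.8
  — ten-year graft survival ≈0.85 / 0.78 / 0.64, a hazard gradient of the
  size reported for high-normal lead. DWFG is gamma(1.1, 0.04)
  (≈2–3%/year late mortality with a functioning graft) and DwGF
  gamma(1.0, 0.15) (median survival on dialysis ≈5 years). These values
  were chosen once for clinical plausibility; the real cohort's fitted
  parameters are not public, so headline magnitudes (ΔC, CEAC, VOI) are not
  expected to reproduce any particular published figures — the pipeline is
  exercised under its own stated conditions.
* **Censoring** is administrative at 10 years (recruitment ≈2008–2011 with
  follow-up to ≈2020); no loss-to-follow-up process. GF, DWFG and DwGF are
  independent latent times per patient, because each endpoint is fitted
  separately and their correlation is unspecified.

What passing tests therefore show: the estimation, engine, economics and
uncertainty machinery are correct against closed-form and simulation
oracles under these conditions. What they do not show: calibration to the
real cohort (covariate-adjusted hazards, competing-risk correlation, the
true lead–hazard dose response).

## Intervention strategy

Base case: every incident KTR is screened once at entry (blood draw €15.00
+ lead assay €50.63); the eligible high-tertile patients (lead strictly
above 0.38 µg/L) receive one DMSA course (€570.95); a monitoring blood test
opens year 2 and 60% receive a repeated course; from year 6, surviving
initially-eligible patients are re-screened every 5 years and 10% are
re-treated. Treated patients carry the medium-tertile graft-failure risk
from cycle 2 onwards (the chelation year is cycle 1; effect onset is
configurable); re-exposed patients are assumed detected and re-treated
within the screening cycle, so re-exposure changes costs but never the
occupied risk stratum. Second and third first-year courses (scenarios that
enable them) each cost a DMSA course plus one monitoring blood test. Safety
measures add an iron lab (€26.39) and/or AST/ALT lab (€5.38) per
administered course, and optionally oral iron supplementation (€46.48 per
8 weeks, scaled by the prescribed weeks). All 26 scenario rows ship in
`data/scenarios.yaml`; the re-exposure columns are encoded as a delay to
the first follow-up screen plus an interval between screens.

## Economics

Societal costs = health-state-related + screening/treatment-related +
productivity losses; the payer perspective drops the last category.

* Dialysis (GF states) costs the modality-weighted
  0.80·113,142.50 + 0.04·106,344.10 + 0.08·109,863.60 + 0.08·94,756.94
  = €111,137.41/year; functioning-graft upkeep €14,376.98/year; one-off
  costs: graft-failure initiation €2,818.80, transplantation €103,993.68,
  death €1,392.03 (all EUR 2022).
* Utilities: functioning graft 0.81; graft failure is the HD/PD-weighted
  0.84·0.56 + 0.16·0.58 = 0.5632; death 0. The 84/16 utility split is kept
  independent of the 80/4/8/8 cost-side modality mix, exactly as the source
  inputs print them.
* Productivity losses use the friction-cost method (85-day friction period,
  8-hour days, sex-mixed wage 0.6·€28.45 + 0.4·€24.70): job loss at graft
  failure (difference of working shares between post-transplant and
  dialysis states by age band), hospital absence at retransplantation
  (50/50 living/deceased donor mix over 13.30/7.80 days — the source split
  is not public), and a friction period at death before 65, using the
  working share of the state the death occurred from. Ages below 45 use the
  45–54 band.
* Discounting: costs 4%/year, effects 1.5%/year, first cycle undiscounted
  (factor (1+r)^−(t−1)); both rates configurable.
* ICER = ΔC/ΔE with dominance labels when the signs make the ratio
  misleading.

## Sensitivity analysis

DSA sets one parameter at a time to its 95% CI bounds (CI width / 3.92 as
the implied SE; parameters without a published CI get an SE of 25% of the
value), plus a −50% / ×2 DMSA-price scenario, and ranks parameters by
output swing for the tornado (top 15 by default). PSA (10,000 iterations)
draws beta for utilities and working percentages (moments matched to mean
and CI), gamma for all costs, and normal for course numbers, hospital days,
the retransplantation and primary-non-function probabilities, and the
survival parameters (from their fitted CIs). Normal draws for probabilities
are truncated to [0,1] and positive quantities to (0,∞), with the clip rate
logged; counts are not rounded (the cohort model is continuous). Survival
parameters are drawn independently — no covariance matrix is available —
which understates their joint uncertainty; flagged as a limitation.

## Budget impact

Five-year, payer-perspective, dynamic national cohort: prevalence 12,068,
incidence 957/year. Year 1 screens prevalent + incident; later years screen
each incident cohort at entry. Prevalent patients enter distributed over
graft age using the alive distribution of the standard-of-care model
(steady-state reading), with each lead tertile holding its one-third share
of the alive prevalent population so that a third of all KTR is eligible;
a naive all-new-graft mode (`mode="inception"`) is provided for comparison.
Prevalent high-tertile patients are treated in calendar year 1 and carry
medium-tertile risk from year 2 at their current graft age.

## Value of information

All measures are computed from the PSA sample on incremental net benefit
INB = WTP·ΔE − ΔC and reported in €/KTR (population value divided by the
10,000 cohort; per-eligible-KTR values are three times larger).

* **EVPI** = mean(max(0, INB)) − max(0, mean(INB)).
* **EVPPI** uses the single-loop nonparametric-regression estimator: INB is
  regressed on the subset's draws with an additive cubic-spline basis
  (5 knots per parameter) and the EVPI formula is applied to the fitted
  conditional mean. Fitted values are **cross-fitted** (5-fold out-of-fold
  predictions): in-sample smoother wiggle otherwise masquerades as
  decision-relevant signal and biases EVPPI upward, noticeably so when the
  decision is nearly certain. Estimates remain Monte-Carlo noisy at the
  ±few × sd(INB)/√n level, so the EVPPI ≤ EVPI ordering holds up to that
  error, not exactly.
* **EVSI** simulates, per PSA iteration, a prospective graft-failure
  follow-up study of n KTR (split between the medium and high tertiles,
  10-year follow-up, lognormal event times from that iteration's meanlog/
  sdlog draws), summarizes it by each arm's event fraction and mean log
  observed time, and regresses INB on the four summaries; evaluated on the
  grid n ∈ {0, 100, 250, 500, 1000}.

## Problem sizes and reproducibility

Default analysis sizes: cohort n = 670, Markov cohort 10,000 × 40 cycles,
PSA 10,000 iterations, EVSI grid to n = 1,000. A full model evaluation runs
in milliseconds; the complete acceptance computation takes about a minute.
Every stochastic stage draws a named 31-bit child seed from the master seed
(recorded in the run manifest) so a configuration + seed pair reproduces
outputs byte for byte.

## Known limitations

* Synthetic truth is stylized: independent latent endpoint times, no
  covariates, administrative censoring only, lead tail lighter than the
  source distribution.
* Under the default synthetic conditions the fitted tertile separation is
  large relative to its uncertainty, so the probability of
  cost-effectiveness is near 1 and VOI values are small; with externally
  supplied survival parameters (the `survival_params` bypass) the same
  machinery propagates whatever uncertainty those carry.
* Survival-parameter PSA draws ignore within-model correlation.
* Utilities are not age-adjusted; no inflation machinery (inputs are taken
  as EUR 2022); no market-uptake ramping in the budget impact.
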