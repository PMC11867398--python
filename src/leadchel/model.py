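"""End-to-end deterministic model: inputs -> traces -> incremental result.

``ModelInputs`` bundles everything one model evaluation needs: the fitted
(or supplied) survival parameters for the three endpoints, Markov settings,
costs, utilities, productivity and discounting inputs.  ``run_cea`` runs
both arms — standard of care and the screening/chelation strategy — on
identical parameters and returns the incremental result, which is the unit
of work for the deterministic and probabilistic sensitivity analyses.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

from . import survival as sv
from .econ import (CEAResult, CostInputs, DiscountRates,
                   ProductivityInputs, UtilityInputs, compute_icer,
                   evaluate_arm)
from .markov import GROUPS, MarkovTrace, ModelParameters, run_cohort
from .strategy import (InterventionCosting, StrategySpec, build_overlay,
                       intervention_costs_per_cycle)


@dataclass
class SurvivalParamSet:
    """One endpoint's chosen family with point estimates and uncertainty."""

    family: str
    params: dict[str, float]
    se: dict[str, float] = field(default_factory=dict)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    @classmethod
    def from_fit(cls, fit: sv.ParametricFit) -> "SurvivalParamSet":
        return cls(family=fit.family, params=dict(fit.params),
                   se=dict(fit.se), ci=dict(fit.ci))


@dataclass
class SurvivalInputs:
    """Chosen survival models: graft failure per lead tertile, two deaths."""

    gf: dict[str, SurvivalParamSet]
    dwfg: SurvivalParamSet
    dwgf: SurvivalParamSet

    def tp_dict(self, horizon: int):
        tp_gf = {g: sv.tp_series(s.family, s.params, horizon)
                 for g, s in self.gf.items()}
        tp_dwfg = sv.tp_series(self.dwfg.family, self.dwfg.params, horizon)
        tp_dwgf = sv.tp_series(self.dwgf.family, self.dwgf.params, horizon)
        return tp_gf, tp_dwfg, tp_dwgf


@dataclass
class ModelInputs:
    survival: SurvivalInputs
    costs: CostInputs = field(default_factory=CostInputs)
    utilities: UtilityInputs = field(default_factory=UtilityInputs)
    productivity: ProductivityInputs = field(default_factory=ProductivityInputs)
    rates: DiscountRates = field(default_factory=DiscountRates)
    intervention_costing: InterventionCosting = field(default_factory=InterventionCosting)
    group_mix: dict[str, float] = field(
        default_factory=lambda: {g: 1.0 / 3.0 for g in GROUPS})
    p_retransplant_base: float = 0.15
    age_decline_start: float = 65.0
    age_decline_zero: float = 80.0
    p_primary_nonfunction: float = 0.007
    baseline_age: float = 53.0
    horizon: int = 40
    cohort_size: float = 10_000.0

    def copy(self) -> "ModelInputs":
        return copy.deepcopy(self)

    def markov_parameters(self, horizon: int | None = None) -> ModelParameters:
        horizon = horizon or self.horizon
        tp_gf, tp_dwfg, tp_dwgf = self.survival.tp_dict(horizon)
        return ModelParameters(
            tp_gf=tp_gf, tp_dwfg=tp_dwfg, tp_dwgf=tp_dwgf,
            p_retransplant_base=self.p_retransplant_base,
            age_decline_start=self.age_decline_start,
            age_decline_zero=self.age_decline_zero,
            p_primary_nonfunction=self.p_primary_nonfunction,
            baseline_age=self.baseline_age,
            horizon=horizon, cohort_size=self.cohort_size,
        )


@dataclass
class ModelRun:
    """Traces and the incremental result of one two-arm evaluation."""

    result: CEAResult
    trace_intervention: MarkovTrace
    trace_soc: MarkovTrace
    group_traces_intervention: dict[str, MarkovTrace]
    group_traces_soc: dict[str, MarkovTrace]
    intervention_costs: object  # per-cycle undiscounted € array


def effective_rates(inputs: ModelInputs, strategy: StrategySpec) -> DiscountRates:
    rc = strategy.disc_costs if strategy.disc_costs is not None else inputs.rates.costs
    re = strategy.disc_effects if strategy.disc_effects is not None else inputs.rates.effects
    return DiscountRates(costs=rc, effects=re)


def run_cea(inputs: ModelInputs, strategy: StrategySpec | None = None,
            perspective: str = "societal") -> ModelRun:
    """Run both arms and compute ΔC, ΔE and the ICER (or dominance label)."""
    if strategy is None:
        strategy = StrategySpec()
    horizon = strategy.horizon or inputs.horizon
    rates = effective_rates(inputs, strategy)
    params = inputs.markov_parameters(horizon)

    trace_soc, groups_soc = run_cohort(params, inputs.group_mix)
    overlay = build_overlay(params.tp_gf, strategy)
    trace_int, groups_int = run_cohort(params, inputs.group_mix, overlay=overlay)

    iv_costs = intervention_costs_per_cycle(
        groups_int, strategy, inputs.intervention_costing, inputs.cohort_size)

    arm_int = evaluate_arm(trace_int, inputs.costs, inputs.utilities,
                           inputs.productivity, rates,
                           intervention_costs=iv_costs,
                           baseline_age=inputs.baseline_age)
    arm_soc = evaluate_arm(trace_soc, inputs.costs, inputs.utilities,
                           inputs.productivity, rates,
                           intervention_costs=None,
                           baseline_age=inputs.baseline_age)
    result = compute_icer(arm_int, arm_soc, perspective=perspective)
    return ModelRun(result=result,
                    trace_intervention=trace_int, trace_soc=trace_soc,
                    group_traces_intervention=groups_int,
                    group_traces_soc=groups_soc,
                    intervention_costs=iv_costs)


def fit_survival_inputs(cohort_df, horizon: int = 40,
                        overrides: dict[str, str] | None = None,
                        families=sv.FAMILIES) -> tuple[SurvivalInputs, dict]:
    """Fit all families per endpoint on a cohort table and select models.

    ``overrides`` maps endpoint names (``GF``, ``DWFG``, ``DwGF``) to family
    names, mirroring expert-informed selection; the default forces the
    base-case choices (lognormal graft failure, gamma deaths).  Returns the
    chosen :class:`SurvivalInputs` plus the full ranked fit lists per
    endpoint/group for inspection.
    """
    if overrides is None:
        overrides = {"GF": "lognormal", "DWFG": "gamma", "DwGF": "gamma"}
    all_fits: dict[str, list[sv.ParametricFit]] = {}

    gf_sets: dict[str, SurvivalParamSet] = {}
    for g in GROUPS:
        sub = cohort_df[cohort_df["group"] == g]
        fits = sv.fit_all_families(sub["time_gf"].to_numpy(),
                                   sub["event_gf"].to_numpy(dtype=bool),
                                   endpoint="GF", group=g, families=families)
        ranked, chosen = sv.select_model(fits, override=overrides.get("GF"))
        all_fits[f"GF:{g}"] = ranked
        gf_sets[g] = SurvivalParamSet.from_fit(chosen)

    death_sets = {}
    for endpoint, tcol, ecol in (("DWFG", "time_dwfg", "event_dwfg"),
                                 ("DwGF", "time_dwgf", "event_dwgf")):
        fits = sv.fit_all_families(cohort_df[tcol].to_numpy(),
                                   cohort_df[ecol].to_numpy(dtype=bool),
                                   endpoint=endpoint, group="all",
                                   families=families)
        ranked, chosen = sv.select_model(fits, override=overrides.get(endpoint))
        all_fits[endpoint] = ranked
        death_sets[endpoint] = SurvivalParamSet.from_fit(chosen)

    inputs = SurvivalInputs(gf=gf_sets, dwfg=death_sets["DWFG"],
                            dwgf=death_sets["DwGF"])
    return inputs, all_fits
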