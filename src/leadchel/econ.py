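"""Costs, QALYs, productivity losses, and the incremental result.

Societal-perspective totals are the sum of three categories per arm:

* health-state-related: transplant upkeep while a graft functions, dialysis
  while in graft failure (modality-mix weighted), plus one-off costs at
  graft failure, retransplantation, and death;
* screening/treatment-related: the intervention cascade (zero under
  standard of care);
* productivity losses by the friction-cost method, attached to the
  transition events (job loss at graft failure, hospital stay at
  retransplantation, death before retirement age).

State-membership quantities (upkeep, dialysis, QALYs) use the trapezoidal
half-cycle-corrected occupancies; one-off quantities use the event flows at
the cycle of the event.  Costs discount at 4%/year and effects at 1.5%/year
by default, with the first cycle undiscounted (factor ``(1+r)^-(t-1)``).
The payer perspective simply excludes productivity losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markov import FG1, FG2, GF1, GF2, MarkovTrace


@dataclass
class CostInputs:
    gf_initial: float = 2_818.80
    dialysis_chd: float = 113_142.50
    dialysis_hhd: float = 106_344.10
    dialysis_apd: float = 109_863.60
    dialysis_capd: float = 94_756.94
    modality_mix: tuple[float, float, float, float] = (0.80, 0.04, 0.08, 0.08)
    transplantation: float = 103_993.68
    transplant_upkeep_annual: float = 14_376.98
    death_oneoff: float = 1_392.03

    def __post_init__(self):
        if abs(sum(self.modality_mix) - 1.0) > 1e-9:
            raise ValueError("modality_mix must sum to 1")

    @property
    def dialysis_weighted(self) -> float:
        """Modality-mix-weighted annual dialysis cost."""
        mix = self.modality_mix
        return (mix[0] * self.dialysis_chd + mix[1] * self.dialysis_hhd
                + mix[2] * self.dialysis_apd + mix[3] * self.dialysis_capd)


@dataclass
class UtilityInputs:
    u_fg: float = 0.81
    u_hd: float = 0.56
    u_pd: float = 0.58
    hd_share: float = 0.84
    pd_share: float = 0.16
    u_death: float = 0.0

    def __post_init__(self):
        if abs(self.hd_share + self.pd_share - 1.0) > 1e-9:
            raise ValueError("hd_share + pd_share must equal 1")
        for u in (self.u_fg, self.u_hd, self.u_pd):
            if not 0.0 <= u <= 1.0:
                raise ValueError("utilities must lie in [0, 1]")

    @property
    def u_gf(self) -> float:
        """Dialysis-modality-weighted graft-failure utility."""
        return self.hd_share * self.u_hd + self.pd_share * self.u_pd


@dataclass
class ProductivityInputs:
    """Friction-cost inputs.  Working fractions by age band (45-54, 55-64, 65+);
    ages below 45 use the 45-54 values (documented fallback)."""

    work_posttx: list[float] = field(default_factory=lambda: [0.57, 0.41, 0.061])
    work_dialysis: list[float] = field(default_factory=lambda: [0.32, 0.19, 0.028])
    hospital_days_living: float = 13.30
    hospital_days_deceased: float = 7.80
    living_donor_share: float = 0.50
    friction_days: float = 85.0
    hours_per_day: float = 8.0
    wage_male: float = 28.45
    wage_female: float = 24.70
    male_fraction: float = 0.60
    retirement_age: float = 65.0

    @property
    def wage(self) -> float:
        return (self.male_fraction * self.wage_male
                + (1.0 - self.male_fraction) * self.wage_female)

    @property
    def hospital_days(self) -> float:
        return (self.living_donor_share * self.hospital_days_living
                + (1.0 - self.living_donor_share) * self.hospital_days_deceased)

    def _band(self, age: float) -> int:
        if age < 55:
            return 0      # <45 falls back to the 45-54 band
        if age < 65:
            return 1
        return 2

    def posttx_share(self, age: float) -> float:
        return self.work_posttx[self._band(age)]

    def dialysis_share(self, age: float) -> float:
        return self.work_dialysis[self._band(age)]


@dataclass
class DiscountRates:
    costs: float = 0.04
    effects: float = 0.015

    def __post_init__(self):
        if self.costs < 0 or self.effects < 0:
            raise ValueError("discount rates must be non-negative")


def discount(value, rate: float, cycle) -> np.ndarray | float:
    """Present value at the stated cycle: ``value / (1+rate)**(cycle-1)``.

    Cycle 1 is undiscounted by convention.
    """
    cycle = np.asarray(cycle)
    if (cycle < 1).any():
        raise ValueError("cycle must be >= 1")
    return value / (1.0 + rate) ** (cycle - 1)


def _cycles(trace: MarkovTrace) -> np.ndarray:
    return np.arange(1, trace.n_cycles + 1)


def state_costs(trace: MarkovTrace, costs: CostInputs,
                rate: float = 0.04) -> np.ndarray:
    """Discounted health-state-related cost per cycle (length n_cycles)."""
    hc = trace.half_cycle
    fg = hc[:, FG1] + hc[:, FG2]
    gf = hc[:, GF1] + hc[:, GF2]
    per_cycle = fg * costs.transplant_upkeep_annual + gf * costs.dialysis_weighted
    gf_events = trace.flows["gf1_events"][1:] + trace.flows["gf2_events"][1:]
    deaths = trace.flows["death_fg"][1:] + trace.flows["death_gf"][1:]
    per_cycle = (per_cycle
                 + gf_events * costs.gf_initial
                 + trace.flows["retransplant"][1:] * costs.transplantation
                 + deaths * costs.death_oneoff)
    return discount(per_cycle, rate, _cycles(trace))


def qalys(trace: MarkovTrace, utilities: UtilityInputs,
          rate: float = 0.015) -> np.ndarray:
    """Discounted QALYs per cycle (half-cycle corrected occupancies)."""
    hc = trace.half_cycle
    fg = hc[:, FG1] + hc[:, FG2]
    gf = hc[:, GF1] + hc[:, GF2]
    per_cycle = fg * utilities.u_fg + gf * utilities.u_gf
    return discount(per_cycle, rate, _cycles(trace))


def productivity_losses(trace: MarkovTrace, prod: ProductivityInputs,
                        baseline_age: float = 53.0,
                        rate: float = 0.04) -> np.ndarray:
    """Discounted friction-cost productivity losses per cycle.

    Job loss at graft failure (difference in working shares between the
    post-transplant and dialysis states over one friction period), hospital
    absence at retransplantation, and a friction period at death before the
    retirement age (working share of the state the death occurred from).
    """
    n = trace.n_cycles
    hours = prod.hours_per_day
    wage = prod.wage
    out = np.zeros(n)
    for t in range(1, n + 1):
        age = baseline_age + t
        gf_events = trace.flows["gf1_events"][t] + trace.flows["gf2_events"][t]
        loss = gf_events * max(prod.posttx_share(age) - prod.dialysis_share(age), 0.0) \
            * prod.friction_days * hours * wage
        loss += trace.flows["retransplant"][t] * prod.dialysis_share(age) \
            * prod.hospital_days * hours * wage
        if age < prod.retirement_age:
            loss += trace.flows["death_fg"][t] * prod.posttx_share(age) \
                * prod.friction_days * hours * wage
            loss += trace.flows["death_gf"][t] * prod.dialysis_share(age) \
                * prod.friction_days * hours * wage
        out[t - 1] = loss
    return discount(out, rate, np.arange(1, n + 1))


@dataclass
class ArmResult:
    """Discounted totals for one arm (cohort-level, EUR / QALY)."""

    health_state: float
    screening_treatment: float
    productivity: float
    qalys: float

    @property
    def total_societal(self) -> float:
        return self.health_state + self.screening_treatment + self.productivity

    @property
    def total_payer(self) -> float:
        return self.health_state + self.screening_treatment

    def total(self, perspective: str = "societal") -> float:
        if perspective == "societal":
            return self.total_societal
        if perspective == "payer":
            return self.total_payer
        raise ValueError("perspective must be 'societal' or 'payer'")


@dataclass
class CEAResult:
    intervention: ArmResult
    standard_of_care: ArmResult
    delta_c: float
    delta_e: float
    icer: float | None
    dominance: str      # dominant | dominated | tradeoff | indifferent
    perspective: str = "societal"


def evaluate_arm(trace: MarkovTrace,
                 costs: CostInputs,
                 utilities: UtilityInputs,
                 prod: ProductivityInputs,
                 rates: DiscountRates,
                 intervention_costs: np.ndarray | None = None,
                 baseline_age: float = 53.0) -> ArmResult:
    """Discounted category totals and QALYs for one arm's trace."""
    hs = state_costs(trace, costs, rates.costs).sum()
    q = qalys(trace, utilities, rates.effects).sum()
    pl = productivity_losses(trace, prod, baseline_age, rates.costs).sum()
    st = 0.0
    if intervention_costs is not None:
        cyc = np.arange(1, trace.n_cycles + 1)
        st = discount(intervention_costs[1:trace.n_cycles + 1], rates.costs, cyc).sum()
    return ArmResult(health_state=float(hs), screening_treatment=float(st),
                     productivity=float(pl), qalys=float(q))


def compute_icer(intervention: ArmResult, soc: ArmResult,
                 perspective: str = "societal") -> CEAResult:
    """Incremental result: ΔC, ΔE, the ICER or a dominance label."""
    dc = intervention.total(perspective) - soc.total(perspective)
    de = intervention.qalys - soc.qalys
    if dc < 0 and de > 0:
        dominance = "dominant"
    elif dc > 0 and de < 0:
        dominance = "dominated"
    elif dc == 0 and de == 0:
        dominance = "indifferent"
    else:
        dominance = "tradeoff"
    icer = dc / de if de != 0 else None
    return CEAResult(intervention=intervention, standard_of_care=soc,
                     delta_c=float(dc), delta_e=float(de),
                     icer=icer, dominance=dominance, perspective=perspective)
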