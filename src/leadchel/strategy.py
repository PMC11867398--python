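"""Screening / chelation strategy overlays and intervention costing.

The intervention is: screen every incident kidney-transplant recipient's
plasma lead once at entry; treat those above the eligibility threshold
(the high tertile, > 0.38 µg/L) with oral DMSA; monitor with a blood test at
the start of year 2 and re-treat a fraction; re-screen the surviving
initially-eligible patients for re-exposure on a fixed interval (every
5 years from year 6 in the base case) and re-treat the re-exposed fraction.

Treated patients carry the medium-tertile graft-failure risk from the
effect-onset cycle onwards (effect of lowering the lead burden from high to
medium); re-exposed patients are assumed detected and re-treated within the
screening cycle, so only costs change.  The standard-of-care arm accrues no
screening or treatment costs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .markov import MarkovTrace


@dataclass
class InterventionCosting:
    """Unit costs (EUR 2022) of the screening / chelation cascade."""

    blood_draw: float = 15.00
    lead_lab: float = 50.63
    iron_lab: float = 26.39
    ast_alt_lab: float = 5.38
    dmsa_course: float = 570.95
    iron_supplement: float = 46.48      # per supplement_unit_weeks of oral iron
    supplement_unit_weeks: float = 8.0

    @property
    def screening_bt(self) -> float:
        """One screening blood test: draw plus lead lab."""
        return self.blood_draw + self.lead_lab


@dataclass
class StrategySpec:
    """One scenario row: strategy knobs plus horizon/discounting overrides."""

    label: str = "BC"
    horizon: int | None = None            # None -> model horizon (lifetime)
    disc_costs: float | None = None       # None -> global default (4%)
    disc_effects: float | None = None     # None -> global default (1.5%)
    screening_bt: bool = True
    eligibility_threshold: float = 0.38
    c1: float = 1.0                       # course fractions among eligible, year 1
    c2: float = 0.0
    c3: float = 0.0
    monitoring_bt_year2: bool = True
    repeated_fraction_year2: float = 0.60
    safety_iron_check: bool = False
    safety_iron_supplement_weeks: float = 0.0
    safety_liver_check: bool = False
    reexposure_delay: int | None = 5      # years after year 1 until first re-screen
    reexposure_interval: int = 5
    reexposure_fraction: float = 0.10
    effect_onset_cycle: int = 2

    def __post_init__(self):
        for f in (self.c1, self.c2, self.c3, self.repeated_fraction_year2,
                  self.reexposure_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.reexposure_delay is not None and self.reexposure_interval < 1:
            raise ValueError("re-exposure interval must be >= 1 year")

    def reexposure_cycles(self, horizon: int) -> list[int]:
        """Model cycles at which follow-up re-exposure screening happens."""
        if self.reexposure_delay is None:
            return []
        cycles = []
        t = 1 + self.reexposure_delay
        while t <= horizon:
            cycles.append(t)
            t += self.reexposure_interval
        return cycles


def eligibility(lead: float | np.ndarray, threshold: float = 0.38):
    """Eligible for chelation iff lead strictly exceeds the threshold."""
    return np.asarray(lead) > threshold


def build_overlay(tp_gf: dict[str, np.ndarray], spec: StrategySpec) -> dict:
    """Graft-failure-series overlay for the intervention arm.

    The treated high group keeps its own series up to the effect-onset cycle
    and uses the medium-group series from then on; a second graft after
    treatment carries medium risk throughout (its clock restarts after
    the treatment effect is in place).
    """
    high = np.asarray(tp_gf["high"], dtype=float)
    med = np.asarray(tp_gf["medium"], dtype=float)
    onset = spec.effect_onset_cycle
    composite = np.concatenate([high[: onset - 1], med[onset - 1:]])
    return {"high": {"tp_fg1": composite, "tp_fg2": med}}


def intervention_costs_per_cycle(
    group_traces: dict[str, MarkovTrace],
    spec: StrategySpec,
    costing: InterventionCosting,
    cohort_size: float,
) -> np.ndarray:
    """Undiscounted screening/treatment cost at each cycle (index = cycle).

    Cycle 1 screens the whole entering cohort and administers the first-year
    courses to the eligible (high) group; cycle 2 monitors the eligible
    survivors and re-treats ``repeated_fraction_year2`` of them; each
    re-exposure screening cycle tests all surviving initially-eligible
    patients and re-treats the re-exposed fraction.  Safety measures (iron /
    liver labs, oral iron supplementation) add per administered course.
    Survivor counts are taken at the start of the cycle in question.
    """
    high = group_traces["high"]
    n_cycles = high.n_cycles
    alive_high = high.alive                 # boundary 0..n
    eligible0 = alive_high[0]

    costs = np.zeros(n_cycles + 1)
    courses = np.zeros(n_cycles + 1)        # administered per cycle (for safety)

    if not spec.screening_bt:
        return costs

    bt = costing.screening_bt

    # Year 1: screen everyone, treat the eligible group.
    costs[1] += bt * cohort_size
    first_year_courses = eligible0 * (spec.c1 + spec.c2 + spec.c3)
    costs[1] += costing.dmsa_course * first_year_courses
    # each 2nd/3rd course needs its own monitoring blood test within year 1
    costs[1] += bt * eligible0 * (spec.c2 + spec.c3)
    courses[1] = first_year_courses

    # Year 2: monitoring blood test and repeated course for a fraction.
    if n_cycles >= 2 and spec.monitoring_bt_year2:
        survivors = alive_high[1]
        costs[2] += bt * survivors
        repeated = spec.repeated_fraction_year2 * survivors
        costs[2] += costing.dmsa_course * repeated
        courses[2] = repeated

    # Re-exposure screenings.
    for t in spec.reexposure_cycles(n_cycles):
        survivors = alive_high[t - 1]
        costs[t] += bt * survivors
        retreated = spec.reexposure_fraction * survivors
        costs[t] += costing.dmsa_course * retreated
        courses[t] += retreated

    # Safety measures per administered course.
    per_course = 0.0
    if spec.safety_iron_check:
        per_course += costing.iron_lab
        if spec.safety_iron_supplement_weeks > 0:
            per_course += (costing.iron_supplement
                           * spec.safety_iron_supplement_weeks
                           / costing.supplement_unit_weeks)
    if spec.safety_liver_check:
        per_course += costing.ast_alt_lab
    if per_course > 0.0:
        costs += per_course * courses

    return costs


# ---------------------------------------------------------------------------
# Scenario table
# ---------------------------------------------------------------------------

def load_scenarios(path=None) -> dict[str, StrategySpec]:
    """Load the scenario table (label -> StrategySpec); ships with 26 rows."""
    if path is None:
        text = resources.files("leadchel").joinpath("data/scenarios.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out: dict[str, StrategySpec] = {}
    for row in raw["scenarios"]:
        spec = StrategySpec(**row)
        out[spec.label] = spec
    return out
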