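"""Five-year national budget impact (healthcare payer perspective).

A dynamic cohort: the prevalent kidney-transplant population (12,068 in the
Netherlands) is in the model at year 1 and a new incident cohort (957/year)
enters every year.  Screening covers everyone alive in year 1 (prevalent +
incident) and each later year's incident entrants; roughly a third
(the high lead tertile) is eligible for chelation.  Costs are
health-state-related plus screening/treatment-related (productivity is
excluded under the payer perspective), discounted at the cost rate with
year 1 undiscounted.  The budget impact is the intervention arm's yearly
total minus standard of care's.

Prevalent patients are distributed over graft age using the alive
distribution of the standard-of-care cohort model (a steady-state reading
of a dynamic national cohort); ``mode="inception"`` instead puts everyone
at the first cycle with a fresh graft, for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .econ import state_costs
from .markov import EngineState, MarkovTrace, run_group
from .model import ModelInputs
from .strategy import StrategySpec, build_overlay


@dataclass
class PopulationSpec:
    prevalence: float = 12_068.0
    incidence: float = 957.0
    horizon: int = 5

    def __post_init__(self):
        if self.prevalence < 0 or self.incidence < 0:
            raise ValueError("population counts must be non-negative")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1 year")


@dataclass
class BIAResult:
    table: pd.DataFrame          # category x arm x year (EUR)
    budget_impact: np.ndarray    # per year, intervention - standard of care
    total: float

    def year_total(self, arm: str, year: int) -> float:
        sub = self.table[(self.table["arm"] == arm)]
        return float(sub[f"year_{year}"].sum())


def _piecewise_run(mass: float, init: EngineState | None, start_cycle: int,
                   n_cycles: int, params, tp_fg1_first, tp_fg2_first,
                   tp_fg1_rest, tp_fg2_rest, switch_after: int) -> MarkovTrace:
    """Run ``switch_after`` cycles on the first tp set, the rest on the second.

    Used for the intervention arm: treated patients stay on their original
    (high-tertile) graft-failure risk during the treatment year and carry
    the medium-tertile risk afterwards.
    """
    if switch_after <= 0 or switch_after >= n_cycles:
        tp1 = tp_fg1_first if switch_after >= n_cycles else tp_fg1_rest
        tp2 = tp_fg2_first if switch_after >= n_cycles else tp_fg2_rest
        return run_group(mass, n_cycles, params, tp1, tp2,
                         start_cycle=start_cycle, init=init)
    first, snaps = run_group(mass, switch_after, params, tp_fg1_first,
                             tp_fg2_first, start_cycle=start_cycle, init=init,
                             record_snapshots=True)
    rest = run_group(0.0, n_cycles - switch_after, params, tp_fg1_rest,
                     tp_fg2_rest, start_cycle=start_cycle + switch_after,
                     init=snaps[-1])
    occ = np.vstack([first.occupancy, rest.occupancy[1:]])
    flows = {k: np.concatenate([first.flows[k], rest.flows[k][1:]])
             for k in first.flows}
    return MarkovTrace(occupancy=occ, flows=flows, cohort_size=first.cohort_size)


def _prevalent_pool(inputs: ModelInputs, params, mode: str):
    """(group, graft_age) -> (weight, EngineState snapshot of alive patients)."""
    pool = []
    if mode == "inception":
        for g, frac in inputs.group_mix.items():
            pool.append((g, 0, frac, None))
        return pool
    if mode != "steady_state":
        raise ValueError("mode must be 'steady_state' or 'inception'")
    for g, frac in inputs.group_mix.items():
        trace, snaps = run_group(frac, params.horizon, params,
                                 params.tp_gf[g], params.tp_gf[g],
                                 record_snapshots=True)
        alive = trace.alive
        for a in range(1, params.horizon + 1):
            if alive[a] <= 0:
                continue
            snap = snaps[a].copy()
            scale = 1.0 / alive[a]     # alive patients only, unit mass
            snap.fg1 *= scale
            snap.gf1 *= scale
            snap.gf2 *= scale
            snap.dead = 0.0
            snap.fg2_by_entry = snap.fg2_by_entry * scale
            pool.append((g, a, alive[a], snap))
    # graft-age distribution within each tertile follows the survival curve,
    # but each tertile keeps its share of the (alive) prevalent population —
    # a third of prevalent KTR is eligible, matching the incident mix
    group_total = {g: sum(w for gg, _, w, _ in pool if gg == g)
                   for g in inputs.group_mix}
    return [(g, a, inputs.group_mix[g] * w / group_total[g], s)
            for g, a, w, s in pool]


def run_bia(inputs: ModelInputs, strategy: StrategySpec | None = None,
            population: PopulationSpec | None = None,
            mode: str = "steady_state") -> BIAResult:
    """National five-year budget impact of adopting the screening strategy."""
    strategy = strategy or StrategySpec()
    population = population or PopulationSpec()
    ny = population.horizon
    params = inputs.markov_parameters()
    overlay = build_overlay(params.tp_gf, strategy)
    cost_rate = inputs.rates.costs
    disc = 1.0 / (1.0 + cost_rate) ** np.arange(ny)
    iv = inputs.intervention_costing
    bt = iv.screening_bt
    courses_y1 = strategy.c1 + strategy.c2 + strategy.c3
    # safety add-ons are per administered course, so fold them into the
    # effective course cost
    per_course = 0.0
    if strategy.safety_iron_check:
        per_course += iv.iron_lab
        if strategy.safety_iron_supplement_weeks > 0:
            per_course += (iv.iron_supplement * strategy.safety_iron_supplement_weeks
                           / iv.supplement_unit_weeks)
    if strategy.safety_liver_check:
        per_course += iv.ast_alt_lab
    course_cost = iv.dmsa_course + per_course

    hs = {"soc": np.zeros(ny), "int": np.zeros(ny)}     # health-state-related
    st = {"soc": np.zeros(ny), "int": np.zeros(ny)}     # screening/treatment

    def add_state_costs(arm: str, trace: MarkovTrace, first_year: int):
        undisc = state_costs(trace, inputs.costs, rate=0.0)
        for k, c in enumerate(undisc):
            y = first_year + k
            if y <= ny:
                hs[arm][y - 1] += c * disc[y - 1]

    # --- prevalent population -------------------------------------------
    pool = _prevalent_pool(inputs, params, mode)
    prev_alive_y1 = 0.0
    high_alive = np.zeros(ny + 1)    # boundary counts of treated-eligible prevalents
    for g, a, w, snap in pool:
        mass = population.prevalence * w
        init = None
        if snap is not None:
            init = snap.copy()
            init.fg1 *= mass
            init.gf1 *= mass
            init.gf2 *= mass
            init.fg2_by_entry = init.fg2_by_entry * mass
        prev_alive_y1 += mass
        # standard of care
        tr = run_group(mass, ny, params, params.tp_gf[g], params.tp_gf[g],
                       start_cycle=a, init=init)
        add_state_costs("soc", tr, 1)
        # intervention: high group switches to medium risk after year 1
        if g == "high":
            tr_i = _piecewise_run(mass, init, a, ny, params,
                                  params.tp_gf["high"], params.tp_gf["high"],
                                  overlay["high"]["tp_fg2"], overlay["high"]["tp_fg2"],
                                  switch_after=strategy.effect_onset_cycle - 1)
            high_alive += tr_i.alive
        else:
            tr_i = tr
        add_state_costs("int", tr_i, 1)

    # prevalent screening/treatment costs (year 1 cascade + year 2 monitoring)
    if strategy.screening_bt:
        st["int"][0] += bt * prev_alive_y1
        st["int"][0] += course_cost * courses_y1 * high_alive[0]
        st["int"][0] += bt * (strategy.c2 + strategy.c3) * high_alive[0]
        if ny >= 2 and strategy.monitoring_bt_year2:
            st["int"][1] += (bt + course_cost
                             * strategy.repeated_fraction_year2) \
                * high_alive[1] * disc[1]

    # --- incident cohorts ------------------------------------------------
    for entry_year in range(1, ny + 1):
        n_cycles = ny - entry_year + 1
        for g, frac in inputs.group_mix.items():
            mass = population.incidence * frac
            tr = run_group(mass, n_cycles, params,
                           params.tp_gf[g], params.tp_gf[g])
            add_state_costs("soc", tr, entry_year)
            if g == "high":
                tr_i = run_group(mass, n_cycles, params,
                                 overlay["high"]["tp_fg1"],
                                 overlay["high"]["tp_fg2"])
            else:
                tr_i = tr
            add_state_costs("int", tr_i, entry_year)
            if g == "high" and strategy.screening_bt:
                alive = tr_i.alive
                st["int"][entry_year - 1] += (
                    course_cost * courses_y1 * alive[0]
                    + bt * (strategy.c2 + strategy.c3) * alive[0]
                ) * disc[entry_year - 1]
                y2 = entry_year + 1
                if y2 <= ny and strategy.monitoring_bt_year2:
                    st["int"][y2 - 1] += (bt + course_cost
                                          * strategy.repeated_fraction_year2
                                          ) * alive[1] * disc[y2 - 1]
        if strategy.screening_bt:
            st["int"][entry_year - 1] += bt * population.incidence * disc[entry_year - 1]

    rows = []
    for arm in ("int", "soc"):
        for cat, series in (("health_state", hs[arm]),
                            ("screening_treatment", st[arm])):
            row = {"arm": "intervention" if arm == "int" else "standard_of_care",
                   "category": cat}
            row.update({f"year_{y}": series[y - 1] for y in range(1, ny + 1)})
            row["total"] = series.sum()
            rows.append(row)
    table = pd.DataFrame(rows)
    impact = (hs["int"] + st["int"]) - (hs["soc"] + st["soc"])
    return BIAResult(table=table, budget_impact=impact, total=float(impact.sum()))
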