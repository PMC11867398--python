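"""Five-state cohort Markov engine.

States: FG1 (first functioning graft), GF1 (first graft failure, dialysis,
retransplantation still possible), FG2 (second graft), GF2 (second graft
failure, dialysis until death), Death (absorbing).  One-year cycles over a
40-year horizon by default; a hypothetical cohort (10,000 by default) enters
at FG1.

Transition probabilities are time-inhomogeneous series derived from
parametric survival curves (see :mod:`leadchel.survival`).  Within a cycle
death is applied first and the remaining transitions are scaled by the
survival complement, so every row of the implicit transition matrix sums
to one.  The second graft's failure clock restarts at retransplantation:
FG2 occupancy is tracked per entry cycle (tunnel bookkeeping) and indexed by
years since the second transplant.

Trapezoidal half-cycle correction is provided on the trace (mean of
consecutive cycle-boundary occupancies); one-off event flows are recorded at
the cycle in which they occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STATES = ("FG1", "GF1", "FG2", "GF2", "Death")
FG1, GF1, FG2, GF2, DEATH = range(5)

FLOWS = ("gf1_events", "gf2_events", "retransplant", "primary_nonfunction",
         "death_fg", "death_gf")

GROUPS = ("low", "medium", "high")


@dataclass
class ModelParameters:
    """All transition inputs for one arm of the cohort model."""

    tp_gf: dict[str, np.ndarray]          # per lead group, indexed by year 1..H
    tp_dwfg: np.ndarray                   # death with functioning graft
    tp_dwgf: np.ndarray                   # death after graft failure
    p_retransplant_base: float = 0.15
    age_decline_start: float = 65.0
    age_decline_zero: float = 80.0
    p_primary_nonfunction: float = 0.007
    baseline_age: float = 53.0
    horizon: int = 40
    cohort_size: float = 10_000.0

    def __post_init__(self):
        self.tp_dwfg = np.asarray(self.tp_dwfg, dtype=float)
        self.tp_dwgf = np.asarray(self.tp_dwgf, dtype=float)
        self.tp_gf = {g: np.asarray(a, dtype=float) for g, a in self.tp_gf.items()}
        for name, arr in [("tp_dwfg", self.tp_dwfg), ("tp_dwgf", self.tp_dwgf),
                          *[(f"tp_gf[{g}]", a) for g, a in self.tp_gf.items()]]:
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.age_decline_zero > self.age_decline_start:
            raise ValueError("age_decline_zero must exceed age_decline_start")
        for p in (self.p_retransplant_base, self.p_primary_nonfunction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def retransplant_probability(age: float, params: ModelParameters) -> float:
    """Annual retransplantation probability as a function of age.

    Constant at the base value up to ``age_decline_start`` (65), then
    declining linearly to zero at ``age_decline_zero`` (80) and staying zero.
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    a0, a1 = params.age_decline_start, params.age_decline_zero
    if age <= a0:
        return params.p_retransplant_base
    if age >= a1:
        return 0.0
    return params.p_retransplant_base * (a1 - age) / (a1 - a0)


def _tp_at(series: np.ndarray, cycle: int) -> float:
    """1-based lookup with tail clamping (last value reused past the grid)."""
    idx = min(cycle - 1, len(series) - 1)
    return float(series[idx])


def build_transition_matrix(cycle: int, group: str, params: ModelParameters,
                            graft2_age: int | None = None) -> np.ndarray:
    """Explicit 5x5 row-stochastic matrix for one cycle and lead group.

    For the FG2 row, ``graft2_age`` gives the years since retransplantation
    (the failure clock of the second graft); it defaults to ``cycle``.
    Exposed mainly for inspection and testing — the cohort run itself uses
    the same arithmetic with tunnel bookkeeping.
    """
    tp_gf = params.tp_gf[group]
    d_fg = _tp_at(params.tp_dwfg, cycle)
    d_gf = _tp_at(params.tp_dwgf, cycle)
    g1 = _tp_at(tp_gf, cycle)
    g2 = _tp_at(tp_gf, graft2_age if graft2_age is not None else cycle)
    age = params.baseline_age + cycle
    rtx = retransplant_probability(age, params)
    pnf = params.p_primary_nonfunction

    M = np.zeros((5, 5))
    M[FG1, DEATH] = d_fg
    M[FG1, GF1] = g1 * (1 - d_fg)
    M[FG1, FG1] = 1 - M[FG1, DEATH] - M[FG1, GF1]

    M[GF1, DEATH] = d_gf
    M[GF1, FG2] = rtx * (1 - pnf) * (1 - d_gf)
    M[GF1, GF2] = rtx * pnf * (1 - d_gf)
    M[GF1, GF1] = 1 - d_gf - M[GF1, FG2] - M[GF1, GF2]

    M[FG2, DEATH] = d_fg
    M[FG2, GF2] = g2 * (1 - d_fg)
    M[FG2, FG2] = 1 - M[FG2, DEATH] - M[FG2, GF2]

    M[GF2, DEATH] = d_gf
    M[GF2, GF2] = 1 - d_gf

    M[DEATH, DEATH] = 1.0

    rows = M.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-12):
        raise ValueError(f"transition matrix rows do not sum to 1: {rows}")
    return M


@dataclass
class EngineState:
    """Internal cohort state at a cycle boundary.

    ``fg2_by_entry[k]`` is the FG2 mass whose second transplant happened at
    absolute model cycle ``k`` (tunnel bookkeeping for the reset failure
    clock of the second graft).
    """

    fg1: float
    gf1: float
    gf2: float
    dead: float
    fg2_by_entry: np.ndarray = field(default_factory=lambda: np.zeros(1))
    cycle: int = 0

    @property
    def fg2(self) -> float:
        return float(self.fg2_by_entry.sum())

    @property
    def alive(self) -> float:
        return self.fg1 + self.gf1 + self.fg2 + self.gf2

    def occupancy(self) -> np.ndarray:
        return np.array([self.fg1, self.gf1, self.fg2, self.gf2, self.dead])

    def copy(self) -> "EngineState":
        return EngineState(self.fg1, self.gf1, self.gf2, self.dead,
                           self.fg2_by_entry.copy(), self.cycle)


@dataclass
class MarkovTrace:
    """Occupancy, half-cycle-corrected occupancy, and event flows."""

    occupancy: np.ndarray            # (n_cycles+1, 5), row 0 = entry
    flows: dict[str, np.ndarray]     # each (n_cycles+1,), index = event cycle
    cohort_size: float

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def half_cycle(self) -> np.ndarray:
        """Trapezoidal occupancy for cycles 1..n (mean of boundary rows)."""
        return 0.5 * (self.occupancy[:-1] + self.occupancy[1:])

    @property
    def alive(self) -> np.ndarray:
        """Alive count at each cycle boundary 0..n."""
        return self.occupancy[:, :DEATH].sum(axis=1)

    def __add__(self, other: "MarkovTrace") -> "MarkovTrace":
        return MarkovTrace(
            occupancy=self.occupancy + other.occupancy,
            flows={k: self.flows[k] + other.flows[k] for k in self.flows},
            cohort_size=self.cohort_size + other.cohort_size,
        )


def run_group(
    n0: float,
    n_cycles: int,
    params: ModelParameters,
    tp_fg1: np.ndarray,
    tp_fg2_by_age: np.ndarray,
    start_cycle: int = 0,
    init: EngineState | None = None,
    record_snapshots: bool = False,
):
    """Propagate one lead-group sub-cohort through the five states.

    ``tp_fg1`` is the graft-failure series for the first graft indexed by
    absolute model cycle; ``tp_fg2_by_age`` is the series for the second
    graft indexed by years since retransplantation (clock reset).  Death and
    retransplantation probabilities are indexed on absolute model time.
    ``start_cycle``/``init`` allow resuming a cohort mid-life (used by the
    budget-impact model for prevalent patients).
    """
    max_cycle = start_cycle + n_cycles
    if init is not None:
        state = init.copy()
        fg2 = np.zeros(max_cycle + 1)
        k = min(len(init.fg2_by_entry), max_cycle + 1)
        fg2[:k] = init.fg2_by_entry[:k]
        fg1, gf1, gf2_pool, dead = state.fg1, state.gf1, state.gf2, state.dead
    else:
        fg1, gf1, gf2_pool, dead = n0, 0.0, 0.0, 0.0
        fg2 = np.zeros(max_cycle + 1)
    total = fg1 + gf1 + gf2_pool + dead + fg2.sum()

    occ = np.zeros((n_cycles + 1, 5))
    flows = {k: np.zeros(n_cycles + 1) for k in FLOWS}
    occ[0] = [fg1, gf1, fg2.sum(), gf2_pool, dead]
    snapshots = None
    if record_snapshots:
        snapshots = [EngineState(fg1, gf1, gf2_pool, dead, fg2.copy(), start_cycle)]

    # precompute clamped series lookups
    cyc = np.arange(1, n_cycles + 1) + start_cycle
    d_fg_seq = params.tp_dwfg[np.minimum(cyc, len(params.tp_dwfg)) - 1]
    d_gf_seq = params.tp_dwgf[np.minimum(cyc, len(params.tp_dwgf)) - 1]
    g1_seq = tp_fg1[np.minimum(cyc, len(tp_fg1)) - 1]
    # second-graft failure probability by years since retransplant (1-based)
    ages = np.arange(1, max_cycle + 1)
    g2_by_age = np.concatenate(
        [[0.0], tp_fg2_by_age[np.minimum(ages, len(tp_fg2_by_age)) - 1]])
    entry_idx = np.arange(max_cycle + 1)

    pnf = params.p_primary_nonfunction
    for t in range(1, n_cycles + 1):
        abs_cycle = start_cycle + t
        d_fg = d_fg_seq[t - 1]
        d_gf = d_gf_seq[t - 1]
        rtx = retransplant_probability(params.baseline_age + abs_cycle, params)

        # FG1
        death_fg = fg1 * d_fg
        gf1_new = fg1 * g1_seq[t - 1] * (1 - d_fg)
        fg1 = fg1 - death_fg - gf1_new

        # FG2 tunnels (vectorized over entry cycles)
        age2 = np.maximum(abs_cycle - entry_idx, 0)
        fail_vec = fg2 * g2_by_age[age2] * (1 - d_fg)
        death_fg += fg2.sum() * d_fg
        gf2_from_fg2 = float(fail_vec.sum())
        fg2 = fg2 * (1 - d_fg) - fail_vec

        # GF1
        death_gf = gf1 * d_gf
        rtx_ok = gf1 * rtx * (1 - pnf) * (1 - d_gf)
        rtx_pnf = gf1 * rtx * pnf * (1 - d_gf)
        gf1 = gf1 - death_gf - rtx_ok - rtx_pnf + gf1_new

        # GF2
        death_gf += gf2_pool * d_gf
        gf2_pool = gf2_pool * (1 - d_gf) + gf2_from_fg2 + rtx_pnf

        fg2[abs_cycle] += rtx_ok
        dead += death_fg + death_gf

        occ[t] = [fg1, gf1, fg2.sum(), gf2_pool, dead]
        flows["gf1_events"][t] = gf1_new
        flows["gf2_events"][t] = gf2_from_fg2
        flows["retransplant"][t] = rtx_ok
        flows["primary_nonfunction"][t] = rtx_pnf
        flows["death_fg"][t] = death_fg
        flows["death_gf"][t] = death_gf
        if record_snapshots:
            snapshots.append(EngineState(fg1, gf1, gf2_pool, dead,
                                         fg2.copy(), abs_cycle))

        if abs(occ[t].sum() - total) > 1e-6 * max(total, 1.0):
            raise RuntimeError("mass conservation violated in Markov engine")

    trace = MarkovTrace(occupancy=occ, flows=flows, cohort_size=total)
    if record_snapshots:
        return trace, snapshots
    return trace


def run_cohort(
    params: ModelParameters,
    group_mix: dict[str, float] | None = None,
    overlay: dict[str, dict[str, np.ndarray]] | None = None,
    n_cycles: int | None = None,
) -> tuple[MarkovTrace, dict[str, MarkovTrace]]:
    """Run the full cohort: one sub-cohort per lead group, summed.

    ``group_mix`` gives each tertile's share of the entering cohort (default
    a third each).  ``overlay`` optionally replaces a group's graft-failure
    series — the intervention arm maps the treated high group onto the
    medium-group series from the effect-onset cycle (see
    :mod:`leadchel.strategy`).  Returns the summed trace and the per-group
    traces (the latter feed intervention costing, which needs the survivor
    counts of the initially eligible group).
    """
    if group_mix is None:
        group_mix = {g: 1.0 / 3.0 for g in GROUPS}
    if abs(sum(group_mix.values()) - 1.0) > 1e-9:
        raise ValueError("group_mix must sum to 1")
    if n_cycles is None:
        n_cycles = params.horizon

    traces: dict[str, MarkovTrace] = {}
    for g, frac in group_mix.items():
        tp_fg1 = params.tp_gf[g]
        tp_fg2 = params.tp_gf[g]
        if overlay and g in overlay:
            tp_fg1 = overlay[g].get("tp_fg1", tp_fg1)
            tp_fg2 = overlay[g].get("tp_fg2", tp_fg2)
        traces[g] = run_group(params.cohort_size * frac, n_cycles, params,
                              np.asarray(tp_fg1, dtype=float),
                              np.asarray(tp_fg2, dtype=float))
    total = None
    for tr in traces.values():
        total = tr if total is None else total + tr
    return total, traces
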