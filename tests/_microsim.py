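"""Individual-level microsimulation oracle for the cohort Markov engine.

Simulates each patient's path through the five states with the same
per-cycle probabilities and the same within-cycle competing order (death
first, remaining transitions on the survivors) as the cohort engine, so the
cohort trace must equal the microsimulation's expectation up to Monte Carlo
error.  Test-only code: the production model is the cohort engine.
"""

import numpy as np

from leadchel.markov import (DEATH, FG1, FG2, GF1, GF2, ModelParameters,
                             retransplant_probability)


def microsimulate(n_patients: int, params: ModelParameters,
                  tp_fg1: np.ndarray, tp_fg2_by_age: np.ndarray,
                  n_cycles: int, seed: int = 0) -> np.ndarray:
    """Occupancy counts (n_cycles+1, 5) for n_patients starting in FG1."""
    rng = np.random.default_rng(seed)
    state = np.full(n_patients, FG1, dtype=np.int8)
    entry = np.zeros(n_patients, dtype=np.int32)   # FG2 entry cycle
    occ = np.zeros((n_cycles + 1, 5))
    occ[0, FG1] = n_patients

    def tp_at(series, cycle):
        return series[min(cycle, len(series)) - 1]

    for t in range(1, n_cycles + 1):
        d_fg = tp_at(params.tp_dwfg, t)
        d_gf = tp_at(params.tp_dwgf, t)
        rtx = retransplant_probability(params.baseline_age + t, params)
        pnf = params.p_primary_nonfunction
        u_death = rng.random(n_patients)
        u_move = rng.random(n_patients)
        u_pnf = rng.random(n_patients)
        new = state.copy()

        fg1 = state == FG1
        dies = fg1 & (u_death < d_fg)
        fails = fg1 & ~dies & (u_move < tp_at(tp_fg1, t))
        new[dies] = DEATH
        new[fails] = GF1

        gf1 = state == GF1
        dies = gf1 & (u_death < d_gf)
        moves = gf1 & ~dies & (u_move < rtx)
        to_gf2 = moves & (u_pnf < pnf)
        new[dies] = DEATH
        new[moves] = FG2
        new[to_gf2] = GF2
        entry[moves & ~to_gf2] = t

        fg2 = state == FG2
        dies = fg2 & (u_death < d_fg)
        age2 = np.maximum(t - entry, 1)
        tp2 = tp_fg2_by_age[np.minimum(age2, len(tp_fg2_by_age)) - 1]
        fails = fg2 & ~dies & (u_move < tp2)
        new[dies] = DEATH
        new[fails] = GF2

        gf2 = state == GF2
        new[gf2 & (u_death < d_gf)] = DEATH

        state = new
        occ[t] = np.bincount(state, minlength=5)
    return occ
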