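"""Deterministic and probabilistic sensitivity analysis.

The univariate DSA re-runs the two-arm model with one parameter at a time
set to the bounds of its 95% confidence interval (parameters without a
published interval get mean ± 1.96 × (25% of the value)); the DMSA drug
price additionally gets a −50% / +200% scenario.  Results are ranked by
output swing for the tornado diagram.

The PSA draws all parameters simultaneously: beta distributions for
utilities and working-population percentages, gamma for costs, normal for
course numbers, hospital days and the retransplant / primary-non-function
probabilities, and normal distributions (from the fitted 95% CIs) for the
survival parameters behind the transition probabilities.  Each iteration
evaluates both arms on the same draw; the resulting (ΔC, ΔE) sample feeds
the cost-effectiveness plane, the CEAC and value-of-information analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelInputs, run_cea
from .strategy import StrategySpec

_Z = 1.96


# ---------------------------------------------------------------------------
# parameter paths
# ---------------------------------------------------------------------------

def _walk(obj, segments):
    for seg in segments:
        if isinstance(obj, dict):
            obj = obj[seg]
        elif isinstance(obj, (list, tuple)):
            obj = obj[int(seg)]
        else:
            obj = getattr(obj, seg)
    return obj


def get_by_path(obj, path: str):
    return _walk(obj, path.split("."))


def set_by_path(obj, path: str, value) -> None:
    segments = path.split(".")
    parent = _walk(obj, segments[:-1])
    last = segments[-1]
    if isinstance(parent, dict):
        parent[last] = value
    elif isinstance(parent, list):
        parent[int(last)] = value
    else:
        setattr(parent, last, value)


@dataclass(eq=False)      # identity hashing: instances key assignment dicts
class Parameter:
    """One entry of the sensitivity-analysis parameter space."""

    name: str
    target: str          # 'inputs' or 'strategy'
    path: str
    base: float
    low: float | None = None
    high: float | None = None
    dist: str | None = None   # beta | gamma | normal | normal_prob | normal_pos

    @property
    def sd(self) -> float:
        """Implied standard deviation: CI width / 3.92, else 25% of the value."""
        if self.low is not None and self.high is not None:
            return (self.high - self.low) / (2 * _Z)
        return 0.25 * abs(self.base)

    def bounds(self) -> tuple[float, float]:
        if self.low is not None and self.high is not None:
            return self.low, self.high
        half = _Z * self.sd
        return self.base - half, self.base + half


def parameter_registry(inputs: ModelInputs,
                       strategy: StrategySpec) -> list[Parameter]:
    """The full parameter space with base values and 95% bounds."""
    P = Parameter
    reg = [
        # chelation-cascade unit costs
        P("blood_draw", "inputs", "intervention_costing.blood_draw", 15.00, 7.65, 22.35, "gamma"),
        P("lead_lab", "inputs", "intervention_costing.lead_lab", 50.63, 25.82, 75.43, "gamma"),
        P("iron_lab", "inputs", "intervention_costing.iron_lab", 26.39, 13.46, 39.32, "gamma"),
        P("ast_alt_lab", "inputs", "intervention_costing.ast_alt_lab", 5.38, 2.74, 8.02, "gamma"),
        P("dmsa_course", "inputs", "intervention_costing.dmsa_course", 570.95, 291.18, 850.72, "gamma"),
        P("iron_supplement", "inputs", "intervention_costing.iron_supplement", 46.48, 23.70, 69.26, "gamma"),
        # health-state costs
        P("gf_initial", "inputs", "costs.gf_initial", 2818.80, 1437.59, 4200.01, "gamma"),
        P("dialysis_chd", "inputs", "costs.dialysis_chd", 113142.50, 61662.98, 164621.94, "gamma"),
        P("dialysis_hhd", "inputs", "costs.dialysis_hhd", 106344.10, 76059.79, 136628.39, "gamma"),
        P("dialysis_apd", "inputs", "costs.dialysis_apd", 109863.60, 64633.50, 155093.72, "gamma"),
        P("dialysis_capd", "inputs", "costs.dialysis_capd", 94756.94, 29540.82, 159973.05, "gamma"),
        P("transplantation", "inputs", "costs.transplantation", 103993.68, 8986.50, 199000.85, "gamma"),
        P("transplant_upkeep", "inputs", "costs.transplant_upkeep_annual", 14376.98, 7332.26, 21421.70, "gamma"),
        P("death_oneoff", "inputs", "costs.death_oneoff", 1392.03, 709.93, 2074.12, "gamma"),
        # productivity
        P("work_posttx_45_54", "inputs", "productivity.work_posttx.0", 0.57, 0.291, 0.849, "beta"),
        P("work_posttx_55_64", "inputs", "productivity.work_posttx.1", 0.41, 0.209, 0.611, "beta"),
        P("work_posttx_65plus", "inputs", "productivity.work_posttx.2", 0.061, 0.031, 0.091, "beta"),
        P("work_dialysis_45_54", "inputs", "productivity.work_dialysis.0", 0.32, 0.163, 0.477, "beta"),
        P("work_dialysis_55_64", "inputs", "productivity.work_dialysis.1", 0.19, 0.097, 0.283, "beta"),
        P("work_dialysis_65plus", "inputs", "productivity.work_dialysis.2", 0.028, 0.014, 0.042, "beta"),
        P("hospital_days_living", "inputs", "productivity.hospital_days_living", 13.30, 6.78, 19.82, "normal_pos"),
        P("hospital_days_deceased", "inputs", "productivity.hospital_days_deceased", 7.80, 3.98, 11.62, "normal_pos"),
        P("friction_days", "inputs", "productivity.friction_days", 85.0, 43.35, 126.65, "normal_pos"),
        P("hours_per_day", "inputs", "productivity.hours_per_day", 8.0, 4.08, 11.92, "normal_pos"),
        P("wage_male", "inputs", "productivity.wage_male", 28.45, 23.47, 68.57, "gamma"),
        P("wage_female", "inputs", "productivity.wage_female", 24.70, 19.57, 57.17, "gamma"),
        # utilities
        P("u_fg", "inputs", "utilities.u_fg", 0.81, 0.72, 0.90, "beta"),
        P("u_hd", "inputs", "utilities.u_hd", 0.56, 0.49, 0.62, "beta"),
        P("u_pd", "inputs", "utilities.u_pd", 0.58, 0.50, 0.67, "beta"),
        # probabilities / strategy
        P("p_primary_nonfunction", "inputs", "p_primary_nonfunction", 0.007, 0.004, 0.010, "normal_prob"),
        P("p_retransplant", "inputs", "p_retransplant_base", 0.15, None, None, "normal_prob"),
        P("repeated_fraction_year2", "strategy", "repeated_fraction_year2", 0.60, None, None, "normal_prob"),
    ]
    # survival parameters of the chosen models, CIs from the fits
    surv = inputs.survival
    sets = [(f"tp_gf_{g}", f"survival.gf.{g}", surv.gf[g]) for g in surv.gf]
    sets += [("tp_dwfg", "survival.dwfg", surv.dwfg),
             ("tp_dwgf", "survival.dwgf", surv.dwgf)]
    for label, base_path, pset in sets:
        for pname, value in pset.params.items():
            ci = pset.ci.get(pname)
            lo, hi = (ci if ci else (None, None))
            positive = pname in ("sdlog", "shape", "rate", "scale", "sigma")
            reg.append(Parameter(
                name=f"{label}_{pname}", target="inputs",
                path=f"{base_path}.params.{pname}", base=value,
                low=lo, high=hi,
                dist="normal_pos" if positive else "normal"))
    return reg


# ---------------------------------------------------------------------------
# DSA
# ---------------------------------------------------------------------------

def _apply(inputs: ModelInputs, strategy: StrategySpec,
           assignments: dict[Parameter, float]):
    new_inputs = inputs.copy()
    new_strategy = replace(strategy)
    for param, value in assignments.items():
        target = new_inputs if param.target == "inputs" else new_strategy
        set_by_path(target, param.path, value)
    return new_inputs, new_strategy


def run_dsa(inputs: ModelInputs, strategy: StrategySpec | None = None,
            registry: list[Parameter] | None = None,
            perspective: str = "societal") -> pd.DataFrame:
    """One-way sensitivity: each parameter at its CI bounds.

    Returns a tidy frame (parameter, bound, value, delta_c, delta_e) sorted
    by |ΔC| swing; includes the −50% / +200% DMSA-price scenario rows.
    """
    strategy = strategy or StrategySpec()
    registry = registry or parameter_registry(inputs, strategy)
    base = run_cea(inputs, strategy, perspective).result

    rows = []
    cases: list[tuple[Parameter, str, float]] = []
    for p in registry:
        lo, hi = p.bounds()
        cases += [(p, "low", lo), (p, "high", hi)]
    dmsa = next(p for p in registry if p.name == "dmsa_course")
    cases += [(replace(dmsa, name="dmsa_price_scenario"), "low", 0.5 * dmsa.base),
              (replace(dmsa, name="dmsa_price_scenario"), "high", 2.0 * dmsa.base)]

    for p, bound, value in cases:
        inp, strat = _apply(inputs, strategy, {p: value})
        res = run_cea(inp, strat, perspective).result
        rows.append({"parameter": p.name, "bound": bound, "value": value,
                     "delta_c": res.delta_c, "delta_e": res.delta_e})
    df = pd.DataFrame(rows)
    swings = (df.groupby("parameter")
                .agg(swing_c=("delta_c", lambda s: s.max() - s.min()),
                     swing_e=("delta_e", lambda s: s.max() - s.min())))
    df = df.merge(swings, on="parameter")
    df["base_delta_c"] = base.delta_c
    df["base_delta_e"] = base.delta_e
    return df.sort_values(["swing_c", "parameter", "bound"],
                          ascending=[False, True, True]).reset_index(drop=True)


def tornado(dsa: pd.DataFrame, on: str = "swing_c", top: int = 15) -> pd.DataFrame:
    """Top-``top`` parameters by swing, widest first (tornado ordering)."""
    order = (dsa.drop_duplicates("parameter")
                .sort_values(on, ascending=False)
                .head(top)["parameter"])
    return dsa[dsa["parameter"].isin(order)].copy()


# ---------------------------------------------------------------------------
# PSA
# ---------------------------------------------------------------------------

def beta_from_mean_ci(mean: float, low: float, high: float) -> tuple[float, float]:
    """Method-of-moments beta hyperparameters from a mean and 95% CI."""
    var = ((high - low) / (2 * _Z)) ** 2
    if var <= 0:
        raise ValueError("beta requires a positive variance")
    if var >= mean * (1 - mean):
        raise ValueError(f"infeasible beta moment match (mean={mean}, var={var})")
    nu = mean * (1 - mean) / var - 1.0
    return mean * nu, (1 - mean) * nu


def gamma_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments gamma (shape, scale)."""
    if mean <= 0 or sd <= 0:
        raise ValueError("gamma requires positive mean and sd")
    shape = (mean / sd) ** 2
    return shape, sd ** 2 / mean


@dataclass
class PSAResult:
    """Per-iteration parameter draws and two-arm outcomes."""

    samples: pd.DataFrame    # columns: parameter names + outcome columns
    cohort_size: float
    seed: int | None = None
    clip_rate: float = 0.0
    param_names: list[str] = field(default_factory=list)

    @property
    def delta_c(self) -> np.ndarray:
        return self.samples["delta_c"].to_numpy()

    @property
    def delta_e(self) -> np.ndarray:
        return self.samples["delta_e"].to_numpy()

    def net_benefit(self, wtp: float) -> np.ndarray:
        """Incremental net monetary benefit per iteration at one WTP."""
        return wtp * self.delta_e - self.delta_c


def draw_parameters(registry: list[Parameter], n_iter: int,
                    rng: np.random.Generator, scale: float = 1.0,
                    vary: set[str] | None = None):
    """Monte-Carlo parameter draw matrix; returns (DataFrame, clip_rate).

    ``scale`` multiplies every standard deviation (0 reproduces the
    deterministic inputs); ``vary`` restricts sampling to the named subset,
    holding everything else at its base value.
    """
    cols = {}
    clipped = 0
    total = 0
    for p in registry:
        if (vary is not None and p.name not in vary) or p.dist is None:
            cols[p.name] = np.full(n_iter, p.base)
            continue
        sd = p.sd * scale
        if sd == 0:
            cols[p.name] = np.full(n_iter, p.base)
            continue
        if p.dist == "beta":
            try:
                a, b = beta_from_mean_ci(p.base, p.base - _Z * sd, p.base + _Z * sd)
            except ValueError as exc:
                raise ValueError(f"parameter {p.name!r}: {exc}") from exc
            draws = rng.beta(a, b, n_iter)
        elif p.dist == "gamma":
            shape, scl = gamma_from_mean_sd(p.base, sd)
            draws = rng.gamma(shape, scl, n_iter)
        else:
            draws = rng.normal(p.base, sd, n_iter)
            if p.dist == "normal_prob":
                lo, hi = 0.0, 1.0
            elif p.dist == "normal_pos":
                lo, hi = 1e-9, np.inf
            else:
                lo, hi = -np.inf, np.inf
            clipped += int(((draws < lo) | (draws > hi)).sum())
            draws = np.clip(draws, lo, hi)
        total += n_iter
        cols[p.name] = draws
    clip_rate = clipped / total if total else 0.0
    return pd.DataFrame(cols), clip_rate


def run_psa(inputs: ModelInputs, strategy: StrategySpec | None = None,
            n_iter: int = 10_000, seed: int = 0, scale: float = 1.0,
            vary: set[str] | None = None, exclude: set[str] | None = None,
            registry: list[Parameter] | None = None,
            perspective: str = "societal") -> PSAResult:
    """Probabilistic sensitivity analysis.

    Every iteration assigns one joint parameter draw, runs both arms on it,
    and records per-arm discounted totals plus (ΔC, ΔE).  A fixed seed gives
    a bit-identical sample set on rerun.
    """
    strategy = strategy or StrategySpec()
    registry = registry or parameter_registry(inputs, strategy)
    if exclude is not None:
        vary = {p.name for p in registry} - set(exclude)
    rng = np.random.default_rng(seed)
    draws, clip_rate = draw_parameters(registry, n_iter, rng, scale, vary)

    out = np.empty((n_iter, 6))
    columns = {p: draws[p.name].to_numpy() for p in registry}
    for i in range(n_iter):
        assignments = {p: col[i] for p, col in columns.items()}
        inp, strat = _apply(inputs, strategy, assignments)
        res = run_cea(inp, strat, perspective).result
        out[i] = (res.delta_c, res.delta_e,
                  res.intervention.total(perspective), res.intervention.qalys,
                  res.standard_of_care.total(perspective), res.standard_of_care.qalys)

    samples = draws.copy()
    samples[["delta_c", "delta_e", "cost_int", "qaly_int",
             "cost_soc", "qaly_soc"]] = out
    return PSAResult(samples=samples, cohort_size=inputs.cohort_size,
                     seed=seed, clip_rate=clip_rate,
                     param_names=[p.name for p in registry])


def ceac(delta_c: np.ndarray, delta_e: np.ndarray,
         wtp_grid: np.ndarray) -> np.ndarray:
    """Probability of positive net benefit at each willingness-to-pay."""
    delta_c = np.asarray(delta_c, dtype=float)
    delta_e = np.asarray(delta_e, dtype=float)
    if delta_c.size == 0:
        raise ValueError("no PSA samples")
    wtp = np.atleast_1d(np.asarray(wtp_grid, dtype=float))
    nb = wtp[:, None] * delta_e[None, :] - delta_c[None, :]
    return (nb > 0).mean(axis=1)
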