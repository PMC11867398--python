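"""Pipeline orchestration: stages, seeds, and tabular output files.

Stages run in dependency order: synthetic cohort -> survival fitting (or
the supplied-parameter bypass) -> two-arm Markov evaluation -> optional
sensitivity, budget-impact and value-of-information stages.  Every
stochastic stage draws its seed from a named child of the master seed
(recorded in the run manifest), so the same configuration and seed produce
byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import budget, config as cfgmod, voi
from .cohort import generate_cohort, write_cohort
from .markov import STATES
from .model import ModelInputs, ModelRun, fit_survival_inputs, run_cea
from .sensitivity import ceac, run_dsa, run_psa
from .strategy import StrategySpec, load_scenarios

_SEED_STREAMS = ("cohort", "psa", "evsi")


def child_seeds(master_seed: int) -> dict[str, int]:
    """Named 31-bit child seeds derived from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(_SEED_STREAMS))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(_SEED_STREAMS, children)}


def prepare_inputs(cfg: dict, seeds: dict[str, int],
                   outdir: Path | None = None):
    """Cohort generation + survival estimation (or bypass) -> ModelInputs."""
    spec = cfgmod.cohort_spec(cfg, seeds["cohort"])
    cohort_df = generate_cohort(spec)
    if outdir is not None:
        write_cohort(cohort_df, outdir / "cohort.csv")

    if cfg.get("survival_params"):
        survival = cfgmod.survival_inputs_from_config(cfg["survival_params"])
        fits = {}
    else:
        survival, fits = fit_survival_inputs(
            cohort_df, horizon=cfg["model"]["horizon"],
            overrides=cfg["survival_overrides"])
        if outdir is not None:
            rows = []
            for key, ranked in fits.items():
                for rank, f in enumerate(ranked):
                    rows.append({"endpoint": key, "rank": rank,
                                 "family": f.family, "loglik": f.loglik,
                                 "aic": f.aic, "bic": f.bic,
                                 **{f"param_{k}": v for k, v in f.params.items()}})
            pd.DataFrame(rows).to_csv(outdir / "survival_fits.csv", index=False)
    return cfgmod.model_inputs(cfg, survival), cohort_df


def trace_frame(run: ModelRun) -> pd.DataFrame:
    frames = []
    for arm, trace in (("intervention", run.trace_intervention),
                       ("standard_of_care", run.trace_soc)):
        df = pd.DataFrame(trace.occupancy, columns=STATES)
        df.insert(0, "cycle", np.arange(trace.n_cycles + 1))
        df.insert(0, "arm", arm)
        for k, v in trace.flows.items():
            df[k] = v
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def cea_table(run: ModelRun) -> pd.DataFrame:
    """Deterministic results shaped like the headline cost-effectiveness table."""
    r = run.result
    rows = []
    for arm_name, arm in (("intervention", r.intervention),
                          ("standard_of_care", r.standard_of_care)):
        rows += [
            {"arm": arm_name, "row": "health_state", "costs": arm.health_state},
            {"arm": arm_name, "row": "screening_treatment",
             "costs": arm.screening_treatment},
            {"arm": arm_name, "row": "productivity", "costs": arm.productivity},
            {"arm": arm_name, "row": "total", "costs": arm.total(r.perspective),
             "qalys": arm.qalys},
        ]
    df = pd.DataFrame(rows)
    df["delta_c"] = np.nan
    df["delta_e"] = np.nan
    df["icer"] = None
    mask = (df["arm"] == "intervention") & (df["row"] == "total")
    df.loc[mask, "delta_c"] = r.delta_c
    df.loc[mask, "delta_e"] = r.delta_e
    df.loc[mask, "icer"] = (r.dominance if r.icer is None or
                            r.dominance != "tradeoff" else r.icer)
    return df


def run_pipeline(cfg: dict | None = None, stages=("cea",),
                 outdir: str | Path | None = None) -> dict:
    """Execute the requested stages; returns a result bundle dict.

    Recognized stages: ``cea`` (always useful), ``dsa``, ``psa`` (implies
    the CEAC), ``bia``, ``voi`` (requires ``psa``).  When ``outdir`` is
    given all tabular outputs plus a JSON manifest are written there.
    """
    cfg = cfg or cfgmod.load_config()
    outdir = Path(outdir if outdir is not None else cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(int(cfg["seed"]))

    scenarios = load_scenarios()
    label = str(cfg["scenario"])
    if label not in scenarios:
        raise cfgmod.ConfigError(f"unknown scenario {label!r}")
    strategy: StrategySpec = scenarios[label]
    perspective = cfg["perspective"]

    inputs, cohort_df = prepare_inputs(cfg, seeds, outdir)
    bundle: dict = {"config": cfg, "seeds": seeds, "inputs": inputs,
                    "strategy": strategy}

    run = run_cea(inputs, strategy, perspective)
    bundle["cea"] = run
    cea_table(run).to_csv(outdir / "cea_results.csv", index=False)
    trace_frame(run).to_csv(outdir / "trace.csv", index=False)

    if "dsa" in stages:
        dsa = run_dsa(inputs, strategy, perspective=perspective)
        dsa.to_csv(outdir / "dsa.csv", index=False)
        bundle["dsa"] = dsa

    if "psa" in stages or "voi" in stages:
        psa = run_psa(inputs, strategy, n_iter=int(cfg["n_psa_iterations"]),
                      seed=seeds["psa"], perspective=perspective)
        psa.samples.to_csv(outdir / "psa_samples.csv", index=False)
        wtp_grid = np.asarray(cfg["wtp_grid"], dtype=float)
        acc = ceac(psa.delta_c, psa.delta_e, wtp_grid)
        pd.DataFrame({"wtp": wtp_grid, "probability_cost_effective": acc}) \
            .to_csv(outdir / "ceac.csv", index=False)
        bundle["psa"] = psa
        bundle["ceac"] = acc

    if "bia" in stages:
        pop = budget.PopulationSpec(**cfg["population"])
        bia = budget.run_bia(inputs, strategy, pop)
        bia.table.to_csv(outdir / "bia.csv", index=False)
        bundle["bia"] = bia

    if "voi" in stages:
        psa = bundle["psa"]
        wtp = float(cfg["wtp"])
        wtp_grid = np.asarray(cfg["wtp_grid"], dtype=float)
        rows = [{"measure": "evpi", "subset": "", "n": "",
                 **{f"wtp_{int(w)}": voi.evpi(psa.net_benefit(w), psa.cohort_size)
                    for w in wtp_grid}}]
        for name, values in voi.evppi_subsets(
                psa, voi.default_subsets(psa), wtp_grid).items():
            rows.append({"measure": "evppi", "subset": name, "n": "",
                         **{f"wtp_{int(w)}": v for w, v in zip(wtp_grid, values)}})
        evsi = voi.evsi_gf_trial(psa, wtp, [0, 100, 250, 500, 1000],
                                 seed=seeds["evsi"])
        for n, v in evsi.items():
            rows.append({"measure": "evsi", "subset": "gf_meanlog_medium_high",
                         "n": n, f"wtp_{int(wtp)}": v})
        pd.DataFrame(rows).to_csv(outdir / "voi.csv", index=False)
        bundle["voi"] = {"evsi": evsi, "rows": rows}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(cfgmod.manifest(cfg, seeds), fh, indent=2)
    return bundle
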