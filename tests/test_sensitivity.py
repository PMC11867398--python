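import numpy as np
import pytest
from scipy import stats

from leadchel.model import run_cea
from leadchel.sensitivity import (Parameter, beta_from_mean_ci, ceac,
                                  draw_parameters, gamma_from_mean_sd,
                                  get_by_path, parameter_registry, run_dsa,
                                  run_psa, set_by_path)
from leadchel.strategy import StrategySpec


class TestDistributionMatching:
    def test_beta_matches_mean_and_ci(self, rng):
        a, b = beta_from_mean_ci(0.81, 0.72, 0.90)
        draws = rng.beta(a, b, 100_000)
        assert draws.mean() == pytest.approx(0.81, abs=0.01)
        lo, hi = np.quantile(draws, [0.025, 0.975])
        assert lo == pytest.approx(0.72, abs=0.01)
        assert hi == pytest.approx(0.90, abs=0.01)

    def test_beta_infeasible_variance_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            beta_from_mean_ci(0.5, -2.0, 3.0)

    def test_gamma_matches_moments(self):
        shape, scale = gamma_from_mean_sd(570.95, 142.0)
        dist = stats.gamma(shape, scale=scale)
        assert dist.mean() == pytest.approx(570.95)
        assert dist.std() == pytest.approx(142.0)


class TestParameterPaths:
    def test_roundtrip_nested_paths(self, model_inputs):
        inp = model_inputs.copy()
        set_by_path(inp, "costs.gf_initial", 1000.0)
        assert get_by_path(inp, "costs.gf_initial") == 1000.0
        set_by_path(inp, "productivity.work_posttx.1", 0.5)
        assert inp.productivity.work_posttx[1] == 0.5
        set_by_path(inp, "survival.gf.high.params.meanlog", 2.5)
        assert inp.survival.gf["high"].params["meanlog"] == 2.5

    def test_registry_covers_survival_parameters(self, model_inputs):
        names = {p.name for p in
                 parameter_registry(model_inputs, StrategySpec())}
        assert {"tp_gf_high_meanlog", "tp_gf_medium_sdlog", "tp_dwfg_shape",
                "tp_dwgf_rate", "u_fg", "dmsa_course"} <= names

    def test_se25_fallback_bounds(self):
        p = Parameter("x", "inputs", "y", 0.15, dist="normal_prob")
        lo, hi = p.bounds()
        assert lo == pytest.approx(0.15 - 1.96 * 0.0375)
        assert hi == pytest.approx(0.15 + 1.96 * 0.0375)


class TestDSA:
    def test_base_value_reproduces_base_case(self, model_inputs):
        strategy = StrategySpec()
        base = run_cea(model_inputs, strategy).result
        reg = parameter_registry(model_inputs, strategy)
        p = next(q for q in reg if q.name == "u_fg")
        from leadchel.sensitivity import _apply
        inp, strat = _apply(model_inputs, strategy, {p: p.base})
        res = run_cea(inp, strat).result
        assert res.delta_c == pytest.approx(base.delta_c)
        assert res.delta_e == pytest.approx(base.delta_e)

    def test_dsa_frame_and_dmsa_price_scenario(self, model_inputs):
        reg = [p for p in parameter_registry(model_inputs, StrategySpec())
               if p.name in ("dmsa_course", "u_fg", "tp_gf_high_meanlog")]
        df = run_dsa(model_inputs, StrategySpec(), registry=reg)
        sub = df[df["parameter"] == "dmsa_price_scenario"]
        assert sorted(sub["value"]) == pytest.approx([285.475, 1141.90])
        # graft-failure survival parameters dominate the tornado
        top = df.drop_duplicates("parameter").iloc[0]
        assert top["parameter"] == "tp_gf_high_meanlog"
        # utility variation moves effects, not costs
        u = df[df["parameter"] == "u_fg"]
        assert u["swing_e"].iloc[0] > 0
        assert u["swing_c"].iloc[0] == pytest.approx(0.0, abs=1e-6)


class TestPSA:
    def test_zero_variance_reproduces_deterministic(self, model_inputs):
        base = run_cea(model_inputs, StrategySpec()).result
        psa = run_psa(model_inputs, StrategySpec(), n_iter=4, seed=3,
                      scale=0.0)
        np.testing.assert_allclose(psa.delta_c, base.delta_c)
        np.testing.assert_allclose(psa.delta_e, base.delta_e)

    def test_mean_converges_to_deterministic_as_variance_shrinks(
            self, model_inputs):
        base = run_cea(model_inputs, StrategySpec()).result
        gaps = []
        for scale in (0.5, 0.05):
            psa = run_psa(model_inputs, StrategySpec(), n_iter=60, seed=5,
                          scale=scale)
            gaps.append(abs(psa.delta_e.mean() - base.delta_e))
        assert gaps[1] < gaps[0]

    def test_fixed_seed_is_bit_reproducible(self, model_inputs):
        a = run_psa(model_inputs, StrategySpec(), n_iter=20, seed=7)
        b = run_psa(model_inputs, StrategySpec(), n_iter=20, seed=7)
        assert a.samples.equals(b.samples)

    def test_draw_truncation(self, rng):
        reg = [Parameter("p", "inputs", "x", 0.5, 0.0, 1.0, "normal_prob"),
               Parameter("d", "inputs", "y", 5.0, 1.0, 9.0, "normal_pos"),
               Parameter("u", "inputs", "z", 0.8, 0.7, 0.9, "beta"),
               Parameter("c", "inputs", "w", 100.0, 50.0, 150.0, "gamma")]
        draws, clip_rate = draw_parameters(reg, 20_000, rng, scale=3.0)
        assert ((draws["p"] >= 0) & (draws["p"] <= 1)).all()
        assert (draws["d"] > 0).all()
        assert ((draws["u"] >= 0) & (draws["u"] <= 1)).all()
        assert (draws["c"] >= 0).all()
        assert clip_rate > 0   # heavy inflation must have clipped something

    def test_subset_variation_keeps_others_fixed(self, model_inputs):
        psa = run_psa(model_inputs, StrategySpec(), n_iter=10, seed=1,
                      vary={"u_fg"})
        assert psa.samples["u_fg"].std() > 0
        assert psa.samples["dmsa_course"].nunique() == 1


class TestCEAC:
    def test_enumerated_four_sample_set(self):
        dc = np.array([-10.0, 5.0, 5.0, -10.0])
        de = np.array([1.0, 1.0, -1.0, -1.0])
        # by enumeration: nb(wtp) = wtp*de - dc
        assert ceac(dc, de, [0.0])[0] == 0.5          # dc < 0 in 2 of 4
        assert ceac(dc, de, [20.0])[0] == 0.5         # {30, 15, -25, -10}
        assert ceac(dc, de, [6.0])[0] == 0.75         # {16, 1, -11, 4}

    def test_all_dominant_iterations_give_one(self):
        dc = -np.ones(50)
        de = np.ones(50)
        assert (ceac(dc, de, [0, 50_000, 1e6]) == 1.0).all()

    def test_equals_quadrant_tally(self, psa_small):
        wtp = 50_000.0
        prob = ceac(psa_small.delta_c, psa_small.delta_e, [wtp])[0]
        dc, de = psa_small.delta_c, psa_small.delta_e
        # independent tally over the four plane quadrants
        tally = ((dc < 0) & (de > 0)).sum()
        tally += (((de > 0) & (dc >= 0) & (dc / de < wtp)).sum()
                  + ((de < 0) & (dc < 0) & (dc / de > wtp)).sum())
        assert prob == pytest.approx(tally / len(dc))
        assert 0.0 <= prob <= 1.0

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            ceac(np.array([]), np.array([]), [0.0])
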