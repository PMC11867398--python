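import numpy as np
import pytest

from leadchel.econ import (ArmResult, CostInputs, DiscountRates,
                           ProductivityInputs, UtilityInputs, compute_icer,
                           discount, productivity_losses, qalys, state_costs)
from leadchel.markov import FLOWS, MarkovTrace
from leadchel.model import run_cea
from leadchel.strategy import StrategySpec


def _trace(occupancy, flows=None):
    occupancy = np.asarray(occupancy, dtype=float)
    f = {k: np.zeros(len(occupancy)) for k in FLOWS}
    if flows:
        for k, v in flows.items():
            f[k] = np.asarray(v, dtype=float)
    return MarkovTrace(occupancy=occupancy, flows=f,
                       cohort_size=occupancy[0].sum())


class TestDiscounting:
    def test_first_cycle_undiscounted(self):
        assert discount(123.0, 0.04, 1) == 123.0

    def test_one_cycle_at_four_percent(self):
        assert discount(104.0, 0.04, 2) == pytest.approx(100.0)

    def test_stream_matches_annuity_closed_form(self):
        # oracle: 40-year annuity-due of 100 at 4%
        cycles = np.arange(1, 41)
        looped = discount(np.full(40, 100.0), 0.04, cycles).sum()
        annuity = 100 * (1 - 1.04 ** -40) / 0.04 * 1.04
        assert looped == pytest.approx(annuity, rel=1e-12)

    def test_cycle_zero_rejected(self):
        with pytest.raises(ValueError):
            discount(1.0, 0.04, 0)


class TestWeightedInputs:
    def test_modality_weighted_dialysis_cost(self):
        # independent hand computation from the unit costs and the mix
        assert CostInputs().dialysis_weighted == pytest.approx(111_137.41, abs=0.005)

    def test_weighted_graft_failure_utility(self):
        assert UtilityInputs().u_gf == pytest.approx(0.5632)

    def test_modality_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CostInputs(modality_mix=(0.9, 0.04, 0.08, 0.08))


class TestStateCostsAndQalys:
    def test_fg_cohort_one_cycle_qalys(self):
        tr = _trace([[10_000, 0, 0, 0, 0], [10_000, 0, 0, 0, 0]])
        assert qalys(tr, UtilityInputs(), rate=0.0).sum() == pytest.approx(8_100.0)

    def test_dead_cohort_accrues_nothing(self):
        tr = _trace([[0, 0, 0, 0, 10_000], [0, 0, 0, 0, 10_000]])
        assert qalys(tr, UtilityInputs()).sum() == 0.0
        assert state_costs(tr, CostInputs()).sum() == 0.0

    def test_single_transplant_adds_oneoff_cost(self):
        tr = _trace([[0, 1, 0, 0, 0], [0, 0, 1, 0, 0]],
                    flows={"retransplant": [0, 1]})
        c = state_costs(tr, CostInputs(), rate=0.0).sum()
        # half a year in GF1, half in FG2, plus the transplant itself
        expected = (103_993.68 + 0.5 * CostInputs().dialysis_weighted
                    + 0.5 * 14_376.98)
        assert c == pytest.approx(expected)

    def test_empty_gf_states_no_dialysis_cost(self):
        tr = _trace([[100, 0, 0, 0, 0], [100, 0, 0, 0, 0]])
        c = state_costs(tr, CostInputs(), rate=0.0).sum()
        assert c == pytest.approx(100 * 14_376.98)


class TestProductivityLosses:
    def test_transplant_hospital_stay_loss(self):
        # one retransplant, living donor, male wages, 45-54 band
        prod = ProductivityInputs(male_fraction=1.0, living_donor_share=1.0)
        tr = _trace([[0, 1, 0, 0, 0], [0, 0, 1, 0, 0]],
                    flows={"retransplant": [0, 1]})
        loss = productivity_losses(tr, prod, baseline_age=50.0).sum()
        assert loss == pytest.approx(0.32 * 13.30 * 8 * 28.45)

    def test_graft_failure_job_loss_oldest_band(self):
        prod = ProductivityInputs(male_fraction=1.0)
        tr = _trace([[1, 0, 0, 0, 0], [0, 1, 0, 0, 0]],
                    flows={"gf1_events": [0, 1]})
        loss = productivity_losses(tr, prod, baseline_age=70.0).sum()
        assert loss == pytest.approx((0.061 - 0.028) * 85 * 8 * 28.45)

    def test_equal_work_shares_give_zero_job_loss(self):
        prod = ProductivityInputs(work_posttx=[0.3, 0.3, 0.03],
                                  work_dialysis=[0.3, 0.3, 0.03])
        tr = _trace([[1, 0, 0, 0, 0], [0, 1, 0, 0, 0]],
                    flows={"gf1_events": [0, 1]})
        assert productivity_losses(tr, prod, baseline_age=50.0).sum() == 0.0

    def test_death_loss_only_before_retirement(self):
        prod = ProductivityInputs(male_fraction=1.0)
        tr = _trace([[1, 0, 0, 0, 0], [0, 0, 0, 0, 1]],
                    flows={"death_fg": [0, 1]})
        young = productivity_losses(tr, prod, baseline_age=50.0).sum()
        old = productivity_losses(tr, prod, baseline_age=70.0).sum()
        assert young == pytest.approx(0.57 * 85 * 8 * 28.45)
        assert old == 0.0


class TestIncrementalResult:
    def _arm(self, cost, qaly):
        return ArmResult(health_state=cost, screening_treatment=0.0,
                         productivity=0.0, qalys=qaly)

    def test_dominant_label(self):
        res = compute_icer(self._arm(900.0, 11.0), self._arm(1000.0, 10.0))
        assert res.dominance == "dominant"
        assert res.delta_c == -100.0 and res.delta_e == 1.0

    def test_tradeoff_icer_value(self):
        res = compute_icer(self._arm(150_000.0, 11.0), self._arm(100_000.0, 10.0))
        assert res.dominance == "tradeoff"
        assert res.icer == pytest.approx(50_000.0)

    def test_identical_arms_undefined_icer(self):
        res = compute_icer(self._arm(100.0, 10.0), self._arm(100.0, 10.0))
        assert res.icer is None and res.dominance == "indifferent"

    def test_dominated_label(self):
        res = compute_icer(self._arm(1100.0, 9.0), self._arm(1000.0, 10.0))
        assert res.dominance == "dominated"


class TestModelLevelInvariants:
    def test_total_equals_sum_of_categories(self, model_inputs):
        r = run_cea(model_inputs, StrategySpec()).result
        for arm in (r.intervention, r.standard_of_care):
            assert arm.total_societal == pytest.approx(
                arm.health_state + arm.screening_treatment + arm.productivity)

    def test_payer_total_never_exceeds_societal(self, model_inputs):
        r = run_cea(model_inputs, StrategySpec()).result
        for arm in (r.intervention, r.standard_of_care):
            assert arm.total_payer <= arm.total_societal

    def test_zero_discount_qalys_equal_person_years(self, model_inputs):
        run = run_cea(model_inputs,
                      StrategySpec(disc_costs=0.0, disc_effects=0.0))
        tr = run.trace_soc
        hc = tr.half_cycle
        u = model_inputs.utilities
        expected = (hc[:, [0, 2]].sum() * u.u_fg + hc[:, [1, 3]].sum() * u.u_gf)
        assert run.result.standard_of_care.qalys == pytest.approx(expected)

    def test_worse_graft_survival_never_helps_soc_arm(self, model_inputs):
        base = run_cea(model_inputs, StrategySpec()).result.standard_of_care
        worse_inputs = model_inputs.copy()
        for g in worse_inputs.survival.gf:
            worse_inputs.survival.gf[g].params["meanlog"] -= 0.5
        worse = run_cea(worse_inputs, StrategySpec()).result.standard_of_care
        assert worse.health_state >= base.health_state
        assert worse.qalys <= base.qalys
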