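import numpy as np
import pytest

from tnbc_cea.config import default_curves
from tnbc_cea.economics import (EconomicInputs, accrue, ae_burden_first_cycle,
                                discount_factor, drug_cost_cycle,
                                subsequent_cycle_cost)
from tnbc_cea.markov import ModelConfig, run_trace
from tnbc_cea.survival import SurvivalParams

CFG = ModelConfig()
INP = EconomicInputs()


class TestDrugCost:
    def test_nab_paclitaxel_vial_arithmetic(self):
        # 125 mg/m2 x 1.84 m2 = 230 mg -> 3 vials, twice per cycle
        assert drug_cost_cycle("placebo", 0, INP, CFG) == pytest.approx(8_682.84)

    def test_combination_adds_toripalimab(self):
        assert drug_cost_cycle("combo", 0, INP, CFG) == pytest.approx(17_574.87)

    def test_zero_after_treatment_cap(self):
        assert drug_cost_cycle("combo", 40, INP, CFG) == 0.0

    def test_fractional_vials_without_rounding(self):
        cfg = CFG.with_(vial_rounding=False)
        assert drug_cost_cycle("placebo", 0, INP, cfg) == pytest.approx(
            2.3 * 1_447.14 * 2)

    def test_unknown_arm_rejected(self):
        with pytest.raises(ValueError):
            drug_cost_cycle("both", 0, INP, CFG)


class TestAEBurden:
    def test_combination_arm_cost(self):
        cost, _ = ae_burden_first_cycle("combo", INP, CFG)
        assert cost == pytest.approx(0.25 * 57.21 + 0.26 * 24_376)

    def test_control_arm_cost(self):
        cost, _ = ae_burden_first_cycle("placebo", INP, CFG)
        assert cost == pytest.approx(6_838.44, abs=0.01)

    def test_zero_incidence_means_no_burden(self):
        inp = INP.with_value("ae_leukopenia_combo", 0.0) \
                 .with_value("ae_neutropenia_combo", 0.0)
        assert ae_burden_first_cycle("combo", inp, CFG) == (0.0, 0.0)


class TestDiscounting:
    def test_no_discount_at_time_zero(self):
        assert discount_factor(0, CFG) == 1.0

    def test_one_year_factor(self):
        t_one_year = 365.25 / 21.0  # cycles per year (fractional, for the check)
        cfg = CFG
        assert (1.05) ** (-1.0) == pytest.approx(
            discount_factor(1, cfg.with_(cycle_days=365.25)))

    def test_horizon_factor(self):
        # 1.05^(−87·21/365.25) with 87 cycles spanning 5.002 years
        assert discount_factor(87, CFG) == pytest.approx(0.78345, abs=5e-5)


class TestSubsequentTherapy:
    def test_base_prices_reproduce_printed_total(self):
        assert subsequent_cycle_cost(INP) == pytest.approx(6_533.66, abs=1e-9)

    def test_chemo_price_feeds_through(self):
        dearer = INP.with_value("cost_gemcitabine_mg", 0.03)
        assert subsequent_cycle_cost(dearer) == pytest.approx(
            6_533.66 + 1_000 * 1.84 * 2 * 0.01)


class TestAccrual:
    def test_two_cycle_hand_calculation(self):
        # 2-cycle horizon, no discounting, identical PFS/OS halving each
        # cycle: every accrual term is hand-computable.
        cfg = ModelConfig(horizon_years=2 * 21 / 365.25, discount_rate_annual=0.0)
        assert cfg.n_cycles == 2
        lam = np.log(2.0) / cfg.cycle_months
        p = SurvivalParams("exponential", lam)
        trace = run_trace(p, p, cfg)
        acc = accrue(trace, "placebo", INP, cfg)
        drug = 8_682.84 * (1.0 + 0.5)
        labs = 16.36 * (1.0 + 0.5)
        imaging = (152.62 + 105.0) * 1.0          # CT cadence hits cycle 0 only
        terminal = 85_904.0 * (0.5 + 0.25)
        ae = 0.23 * 57.21 + 0.28 * 24_376
        assert acc.total_cost == pytest.approx(drug + labs + imaging + terminal + ae)
        ly = 1.5 * cfg.cycle_years
        assert acc.ly == pytest.approx(ly, rel=1e-12)
        ae_dec = (0.23 * 0.09 + 0.28 * 0.10) * cfg.cycle_years
        assert acc.qaly == pytest.approx(0.76 * ly - ae_dec, rel=1e-9)

    def test_everyone_dead_at_entry_costs_terminal_only(self):
        from tnbc_cea.markov import CohortTrace
        cfg = ModelConfig(horizon_years=2 * 21 / 365.25)
        z = np.zeros(3)
        trace = CohortTrace(pfs_occ=z, pd_occ=z, dead_occ=np.ones(3),
                            new_progressions=z,
                            new_deaths=np.array([0.0, 1.0, 0.0]),
                            pd_tunnel=np.zeros((3, 3)), config=cfg)
        inp = INP.with_value("ae_leukopenia_placebo", 0.0) \
                 .with_value("ae_neutropenia_placebo", 0.0)
        acc = accrue(trace, "placebo", inp, cfg)
        assert acc.total_cost == pytest.approx(85_904.0, rel=1e-9)
        assert acc.ly == 0.0 and acc.qaly == 0.0

    def test_qaly_equals_ly_when_utilities_are_one(self, base_traces, base_spec):
        inp = INP.with_value("u_pfs", 1.0).with_value("u_pd", 1.0) \
                 .with_value("disutil_leukopenia", 0.0) \
                 .with_value("disutil_neutropenia", 0.0)
        acc = accrue(base_traces["combo"], "combo", inp, base_spec.model)
        assert acc.qaly == pytest.approx(acc.ly, rel=1e-12)

    def test_discounting_monotonicity(self, base_spec):
        cfg0 = base_spec.model.with_(discount_rate_annual=0.0)
        curves = base_spec.curves["combo"]
        tr = run_trace(curves["pfs"], curves["os"], cfg0)
        acc0 = accrue(tr, "combo", INP, cfg0)
        tr5 = run_trace(curves["pfs"], curves["os"], base_spec.model)
        acc5 = accrue(tr5, "combo", INP, base_spec.model)
        assert acc0.total_cost > acc5.total_cost
        assert acc0.qaly > acc5.qaly

    def test_toripalimab_price_only_moves_combo_drug_cost(self, base_traces,
                                                          base_spec):
        cfg = base_spec.model
        doubled = INP.with_value("cost_toripalimab_cycle", 2 * 8_892.03)
        for arm in ("combo", "placebo"):
            a0 = accrue(base_traces[arm], arm, INP, cfg)
            a1 = accrue(base_traces[arm], arm, doubled, cfg)
            if arm == "placebo":
                assert a1.total_cost == a0.total_cost
            else:
                disc = (1.05) ** (-cfg.cycle_start_years())
                on = cfg.cycle_start_years() < cfg.treatment_cap_years
                exposure = float(np.sum(base_traces[arm].pfs_occ[:-1] * on * disc))
                assert a1.total_cost - a0.total_cost == pytest.approx(
                    8_892.03 * exposure, rel=1e-9)
            assert a1.qaly == a0.qaly

    def test_qaly_bounded_by_ly_bounded_by_horizon(self, base_traces, base_spec):
        for arm in ("combo", "placebo"):
            acc = accrue(base_traces[arm], arm, INP, base_spec.model)
            assert acc.qaly <= acc.ly <= base_spec.model.horizon_years

    def test_trace_config_mismatch_rejected(self, base_traces):
        with pytest.raises(ValueError):
            accrue(base_traces["combo"], "combo", INP,
                   ModelConfig(horizon_years=1.0))
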