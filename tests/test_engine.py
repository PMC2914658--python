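"""Projection engine: pipeline, hires, update rule, capping, properties."""

import dataclasses

import numpy as np
import pytest

from hrhsim import (
    Override, PipelineUnderflowError, ScenarioSpec,
    annual_hires, compile_schedules, init_pipeline, random_config,
    run_projection, school_outflow, step, zambia_fixture,
)
from conftest import assert_conserved


class TestInitPipeline:
    def test_doctor_cohorts_prefilled_at_baseline_enrolment(self, zambia):
        pipeline = init_pipeline(zambia)
        # training takes 7 years; cohorts back to 2001 feed hires from 2009
        assert set(range(2001, 2019)) == set(pipeline["medicine"])
        assert all(pipeline["medicine"][e] == 74 for e in range(2001, 2009))

    def test_empty_output_class_still_prefilled(self, zambia):
        pipeline = init_pipeline(zambia)
        assert all(pipeline["direct_entry_midwifery"][e] == 174
                   for e in range(2006, 2009))

    def test_zero_enrolment_gives_zero_cohorts(self, zambia):
        sched = compile_schedules(
            zambia, [Override("medicine.enrolment", 0.0, zambia.baseline_year)])
        pipeline = init_pipeline(zambia, sched)
        assert all(v == 0 for e, v in pipeline["medicine"].items() if e >= 2008)


class TestAnnualHires:
    def test_doctor_steady_state_hires(self, zambia):
        pipeline = init_pipeline(zambia)
        sched = compile_schedules(zambia)
        hires = annual_hires(pipeline, zambia.program("medicine"),
                             sched.graduation["medicine"],
                             sched.entry["medicine"], 2009)
        assert hires == pytest.approx(74 * 0.90 * 0.853)  # 56.81

    def test_identity_rates_pass_cohort_through(self, zambia):
        pipeline = init_pipeline(zambia)
        program = zambia.program("medicine")
        from hrhsim.schedules import constant_schedule
        ones = constant_schedule(1.0)
        assert annual_hires(pipeline, program, ones, ones, 2009) == 74

    def test_ramped_cohort_hired_with_lag(self, zambia):
        # doubled enrolment: the 2009 midpoint cohort (111) is hired in 2017
        sched = compile_schedules(
            zambia, [Override("medicine.enrolment_multiplier", 2.0)])
        pipeline = init_pipeline(zambia, sched)
        hires = annual_hires(pipeline, zambia.program("medicine"),
                             sched.graduation["medicine"],
                             sched.entry["medicine"], 2017)
        assert hires == pytest.approx(111 * 0.90 * 0.853)

    def test_missing_cohort_raises_underflow(self, zambia):
        pipeline = init_pipeline(zambia)
        sched = compile_schedules(zambia)
        with pytest.raises(PipelineUnderflowError):
            annual_hires(pipeline, zambia.program("medicine"),
                         sched.graduation["medicine"],
                         sched.entry["medicine"], 2000)


class TestSchoolOutflow:
    def test_base_year_feeder_outflows(self, zambia):
        sched = compile_schedules(zambia)
        out = school_outflow(zambia.programs, sched.enrolment, 2009)
        assert out["enrolled_nurses"] == pytest.approx(0.1489 * 660 + 173)
        assert out["registered_nurses"] == pytest.approx(136)
        assert "doctors" not in out

    def test_outflow_scales_with_destination_enrolment(self, zambia):
        sched = compile_schedules(
            zambia, [Override("enrolled_midwifery.enrolment_multiplier", 2.0)])
        out = school_outflow(zambia.programs, sched.enrolment, 2010)
        assert out["enrolled_nurses"] == pytest.approx(0.1489 * 660 + 2 * 173)


class TestStep:
    def test_doctor_one_step_hand_recursion(self, zambia):
        sched = compile_schedules(zambia)
        pipeline = init_pipeline(zambia)
        stocks = {c.id: c.baseline_stock for c in zambia.stock_classes}
        new = step(stocks, pipeline, zambia, sched, 2008)
        assert new["doctors"] == pytest.approx(
            806 * 0.902 + 74 * 0.90 * 0.853 + 20)  # 803.82
        assert new["clinical_officers"] == pytest.approx(
            1236 * 0.9552 + 155 * 0.90 * 0.914)  # 1308.13
        assert new["enrolled_nurses"] == pytest.approx(
            (5134 - (0.1489 * 660 + 173)) * 0.9552 + 423 * 0.943 * 0.814)

    def test_step_beyond_horizon_rejected(self, zambia):
        sched = compile_schedules(zambia)
        pipeline = init_pipeline(zambia)
        stocks = {c.id: c.baseline_stock for c in zambia.stock_classes}
        with pytest.raises(ValueError):
            step(stocks, pipeline, zambia, sched, 2018)

    def test_all_zero_flows_leave_stock_unchanged(self):
        config = random_config(11, 3, allow_feeders=False)
        zeroed = dataclasses.replace(
            config,
            stock_classes=tuple(
                dataclasses.replace(c, attrition_total=0.0,
                                    attrition_voluntary=0.0,
                                    attrition_involuntary=0.0,
                                    immigration=0.0)
                for c in config.stock_classes),
            programs=tuple(
                dataclasses.replace(p, annual_enrolment=0.0)
                for p in config.programs))
        traj = run_projection(zeroed, capping=False)
        for c in zeroed.stock_classes:
            assert np.allclose(traj.stocks[c.id], c.baseline_stock,
                               atol=1e-12)


class TestRunProjection:
    def test_base_case_2018_stocks(self, base_trajectory):
        assert round(base_trajectory.stock("doctors", 2018)) == 792
        assert round(base_trajectory.stock("clinical_officers", 2018)) == 1828
        assert round(base_trajectory.cadre_stock("midwives", 2018)) in (4273, 4274)

    def test_conservation_base_case(self, base_trajectory):
        assert_conserved(base_trajectory)

    def test_conservation_under_capped_scenario(self, zambia):
        spec = ScenarioSpec("x2", tuple(
            Override(f"{p.id}.enrolment_multiplier", 2.0)
            for p in zambia.programs))
        assert_conserved(run_projection(zambia, spec))

    @pytest.mark.parametrize("seed", range(4))
    def test_conservation_random_configs(self, seed):
        # feeder-free: the identity is exact only where the non-negativity
        # clamp never fires, and random feeders can drain a class to zero
        assert_conserved(run_projection(
            random_config(seed, 5, allow_feeders=False), capping=False))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_geometric_closed_form(self, seed):
        """Constant rates, no feeders, no cap: the recursion has the exact
        solution N_k = (1-a)^k N_0 + (H+m)(1-(1-a)^k)/a."""
        config = random_config(seed, 4, allow_feeders=False)
        traj = run_projection(config, capping=False)
        k = len(traj.years) - 1
        for c in config.stock_classes:
            program = config.programs_into_class(c.id)[0]
            H = (program.annual_enrolment * program.graduation_rate
                 * program.entry_rate)
            a = c.attrition_total
            inflow = H + c.immigration
            if a > 1e-12:
                expected = ((1 - a) ** k * c.baseline_stock
                            + inflow * (1 - (1 - a) ** k) / a)
            else:
                expected = c.baseline_stock + k * inflow
            assert traj.stocks[c.id][-1] == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("path,direction", [
        ("medicine.enrolment_multiplier", +1),
        ("medicine.graduation_rate", +1),
        ("medicine.entry_rate", +1),
        ("doctors.immigration", +1),
        ("doctors.attrition.total", -1),
    ])
    def test_final_stock_monotone_in_each_lever(self, zambia, path, direction):
        base = run_projection(zambia, capping=False).stock("doctors", 2018)
        if path.endswith("multiplier"):
            value = 1.5
        elif path.endswith("immigration"):
            value = 40.0
        elif path.endswith("total"):
            value = 0.12
        else:
            value = 1.0
        moved = run_projection(zambia, [Override(path, value)],
                               capping=False).stock("doctors", 2018)
        assert (moved - base) * direction > 0


class TestTargetCap:
    def _doubling(self, zambia):
        return ScenarioSpec("x2", tuple(
            Override(f"{p.id}.enrolment_multiplier", 2.0)
            for p in zambia.programs))

    def test_cap_never_exceeded_and_first_capped_year_exact(self, zambia):
        traj = run_projection(zambia, self._doubling(zambia))
        for k in zambia.reporting_cadres:
            stocks = traj.cadre_stocks(k.id)
            assert np.all(stocks <= k.target_stock + 1e-9)
        midwives = traj.cadre_stocks("midwives")
        first = int(np.argmax(traj.capped["midwives"]))
        assert traj.capped["midwives"][first]
        assert midwives[first] == pytest.approx(4751, abs=1e-6)
        assert midwives[-1] == pytest.approx(4751, abs=1e-6)

    def test_cap_records_enrolment_reductions(self, zambia):
        traj = run_projection(zambia, self._doubling(zambia))
        cut = traj.enrolment_reductions
        assert any(cut[p.id] for p in zambia.programs_into_cadre("midwives"))

    def test_base_case_cap_does_not_bind_within_horizon(self, zambia):
        capped = run_projection(zambia, capping=True)
        free = run_projection(zambia, capping=False)
        for c in zambia.stock_classes:
            assert np.allclose(capped.stocks[c.id], free.stocks[c.id],
                               atol=1e-9)
        assert not any(capped.capped[k.id].any()
                       for k in zambia.reporting_cadres)

    def test_unreachable_targets_make_cap_an_identity(self, zambia):
        huge = dataclasses.replace(
            zambia, reporting_cadres=tuple(
                dataclasses.replace(k, target_stock=1e12)
                for k in zambia.reporting_cadres))
        spec = self._doubling(zambia)
        capped = run_projection(huge, spec, capping=True)
        free = run_projection(huge, spec, capping=False)
        for c in zambia.stock_classes:
            assert np.allclose(capped.stocks[c.id], free.stocks[c.id],
                               atol=1e-9)
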