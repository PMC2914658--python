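"""Configuration types, validation, fixture values and file round-trips."""

import dataclasses

import pandas as pd
import pytest

from hrhsim import (
    Feeder, ProgramSpec, ReportingCadre, StockClass, ModelConfig,
    SchemaError, ValidationError,
    load_config, write_config, random_config, run_projection,
    write_trajectory_csv,
)
from hrhsim.params import config_from_dict, config_to_dict, validate_config


class TestZambiaFixture:
    def test_structure(self, zambia):
        assert len(zambia.stock_classes) == 7
        assert len(zambia.programs) == 7
        assert len(zambia.reporting_cadres) == 4
        assert zambia.baseline_year == 2008
        assert zambia.horizon_year == 2018

    def test_published_totals(self, zambia):
        assert sum(c.baseline_stock for c in zambia.stock_classes) == 10679
        assert sum(p.annual_enrolment for p in zambia.programs) == 1795
        assert sum(k.target_stock for k in zambia.reporting_cadres) == 24319

    def test_doctor_attrition_split(self, zambia):
        doctors = zambia.stock_class("doctors")
        assert doctors.attrition_voluntary == pytest.approx(0.0314)
        assert doctors.attrition_involuntary == pytest.approx(0.0666)
        assert doctors.attrition_total == pytest.approx(0.0980)
        assert doctors.immigration == 20

    def test_feeder_links(self, zambia):
        rn = zambia.program("registered_nursing")
        assert rn.feeder == Feeder("enrolled_nurses", 0.1489)
        assert zambia.program("registered_midwifery").feeder == \
            Feeder("registered_nurses", 1.0)
        assert zambia.program("enrolled_midwifery").feeder == \
            Feeder("enrolled_nurses", 1.0)
        assert zambia.program("direct_entry_midwifery").feeder is None

    def test_midwife_cadre_groups_three_classes(self, zambia):
        assert zambia.cadre("midwives").member_classes == (
            "registered_midwives", "enrolled_midwives", "direct_entry_midwives")


class TestValidation:
    def test_out_of_range_graduation_rate_rejected(self, zambia):
        raw = config_to_dict(zambia)
        raw["programs"][0]["graduation_rate"] = 1.2
        with pytest.raises(ValidationError, match="graduation_rate"):
            config_from_dict(raw)

    def test_unknown_key_rejected(self, zambia):
        raw = config_to_dict(zambia)
        raw["stock_classes"][0]["typo_key"] = 1
        with pytest.raises(SchemaError, match="typo_key"):
            config_from_dict(raw)

    def test_dangling_feeder_source_rejected(self, zambia):
        raw = config_to_dict(zambia)
        raw["programs"][2]["feeder"]["source_class"] = "ghosts"
        with pytest.raises(ValidationError, match="ghosts"):
            config_from_dict(raw)

    def test_attrition_split_must_match_total(self, zambia):
        raw = config_to_dict(zambia)
        raw["stock_classes"][0]["attrition"] = {
            "total": 0.10, "voluntary": 0.0314, "involuntary": 0.0666}
        with pytest.raises(ValidationError, match="disagrees"):
            config_from_dict(raw)

    def test_feeder_cycle_rejected(self):
        config = random_config(0, 2, allow_feeders=False)
        p0, p1 = config.programs
        programs = (
            dataclasses.replace(p0, feeder=Feeder("class_1", 0.5)),
            dataclasses.replace(p1, feeder=Feeder("class_0", 0.5)),
        )
        with pytest.raises(ValidationError, match="cycle"):
            validate_config(dataclasses.replace(config, programs=programs))

    def test_horizon_must_follow_baseline(self, zambia):
        with pytest.raises(ValidationError, match="horizon"):
            validate_config(dataclasses.replace(zambia, horizon_year=2008))

    def test_total_only_attrition_split_by_shares(self):
        raw = config_to_dict(random_config(1, 1, allow_feeders=False))
        raw["stock_classes"][0]["attrition"] = {"total": 0.10}
        config = config_from_dict(raw)
        c = config.stock_classes[0]
        assert c.attrition_voluntary == pytest.approx(0.032)
        assert c.attrition_total == pytest.approx(0.10)


class TestRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_write_then_load_is_identity(self, tmp_path, seed):
        config = random_config(seed, 5)
        path = tmp_path / "config.yaml"
        write_config(config, path)
        assert load_config(path) == config

    def test_fixture_round_trips(self, zambia, tmp_path):
        path = tmp_path / "zambia.yaml"
        write_config(zambia, path)
        assert load_config(path) == zambia


class TestRandomConfig:
    def test_same_seed_same_config(self):
        assert random_config(42, 6) == random_config(42, 6)

    def test_different_seeds_differ(self):
        assert random_config(1, 6) != random_config(2, 6)

    @pytest.mark.parametrize("seed", range(6))
    def test_generated_configs_validate(self, seed):
        validate_config(random_config(seed, 4))

    def test_requires_at_least_one_class(self):
        with pytest.raises(ValueError):
            random_config(0, 0)


class TestTrajectoryCsv:
    def test_row_count_and_reread(self, base_trajectory, tmp_path):
        path = tmp_path / "trajectory.csv"
        write_trajectory_csv(base_trajectory, path)
        frame = pd.read_csv(path)
        assert len(frame) == 7 * 11
        # stocks survive the text round-trip bit-for-bit
        doctors = frame[frame.stock_class == "doctors"].sort_values("year")
        assert list(doctors.stock) == list(base_trajectory.stocks["doctors"])

    def test_empty_trajectory_rejected(self, base_trajectory, tmp_path):
        class Empty:
            def to_frame(self):
                return pd.DataFrame()

        with pytest.raises(ValueError, match="empty"):
            write_trajectory_csv(Empty(), tmp_path / "x.csv")
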