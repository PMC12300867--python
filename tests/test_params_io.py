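"""Parameter model, built-in Japan-2019 values, table I/O and validation."""

import dataclasses

import pandas as pd
import pytest

from dietmarkov import (builtin_japan_2019, load_parameter_set,
                        validate_parameter_set, write_parameter_set)
from dietmarkov.errors import DataError, ParseError, SchemaError


class TestBuiltinFixture:
    def test_has_8_unique_strata_with_costs(self, japan):
        assert len(japan.strata) == 8
        assert len(set(japan.keys())) == 8
        assert {c.key for c in japan.costs} == set(japan.keys())

    @pytest.mark.parametrize("sex, band, field, value", [
        ("men", "40-49", "incidence", 386.9),
        ("men", "70-79", "prevalence", 18541.9),
        ("women", "40-49", "t2d_mortality", 0.3),
        ("women", "70-79", "all_cause_mortality", 1205.0),
    ])
    def test_published_point_rates(self, japan, sex, band, field, value):
        assert getattr(japan.stratum(sex, band), field).value == value

    def test_published_ci_bounds(self, japan):
        inc = japan.stratum("men", "40-49").incidence
        assert (inc.ci_low, inc.ci_high) == (289.6, 498.6)

    def test_costs_and_scalars(self, japan):
        assert japan.cost("women", "70-79").annual_outpatient_nhe == 985_138_127
        assert japan.cost("men", "40-49").annual_outpatient_nhe == 320_339_533
        assert japan.discount_rate == 0.02
        assert japan.horizon == 10
        dr = japan.dose_response
        assert (dr.rr_per_increment, dr.ci_low, dr.ci_high, dr.increment) == \
            (0.93, 0.89, 0.97, 50.0)

    def test_population_marginals(self, japan):
        total = sum(s.population for s in japan.strata)
        men = sum(s.population for s in japan.strata if s.sex == "men")
        women = sum(s.population for s in japan.strata if s.sex == "women")
        assert total == 66_958_000
        assert men == 32_798_000
        assert women == 34_160_000

    def test_validates_clean(self, japan):
        report = validate_parameter_set(japan)
        assert report.is_valid, str(report)


class TestRoundTrip:
    @pytest.mark.parametrize("config_name", ["config.json", "config.yaml"])
    def test_write_then_read_is_identity(self, japan, tmp_path, config_name):
        paths = (tmp_path / "strata.csv", tmp_path / "costs.csv",
                 tmp_path / config_name)
        write_parameter_set(japan, *paths)
        assert load_parameter_set(*paths) == japan  # field-for-field


def _write_fixture_tables(japan, tmp_path):
    paths = (tmp_path / "strata.csv", tmp_path / "costs.csv",
             tmp_path / "config.json")
    write_parameter_set(japan, *paths)
    return paths


class TestLoadErrors:
    def test_missing_column_names_it(self, japan, tmp_path):
        strata, costs, config = _write_fixture_tables(japan, tmp_path)
        df = pd.read_csv(strata).drop(columns=["prevalence_per100k"])
        df.to_csv(strata, index=False)
        with pytest.raises(SchemaError, match="prevalence_per100k"):
            load_parameter_set(strata, costs, config)

    def test_duplicate_stratum_rejected(self, japan, tmp_path):
        strata, costs, config = _write_fixture_tables(japan, tmp_path)
        df = pd.read_csv(strata)
        pd.concat([df, df.iloc[[0]]]).to_csv(strata, index=False)
        with pytest.raises(DataError, match="duplicate"):
            load_parameter_set(strata, costs, config)

    def test_non_numeric_rate_reports_row(self, japan, tmp_path):
        strata, costs, config = _write_fixture_tables(japan, tmp_path)
        df = pd.read_csv(strata)
        df["incidence_per100k"] = df["incidence_per100k"].astype(object)
        df.loc[3, "incidence_per100k"] = "n/a"
        df.to_csv(strata, index=False)
        with pytest.raises(ParseError, match="row 3"):
            load_parameter_set(strata, costs, config)

    def test_t2d_mortality_above_all_cause_names_stratum(self, japan,
                                                         tmp_path):
        strata, costs, config = _write_fixture_tables(japan, tmp_path)
        df = pd.read_csv(strata)
        row = df.index[(df.sex == "women") & (df.age_band == "50-59")][0]
        df.loc[row, ["t2d_mort_per100k", "t2d_mort_lo", "t2d_mort_hi"]] = 999.0
        df.to_csv(strata, index=False)
        with pytest.raises(DataError, match="women 50-59"):
            load_parameter_set(strata, costs, config)


class TestValidateParameterSet:
    def test_negative_discount_is_one_violation(self, japan):
        report = validate_parameter_set(japan.replace(discount_rate=-0.01))
        assert len(report.violations) == 1
        assert "discount_rate" in report.violations[0]

    def test_ci_not_bracketing_names_stratum(self, japan):
        bad = []
        for s in japan.strata:
            if s.key == ("men", "60-69"):
                s = dataclasses.replace(
                    s, incidence=dataclasses.replace(s.incidence,
                                                     ci_low=s.incidence.value + 1))
            bad.append(s)
        report = validate_parameter_set(japan.replace(strata=tuple(bad)))
        assert len(report.violations) == 1
        assert "men 60-69" in report.violations[0]
        assert "incidence" in report.violations[0]

    def test_missing_cost_entry_reported(self, japan):
        report = validate_parameter_set(japan.replace(costs=japan.costs[:-1]))
        assert not report.is_valid
        assert any("no cost entry" in v for v in report.violations)
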