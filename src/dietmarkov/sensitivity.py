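"""Deterministic one-way sensitivity analysis (tornado data).

Each analysis replaces ONE parameter family with its lower and then its
upper 95% CI bound -- simultaneously in every stratum it touches -- re-runs
both the baseline and the intervention scenario under the perturbed value,
and reports the resulting discounted-expenditure savings.  The discount
rate is varied over a fixed 0-4% policy range instead of a CI.

``low``/``high`` columns are ordered by PARAMETER bound, not by output
size: for a protective relative risk the lower RR bound produces the
larger savings, so the outputs legitimately invert.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

from . import comparison
from .errors import ModelError
from .params_io import ParameterSet, RateWithCI, StratumParams
from .risk_model import Scenario

#: parameter families supported by one_way()
PARAMETERS = ("incidence", "prevalence", "t2d_mortality",
              "all_cause_mortality", "relative_risk", "discount_rate")

_RATE_FIELDS = ("incidence", "prevalence", "t2d_mortality",
                "all_cause_mortality")

DISCOUNT_RANGE = (0.0, 0.04)


@dataclass(frozen=True)
class SensitivityRow:
    scenario: str
    sex: str
    parameter: str
    low_savings: float       # savings when the parameter sits at its lower bound
    high_savings: float      # ... at its upper bound
    expected_savings: float  # savings at the point estimates

    @property
    def width(self) -> float:
        return abs(self.high_savings - self.low_savings)


def _rate_at_bound(rate: RateWithCI, bound: str) -> RateWithCI:
    value = rate.ci_low if bound == "low" else rate.ci_high
    return RateWithCI(value=value, ci_low=min(rate.ci_low, value),
                      ci_high=max(rate.ci_high, value))


def _perturb_strata(ps: ParameterSet, field: str, bound: str) -> ParameterSet:
    new_strata = tuple(
        dc_replace(s, **{field: _rate_at_bound(getattr(s, field), bound)})
        for s in ps.strata)
    return ps.replace(strata=new_strata)


def _perturbed_set(ps: ParameterSet, parameter: str,
                   bound: str) -> ParameterSet:
    if parameter in _RATE_FIELDS:
        return _perturb_strata(ps, parameter, bound)
    if parameter == "relative_risk":
        dr = ps.dose_response
        value = dr.ci_low if bound == "low" else dr.ci_high
        return ps.replace(dose_response=dc_replace(dr, rr_per_increment=value))
    if parameter == "discount_rate":
        return ps.replace(discount_rate=DISCOUNT_RANGE[0] if bound == "low"
                          else DISCOUNT_RANGE[1])
    raise ModelError(f"unknown parameter {parameter!r}; supported: "
                     f"{', '.join(PARAMETERS)}")


def _savings_by_sex(ps: ParameterSet, scenario: Scenario,
                    cost_timing: str) -> dict[str, float]:
    base = comparison.run_scenario(ps, Scenario("baseline"),
                                   cost_timing=cost_timing)
    interv = comparison.run_scenario(ps, scenario, cost_timing=cost_timing)
    comp = comparison.compare(base, interv)
    return {sex: comp.prevented(sex=sex).nhe_usd for sex in base.sexes}


def one_way(ps: ParameterSet, scenario: Scenario, parameter: str,
            cost_timing: str = "end") -> list[SensitivityRow]:
    """One SensitivityRow per sex for a single perturbed parameter."""
    if parameter not in PARAMETERS:
        raise ModelError(f"unknown parameter {parameter!r}; supported: "
                         f"{', '.join(PARAMETERS)}")
    expected = _savings_by_sex(ps, scenario, cost_timing)
    low = _savings_by_sex(_perturbed_set(ps, parameter, "low"),
                          scenario, cost_timing)
    high = _savings_by_sex(_perturbed_set(ps, parameter, "high"),
                           scenario, cost_timing)
    return [SensitivityRow(scenario=scenario.name, sex=sex,
                           parameter=parameter, low_savings=low[sex],
                           high_savings=high[sex],
                           expected_savings=expected[sex])
            for sex in expected]


def tornado(ps: ParameterSet, scenario: Scenario,
            cost_timing: str = "end") -> dict[str, list[SensitivityRow]]:
    """All six one-way analyses, per sex, widest output range first
    (ties broken alphabetically by parameter name)."""
    rows: dict[str, list[SensitivityRow]] = {}
    for parameter in PARAMETERS:
        for row in one_way(ps, scenario, parameter, cost_timing=cost_timing):
            rows.setdefault(row.sex, []).append(row)
    return {sex: sorted(sex_rows, key=lambda r: (-r.width, r.parameter))
            for sex, sex_rows in rows.items()}


def tornado_table(rows: dict[str, list[SensitivityRow]]):
    import pandas as pd

    return pd.DataFrame([
        {"sex": row.sex, "parameter": row.parameter,
         "low_savings_usd": row.low_savings,
         "high_savings_usd": row.high_savings,
         "expected_savings_usd": row.expected_savings}
        for sex_rows in rows.values() for row in sex_rows])


def tornado_plot(rows: list[SensitivityRow], path) -> None:
    """Horizontal-bar tornado diagram for one sex."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = sorted(rows, key=lambda r: r.width)
    labels = [r.parameter for r in ordered]
    expected = ordered[0].expected_savings if ordered else 0.0
    fig, ax = plt.subplots(figsize=(7, 0.6 * max(len(ordered), 1) + 1.2))
    for i, row in enumerate(ordered):
        lo = min(row.low_savings, row.high_savings)
        ax.barh(i, row.width, left=lo, color="#4878a8")
    ax.axvline(expected, color="k", lw=1, ls="--")
    ax.set_yticks(range(len(ordered)), labels)
    ax.set_xlabel("cumulative savings (USD)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
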