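"""Scenario execution and baseline-vs-intervention comparison.

``run_scenario`` composes the risk model, the cohort engine and the cost
accrual for every stratum of a parameter set; ``compare`` differences two
scenario results into prevented incident cases, prevented T2D deaths and
saved discounted expenditure, absolute and as a percent of baseline, at the
stratum level and aggregated by sex and overall.  Percentages are always
computed from unrounded aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import economics, markov_cohort, risk_model
from .errors import DietMarkovError, ModelError
from .params_io import ParameterSet
from .risk_model import Scenario

Key = tuple[str, str]

#: outcome column names shared by result tables
OUTCOMES = ("incidence", "t2d_deaths", "nhe_usd")


@dataclass(frozen=True)
class StratumOutcome:
    incidence: float   # cumulative incident cases, persons
    t2d_deaths: float  # cumulative T2D deaths, persons
    nhe_usd: float     # cumulative discounted outpatient expenditure, USD

    def __sub__(self, other: "StratumOutcome") -> "StratumOutcome":
        return StratumOutcome(self.incidence - other.incidence,
                              self.t2d_deaths - other.t2d_deaths,
                              self.nhe_usd - other.nhe_usd)

    def __add__(self, other: "StratumOutcome") -> "StratumOutcome":
        return StratumOutcome(self.incidence + other.incidence,
                              self.t2d_deaths + other.t2d_deaths,
                              self.nhe_usd + other.nhe_usd)


_ZERO = StratumOutcome(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ScenarioResult:
    """Cumulative outcomes per stratum, plus traces, for one scenario run."""

    scenario: str
    per_stratum: dict[Key, StratumOutcome]
    traces: dict[Key, markov_cohort.CohortTrace] = field(repr=False,
                                                         default_factory=dict)

    def aggregate(self, sex: str | None = None) -> StratumOutcome:
        total = _ZERO
        for key, outcome in self.per_stratum.items():
            if sex is None or key[0] == sex:
                total = total + outcome
        return total

    @property
    def sexes(self) -> list[str]:
        seen = []
        for sex, _ in self.per_stratum:
            if sex not in seen:
                seen.append(sex)
        return seen


@dataclass(frozen=True)
class ComparisonResult:
    """Baseline minus scenario, with percent-of-baseline, at every level."""

    baseline: ScenarioResult
    scenario: ScenarioResult

    def prevented(self, key: Key | None = None,
                  sex: str | None = None) -> StratumOutcome:
        if key is not None:
            return self.baseline.per_stratum[key] - self.scenario.per_stratum[key]
        return self.baseline.aggregate(sex) - self.scenario.aggregate(sex)

    def percent_of_baseline(self, key: Key | None = None,
                            sex: str | None = None) -> StratumOutcome:
        base = (self.baseline.per_stratum[key] if key is not None
                else self.baseline.aggregate(sex))
        diff = self.prevented(key=key, sex=sex)

        def pct(d: float, b: float) -> float:
            if b == 0:
                raise ModelError("percent of a zero baseline is undefined")
            return 100.0 * d / b

        return StratumOutcome(pct(diff.incidence, base.incidence),
                              pct(diff.t2d_deaths, base.t2d_deaths),
                              pct(diff.nhe_usd, base.nhe_usd))


def run_scenario(ps: ParameterSet, scenario: Scenario,
                 cost_timing: str = "end") -> ScenarioResult:
    """Run one scenario across every stratum of the parameter set."""
    rr_table = risk_model.scenario_rr_table(ps, scenario)
    per_stratum: dict[Key, StratumOutcome] = {}
    traces: dict[Key, markov_cohort.CohortTrace] = {}
    for stratum in ps.strata:
        trace = markov_cohort.run_cohort(stratum, rr_table[stratum.key],
                                         ps.horizon)
        unit_cost = economics.per_patient_annual_cost(
            ps.cost(*stratum.key), stratum)
        per_stratum[stratum.key] = StratumOutcome(
            incidence=markov_cohort.cumulative_incidence(trace),
            t2d_deaths=markov_cohort.cumulative_t2d_deaths(trace),
            nhe_usd=economics.cumulative_discounted_nhe(
                trace, unit_cost, ps.discount_rate, timing=cost_timing),
        )
        traces[stratum.key] = trace
    return ScenarioResult(scenario=scenario.name, per_stratum=per_stratum,
                          traces=traces)


def compare(baseline: ScenarioResult,
            scenario: ScenarioResult) -> ComparisonResult:
    if set(baseline.per_stratum) != set(scenario.per_stratum):
        raise ModelError("cannot compare results over different strata")
    return ComparisonResult(baseline=baseline, scenario=scenario)


# --------------------------------------------------------------------------
# reporting
# --------------------------------------------------------------------------

def scenario_table(result: ScenarioResult,
                   ps: ParameterSet) -> pd.DataFrame:
    """Cumulative-outcome table: one row per stratum, per-sex subtotals and
    an overall total (the layout of a published projection table)."""
    rows = []
    for sex in result.sexes:
        agg = result.aggregate(sex)
        pop = sum(s.population for s in ps.strata if s.sex == sex)
        rows.append({"sex": sex, "age_band": "all", "population": pop,
                     "incidence": agg.incidence, "t2d_deaths": agg.t2d_deaths,
                     "nhe_usd": agg.nhe_usd})
        for key, outcome in result.per_stratum.items():
            if key[0] != sex:
                continue
            stratum = ps.stratum(*key)
            rows.append({"sex": sex, "age_band": key[1],
                         "population": stratum.population,
                         "incidence": outcome.incidence,
                         "t2d_deaths": outcome.t2d_deaths,
                         "nhe_usd": outcome.nhe_usd})
    total = result.aggregate()
    rows.append({"sex": "all", "age_band": "all",
                 "population": sum(s.population for s in ps.strata),
                 "incidence": total.incidence, "t2d_deaths": total.t2d_deaths,
                 "nhe_usd": total.nhe_usd})
    return pd.DataFrame(rows)


def comparison_table(comp: ComparisonResult) -> pd.DataFrame:
    """Prevented/saved outcomes with percent-of-baseline, same layout."""
    rows = []

    def record(sex: str, band: str, diff: StratumOutcome,
               pct: StratumOutcome) -> None:
        rows.append({"sex": sex, "age_band": band,
                     "prevented_incidence": diff.incidence,
                     "prevented_incidence_pct": pct.incidence,
                     "prevented_deaths": diff.t2d_deaths,
                     "prevented_deaths_pct": pct.t2d_deaths,
                     "saved_nhe_usd": diff.nhe_usd,
                     "saved_nhe_pct": pct.nhe_usd})

    for sex in comp.baseline.sexes:
        record(sex, "all", comp.prevented(sex=sex),
               comp.percent_of_baseline(sex=sex))
        for key in comp.baseline.per_stratum:
            if key[0] == sex:
                record(sex, key[1], comp.prevented(key=key),
                       comp.percent_of_baseline(key=key))
    record("all", "all", comp.prevented(), comp.percent_of_baseline())
    return pd.DataFrame(rows)


def render_report(out_dir: str | Path, ps: ParameterSet,
                  baseline: ScenarioResult,
                  comparisons: dict[str, ComparisonResult]) -> list[Path]:
    """Write the projection table, one comparison table per scenario, and a
    rounded human-readable summary.  Returns the written paths."""
    if not baseline.per_stratum:
        raise DietMarkovError("empty result set, nothing to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    path = out / f"projection_{baseline.scenario}.csv"
    scenario_table(baseline, ps).to_csv(path, index=False)
    written.append(path)

    lines = [f"Baseline scenario over {ps.horizon} annual cycles "
             f"(discount {ps.discount_rate:.0%}/year)"]
    total = baseline.aggregate()
    lines.append(f"  cumulative incident T2D cases: {total.incidence:,.0f}")
    lines.append(f"  cumulative T2D deaths:         {total.t2d_deaths:,.0f}")
    lines.append(f"  cumulative discounted NHE:     USD {total.nhe_usd:,.0f}")

    for name, comp in comparisons.items():
        path = out / f"comparison_{name}.csv"
        comparison_table(comp).to_csv(path, index=False)
        written.append(path)
        diff = comp.prevented()
        pct = comp.percent_of_baseline()
        lines.append(f"{name} vs baseline:")
        lines.append(f"  prevented incident cases: {diff.incidence:,.0f} "
                     f"({pct.incidence:.1f}%)")
        lines.append(f"  prevented T2D deaths:     {diff.t2d_deaths:,.0f} "
                     f"({pct.t2d_deaths:.1f}%)")
        lines.append(f"  saved discounted NHE:     USD {diff.nhe_usd:,.0f} "
                     f"({pct.nhe_usd:.1f}%)")

    summary = out / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    written.append(summary)
    return written
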