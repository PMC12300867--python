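"""Parameter data model, table I/O, validation, and the built-in Japan-2019 set.

The model is parameterized per sex x age-band stratum with the quantities a
national burden-of-disease database publishes: population counts, mean daily
yogurt intake, and annual type-2-diabetes (T2D) incidence, prevalence, T2D
mortality and all-cause mortality, each as a point estimate per 100,000 with
95% CI bounds.  Rates are stored exactly as published (per 100,000) and are
converted to per-cycle probabilities only inside the cohort engine, so no
precision is lost to double rounding.

Tabular data travels as CSV (one row per stratum, mirroring the published
tables); the scalar configuration (discount rate, horizon, dose-response
relative risk) travels as JSON or YAML.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import DataError, ParseError, SchemaError

SEXES = ("men", "women")
AGE_BANDS = ("40-49", "50-59", "60-69", "70-79")

#: column layout of the stratum CSV
STRATA_COLUMNS = (
    "sex", "age_band", "population", "mean_intake_g",
    "incidence_per100k", "incidence_lo", "incidence_hi",
    "prevalence_per100k", "prevalence_lo", "prevalence_hi",
    "t2d_mort_per100k", "t2d_mort_lo", "t2d_mort_hi",
    "allcause_mort_per100k", "allcause_mort_lo", "allcause_mort_hi",
)

#: column layout of the cost CSV
COST_COLUMNS = ("sex", "age_band", "annual_outpatient_nhe_usd")

#: keys of the scalar config file
CONFIG_KEYS = ("discount_rate", "horizon_years", "rr_per_increment",
               "rr_ci_low", "rr_ci_high", "increment_g")


@dataclass(frozen=True)
class RateWithCI:
    """A rate per 100,000 (or a dimensionless ratio) with 95% CI bounds."""

    value: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        for name in ("value", "ci_low", "ci_high"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ParseError(f"non-finite {name}: {v!r}")


@dataclass(frozen=True)
class StratumParams:
    """Demographic and epidemiological rates for one sex x age-band stratum."""

    sex: str
    age_band: str
    population: float            # persons, baseline year
    mean_intake: float           # g/day
    incidence: RateWithCI        # per 100,000 / year
    prevalence: RateWithCI       # per 100,000
    t2d_mortality: RateWithCI    # per 100,000 / year
    all_cause_mortality: RateWithCI  # per 100,000 / year

    @property
    def key(self) -> tuple[str, str]:
        return (self.sex, self.age_band)


@dataclass(frozen=True)
class DoseResponse:
    """Relative risk of T2D incidence per fixed daily-intake increment.

    ``rr_per_increment`` is the multiplicative risk change for every
    ``increment`` g/day of additional intake; it is extrapolated
    log-linearly to other intake changes by the risk model.
    """

    rr_per_increment: float = 0.93
    increment: float = 50.0      # g/day
    ci_low: float = 0.89
    ci_high: float = 0.97


@dataclass(frozen=True)
class CostEntry:
    """Annual outpatient national healthcare expenditure for one stratum's
    prevalent T2D population, in the baseline year (USD)."""

    sex: str
    age_band: str
    annual_outpatient_nhe: float

    @property
    def key(self) -> tuple[str, str]:
        return (self.sex, self.age_band)


@dataclass(frozen=True)
class ParameterSet:
    """Everything the pipeline needs: strata, costs, dose-response, scalars."""

    strata: tuple[StratumParams, ...]
    costs: tuple[CostEntry, ...]
    dose_response: DoseResponse = field(default_factory=DoseResponse)
    discount_rate: float = 0.02  # fraction / year
    horizon: int = 10            # years (annual cycles)

    def stratum(self, sex: str, age_band: str) -> StratumParams:
        for s in self.strata:
            if s.key == (sex, age_band):
                return s
        raise KeyError((sex, age_band))

    def cost(self, sex: str, age_band: str) -> CostEntry:
        for c in self.costs:
            if c.key == (sex, age_band):
                return c
        raise KeyError((sex, age_band))

    def keys(self) -> list[tuple[str, str]]:
        return [s.key for s in self.strata]

    def replace(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)


@dataclass
class ValidationReport:
    """Accumulated invariant violations; empty means the set is valid."""

    violations: list[str] = field(default_factory=list)

    def add(self, message: str) -> None:
        self.violations.append(message)

    @property
    def is_valid(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy iff clean
        return self.is_valid

    def __str__(self) -> str:
        if self.is_valid:
            return "parameter set valid"
        return "parameter set invalid:\n" + "\n".join(
            f"  - {v}" for v in self.violations)


# --------------------------------------------------------------------------
# built-in Japan 2019 parameter set
# --------------------------------------------------------------------------

# (sex, age band): population, intake g/day,
#   incidence (lo, hi), prevalence (lo, hi),
#   T2D mortality (lo, hi), all-cause mortality (lo, hi) -- all per 100,000
_JAPAN_2019 = {
    ("men", "40-49"): (9_374_000, 24.5,
                       (386.9, 289.6, 498.6), (5716.5, 4728.7, 6726.4),
                       (1.1, 1.0, 1.3), (150.6, 147.9, 153.4)),
    ("men", "50-59"): (8_161_000, 31.1,
                       (520.9, 406.6, 658.2), (10032.7, 8734.0, 11449.3),
                       (3.5, 3.2, 3.8), (390.6, 383.1, 398.5)),
    ("men", "60-69"): (7_930_000, 34.4,
                       (517.9, 385.1, 661.3), (15065.7, 13385.8, 16975.4),
                       (7.6, 7.0, 8.2), (996.9, 979.4, 1015.4)),
    ("men", "70-79"): (7_333_000, 40.9,
                       (317.7, 224.6, 418.3), (18541.9, 16590.8, 20761.4),
                       (17.0, 15.5, 18.4), (2579.2, 2538.1, 2622.3)),
    ("women", "40-49"): (9_147_000, 34.1,
                         (224.1, 163.3, 295.4), (3310.0, 2697.6, 3992.1),
                         (0.3, 0.3, 0.4), (88.2, 86.6, 90.0)),
    ("women", "50-59"): (8_117_000, 44.7,
                         (327.5, 244.7, 430.3), (5957.5, 5070.1, 7038.2),
                         (0.9, 0.8, 1.0), (201.1, 197.4, 205.1)),
    ("women", "60-69"): (8_302_000, 47.3,
                         (365.9, 262.1, 483.7), (9303.4, 8126.7, 10724.5),
                         (2.7, 2.5, 3.0), (439.3, 432.3, 446.8)),
    ("women", "70-79"): (8_594_000, 51.4,
                         (303.0, 220.4, 395.8), (12210.5, 10786.8, 13856.9),
                         (8.9, 7.5, 9.9), (1205.0, 1187.4, 1223.8)),
}

# annual outpatient NHE for the prevalent T2D population, 2019 USD
_JAPAN_2019_NHE = {
    ("men", "40-49"): 320_339_533,
    ("men", "50-59"): 599_793_593,
    ("men", "60-69"): 1_085_266_222,
    ("men", "70-79"): 1_452_129_242,
    ("women", "40-49"): 149_412_727,
    ("women", "50-59"): 284_612_996,
    ("women", "60-69"): 620_583_959,
    ("women", "70-79"): 985_138_127,
}


def builtin_japan_2019() -> ParameterSet:
    """The Japanese population aged 40-79 in 2019: 8 strata (2 sexes x 4
    ten-year age bands), with outpatient diabetes expenditures, a 2%/year
    discount rate, a 10-year horizon and a dose-response relative risk of
    0.93 (95% CI 0.89-0.97) per 50 g/day of additional yogurt intake."""
    strata = []
    costs = []
    for sex in SEXES:
        for band in AGE_BANDS:
            pop, intake, inc, prev, tmort, amort = _JAPAN_2019[(sex, band)]
            strata.append(StratumParams(
                sex=sex, age_band=band, population=float(pop),
                mean_intake=intake,
                incidence=RateWithCI(*inc),
                prevalence=RateWithCI(*prev),
                t2d_mortality=RateWithCI(*tmort),
                all_cause_mortality=RateWithCI(*amort),
            ))
            costs.append(CostEntry(sex, band,
                                   float(_JAPAN_2019_NHE[(sex, band)])))
    return ParameterSet(strata=tuple(strata), costs=tuple(costs))


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

def _check_rate(report: ValidationReport, key: tuple[str, str],
                name: str, rate: RateWithCI) -> None:
    label = f"{key[0]} {key[1]}"
    if not (0.0 <= rate.value < 100_000.0):
        report.add(f"{label}: {name} {rate.value} outside [0, 100000)")
    if not (rate.ci_low <= rate.value <= rate.ci_high):
        report.add(f"{label}: {name} CI ({rate.ci_low}, {rate.ci_high}) "
                   f"does not bracket point {rate.value}")


def validate_parameter_set(ps: ParameterSet) -> ValidationReport:
    """Check every invariant; returns a report instead of raising, so a
    caller can show all problems at once."""
    report = ValidationReport()

    seen: set[tuple[str, str]] = set()
    for s in ps.strata:
        label = f"{s.sex} {s.age_band}"
        if s.key in seen:
            report.add(f"{label}: duplicate stratum")
        seen.add(s.key)
        if s.population <= 0:
            report.add(f"{label}: population {s.population} must be > 0")
        if s.mean_intake < 0:
            report.add(f"{label}: mean_intake {s.mean_intake} must be >= 0")
        _check_rate(report, s.key, "incidence", s.incidence)
        _check_rate(report, s.key, "prevalence", s.prevalence)
        _check_rate(report, s.key, "t2d_mortality", s.t2d_mortality)
        _check_rate(report, s.key, "all_cause_mortality", s.all_cause_mortality)
        if s.t2d_mortality.value > s.all_cause_mortality.value:
            report.add(f"{label}: t2d_mortality {s.t2d_mortality.value} exceeds "
                       f"all_cause_mortality {s.all_cause_mortality.value}")

    cost_keys = {c.key for c in ps.costs}
    for c in ps.costs:
        if c.annual_outpatient_nhe < 0:
            report.add(f"{c.sex} {c.age_band}: negative annual cost "
                       f"{c.annual_outpatient_nhe}")
    for s in ps.strata:
        if s.key not in cost_keys:
            report.add(f"{s.sex} {s.age_band}: no cost entry")
    if len(ps.costs) != len(cost_keys):
        report.add("duplicate cost entries")

    dr = ps.dose_response
    if not (0 < dr.ci_low <= dr.rr_per_increment <= dr.ci_high):
        report.add(f"dose_response: CI ({dr.ci_low}, {dr.ci_high}) must satisfy "
                   f"0 < lo <= {dr.rr_per_increment} <= hi")
    if dr.increment <= 0:
        report.add(f"dose_response: increment {dr.increment} must be > 0")
    if ps.discount_rate < 0:
        report.add(f"discount_rate {ps.discount_rate} must be >= 0")
    if ps.horizon < 1:
        report.add(f"horizon {ps.horizon} must be >= 1")
    return report


# --------------------------------------------------------------------------
# CSV / config I/O
# --------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, columns: Iterable[str],
                     path: str | Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _numeric(df: pd.DataFrame, column: str, path: str | Path) -> pd.Series:
    converted = pd.to_numeric(df[column], errors="coerce")
    bad = converted.isna() & df[column].notna()
    if bad.any() or df[column].isna().any():
        row = int((converted.isna()).idxmax())
        raise ParseError(f"{path}: non-numeric value in column {column!r} "
                         f"at row {row}")
    return converted.astype(float)


def read_strata_csv(path: str | Path) -> tuple[StratumParams, ...]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, STRATA_COLUMNS, path)
    numeric = {c: _numeric(df, c, path) for c in STRATA_COLUMNS[2:]}
    strata = []
    seen: set[tuple[str, str]] = set()
    for i in df.index:
        key = (str(df.at[i, "sex"]).strip(), str(df.at[i, "age_band"]).strip())
        if key in seen:
            raise DataError(f"{path}: duplicate stratum {key[0]} {key[1]}")
        seen.add(key)
        g = lambda c: float(numeric[c].at[i])  # noqa: E731
        strata.append(StratumParams(
            sex=key[0], age_band=key[1],
            population=g("population"), mean_intake=g("mean_intake_g"),
            incidence=RateWithCI(g("incidence_per100k"),
                                 g("incidence_lo"), g("incidence_hi")),
            prevalence=RateWithCI(g("prevalence_per100k"),
                                  g("prevalence_lo"), g("prevalence_hi")),
            t2d_mortality=RateWithCI(g("t2d_mort_per100k"),
                                     g("t2d_mort_lo"), g("t2d_mort_hi")),
            all_cause_mortality=RateWithCI(g("allcause_mort_per100k"),
                                           g("allcause_mort_lo"),
                                           g("allcause_mort_hi")),
        ))
    return tuple(strata)


def read_costs_csv(path: str | Path) -> tuple[CostEntry, ...]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, COST_COLUMNS, path)
    values = _numeric(df, "annual_outpatient_nhe_usd", path)
    costs = []
    seen: set[tuple[str, str]] = set()
    for i in df.index:
        key = (str(df.at[i, "sex"]).strip(), str(df.at[i, "age_band"]).strip())
        if key in seen:
            raise DataError(f"{path}: duplicate cost row {key[0]} {key[1]}")
        seen.add(key)
        costs.append(CostEntry(key[0], key[1], float(values.at[i])))
    return tuple(costs)


def _read_config(path: str | Path) -> Mapping[str, float]:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, Mapping):
        raise SchemaError(f"{path}: config must be a mapping")
    missing = [k for k in CONFIG_KEYS if k not in data]
    if missing:
        raise SchemaError(f"{path}: missing key(s) {', '.join(missing)}")
    return data


def load_parameter_set(strata_path: str | Path, costs_path: str | Path,
                       config_path: str | Path) -> ParameterSet:
    """Read a full parameter set from disk and validate it.

    Raises SchemaError / ParseError / DataError for malformed inputs; a
    structurally well-formed set that violates a model invariant raises
    DataError carrying the full validation report.
    """
    cfg = _read_config(config_path)
    ps = ParameterSet(
        strata=read_strata_csv(strata_path),
        costs=read_costs_csv(costs_path),
        dose_response=DoseResponse(
            rr_per_increment=float(cfg["rr_per_increment"]),
            increment=float(cfg["increment_g"]),
            ci_low=float(cfg["rr_ci_low"]),
            ci_high=float(cfg["rr_ci_high"]),
        ),
        discount_rate=float(cfg["discount_rate"]),
        horizon=int(cfg["horizon_years"]),
    )
    report = validate_parameter_set(ps)
    if not report.is_valid:
        raise DataError(str(report))
    return ps


def write_parameter_set(ps: ParameterSet, strata_path: str | Path,
                        costs_path: str | Path,
                        config_path: str | Path) -> None:
    """Inverse of load_parameter_set (round-trips field-for-field)."""
    rows = []
    for s in ps.strata:
        rows.append({
            "sex": s.sex, "age_band": s.age_band,
            "population": s.population, "mean_intake_g": s.mean_intake,
            "incidence_per100k": s.incidence.value,
            "incidence_lo": s.incidence.ci_low,
            "incidence_hi": s.incidence.ci_high,
            "prevalence_per100k": s.prevalence.value,
            "prevalence_lo": s.prevalence.ci_low,
            "prevalence_hi": s.prevalence.ci_high,
            "t2d_mort_per100k": s.t2d_mortality.value,
            "t2d_mort_lo": s.t2d_mortality.ci_low,
            "t2d_mort_hi": s.t2d_mortality.ci_high,
            "allcause_mort_per100k": s.all_cause_mortality.value,
            "allcause_mort_lo": s.all_cause_mortality.ci_low,
            "allcause_mort_hi": s.all_cause_mortality.ci_high,
        })
    pd.DataFrame(rows, columns=list(STRATA_COLUMNS)).to_csv(
        strata_path, index=False)
    pd.DataFrame(
        [{"sex": c.sex, "age_band": c.age_band,
          "annual_outpatient_nhe_usd": c.annual_outpatient_nhe}
         for c in ps.costs],
        columns=list(COST_COLUMNS)).to_csv(costs_path, index=False,
                                           )
    cfg = {
        "discount_rate": ps.discount_rate,
        "horizon_years": ps.horizon,
        "rr_per_increment": ps.dose_response.rr_per_increment,
        "rr_ci_low": ps.dose_response.ci_low,
        "rr_ci_high": ps.dose_response.ci_high,
        "increment_g": ps.dose_response.increment,
    }
    text = Path(config_path)
    if str(config_path).endswith((".yaml", ".yml")):
        text.write_text(yaml.safe_dump(cfg))
    else:
        text.write_text(json.dumps(cfg, indent=2))
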