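"""Cost accrual and discounting.

Outpatient expenditure enters the model as one annual total per stratum (the
published national outpatient spend for that stratum's prevalent T2D
population in the baseline year).  Dividing by the baseline prevalent count
gives a per-patient-year unit cost, which is then accrued over Chronic-T2D
occupancy in every cycle and discounted at a fixed annual rate.

Cost timing within a cycle is a genuine modelling choice; the accrual
function exposes it:

* ``timing="end"`` (default): cycle t accrues cost on end-of-cycle Chronic
  occupancy (people diagnosed during the year incur outpatient costs that
  same year);
* ``timing="start"``: cycle t accrues cost on start-of-cycle occupancy.

Either way the discount exponent for cycle t is t, so the first year is
undiscounted.
"""

from __future__ import annotations

from .errors import ModelError
from .markov_cohort import CHRONIC, CohortTrace
from .params_io import CostEntry, StratumParams

_PER = 100_000.0


def per_patient_annual_cost(cost: CostEntry,
                            stratum: StratumParams) -> float:
    """Annual outpatient cost per prevalent T2D patient (USD/patient-year)."""
    patients = stratum.population * stratum.prevalence.value / _PER
    if patients <= 0:
        raise ModelError(
            f"{stratum.sex} {stratum.age_band}: zero prevalent population, "
            "per-patient cost undefined")
    return cost.annual_outpatient_nhe / patients


def discount_factor(rate: float, cycle_index: int) -> float:
    """(1 + rate) ** -cycle_index; cycle 0 is undiscounted."""
    if rate < 0:
        raise ModelError(f"discount rate {rate} must be >= 0")
    if cycle_index < 0:
        raise ModelError(f"cycle index {cycle_index} must be >= 0")
    return (1.0 + rate) ** (-cycle_index)


def cumulative_discounted_nhe(trace: CohortTrace,
                              cost_per_patient_year: float,
                              rate: float,
                              timing: str = "end") -> float:
    """Discounted outpatient expenditure accrued over Chronic-T2D occupancy."""
    if timing not in ("start", "end"):
        raise ModelError(f"timing must be 'start' or 'end', got {timing!r}")
    offset = 0 if timing == "start" else 1
    total = 0.0
    for t in range(trace.horizon):
        occupancy = trace.occupancy[t + offset, CHRONIC]
        total += occupancy * cost_per_patient_year * discount_factor(rate, t)
    return float(total)
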