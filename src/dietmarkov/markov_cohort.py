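"""Deterministic Markov cohort engine over four health states.

States, in fixed order: Healthy, Chronic T2D, Death from T2D, Death from
other causes.  A closed cohort (no entrants, no aging between strata) is
split between Healthy and Chronic T2D by baseline prevalence and advanced
through annual cycles by a row-stochastic 4x4 transition matrix:

* Healthy -> Chronic T2D: annual incidence probability (incidence rate per
  100,000 used directly as a probability) times the scenario's relative-risk
  multiplier;
* Healthy -> Death(other) and Chronic -> Death(other): all-cause minus T2D
  mortality, so T2D deaths are not double counted;
* Chronic -> Death(T2D): T2D mortality;
* both death states are absorbing; Chronic never reverts to Healthy.

The trace is an expected-value computation with fractional persons; all
transitions are evaluated simultaneously from start-of-cycle occupancy
(no intra-cycle ordering, no half-cycle correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ModelError
from .params_io import StratumParams

STATES = ("healthy", "chronic_t2d", "death_t2d", "death_other")
HEALTHY, CHRONIC, DEATH_T2D, DEATH_OTHER = range(4)

_PER = 100_000.0


@dataclass(frozen=True)
class CohortTrace:
    """Expected per-cycle state occupancy and transition flows for one stratum.

    occupancy has shape (horizon+1, 4); row 0 is the initial split.
    incident_flow[t] and t2d_death_flow[t] are the expected number of
    Healthy->Chronic and Chronic->Death(T2D) transitions during cycle t.
    """

    occupancy: np.ndarray
    incident_flow: np.ndarray
    t2d_death_flow: np.ndarray

    @property
    def horizon(self) -> int:
        return len(self.incident_flow)

    @property
    def population(self) -> float:
        return float(self.occupancy[0].sum())


def initial_occupancy(stratum: StratumParams) -> np.ndarray:
    """Split the stratum between Healthy and Chronic T2D by prevalence."""
    chronic = stratum.population * stratum.prevalence.value / _PER
    return np.array([stratum.population - chronic, chronic, 0.0, 0.0])


def build_transition_matrix(stratum: StratumParams,
                            rr_multiplier: float) -> np.ndarray:
    """Annual transition matrix for one stratum under an incidence multiplier.

    Raises ModelError if any probability leaves [0, 1] (e.g. T2D mortality
    above all-cause mortality, or a multiplier pushing incidence past the
    survival probability).
    """
    if rr_multiplier < 0:
        raise ModelError(f"rr_multiplier {rr_multiplier} must be >= 0")
    p_inc = stratum.incidence.value / _PER * rr_multiplier
    p_death_t2d = stratum.t2d_mortality.value / _PER
    p_death_other = (stratum.all_cause_mortality.value
                     - stratum.t2d_mortality.value) / _PER

    m = np.zeros((4, 4))
    m[HEALTHY, CHRONIC] = p_inc
    m[HEALTHY, DEATH_OTHER] = p_death_other
    m[HEALTHY, HEALTHY] = 1.0 - p_inc - p_death_other
    m[CHRONIC, DEATH_T2D] = p_death_t2d
    m[CHRONIC, DEATH_OTHER] = p_death_other
    m[CHRONIC, CHRONIC] = 1.0 - p_death_t2d - p_death_other
    m[DEATH_T2D, DEATH_T2D] = 1.0
    m[DEATH_OTHER, DEATH_OTHER] = 1.0

    for i, row_name in enumerate(STATES):
        if (m[i] < -1e-15).any() or (m[i] > 1 + 1e-15).any():
            raise ModelError(
                f"transition probabilities out of [0, 1] in row "
                f"{row_name!r} for {stratum.sex} {stratum.age_band}: {m[i]}")
    return m


def run_cohort(stratum: StratumParams, rr_multiplier: float,
               horizon: int) -> CohortTrace:
    """Trace the closed cohort: occupancy[t+1] = occupancy[t] @ M, with
    incident and T2D-death flows read off start-of-cycle occupancy."""
    if horizon < 0:
        raise ModelError(f"horizon {horizon} must be >= 0")
    m = build_transition_matrix(stratum, rr_multiplier)
    occupancy = np.empty((horizon + 1, 4))
    occupancy[0] = initial_occupancy(stratum)
    incident = np.empty(horizon)
    t2d_deaths = np.empty(horizon)
    for t in range(horizon):
        incident[t] = occupancy[t, HEALTHY] * m[HEALTHY, CHRONIC]
        t2d_deaths[t] = occupancy[t, CHRONIC] * m[CHRONIC, DEATH_T2D]
        occupancy[t + 1] = occupancy[t] @ m
    return CohortTrace(occupancy=occupancy, incident_flow=incident,
                       t2d_death_flow=t2d_deaths)


def cumulative_incidence(trace: CohortTrace) -> float:
    """Total expected new T2D cases over the horizon."""
    return float(trace.incident_flow.sum())


def cumulative_t2d_deaths(trace: CohortTrace) -> float:
    """Total expected deaths from T2D over the horizon."""
    return float(trace.t2d_death_flow.sum())


def trace_to_frame(trace: CohortTrace, sex: str, age_band: str,
                   scenario: str) -> pd.DataFrame:
    """Tidy per-cycle occupancy table (one row per cycle x state)."""
    horizon = trace.horizon
    records = []
    for t in range(horizon + 1):
        for i, state in enumerate(STATES):
            records.append({"sex": sex, "age_band": age_band,
                            "scenario": scenario, "cycle": t, "state": state,
                            "persons": trace.occupancy[t, i]})
    return pd.DataFrame.from_records(records)


def flows_to_frame(trace: CohortTrace, sex: str, age_band: str,
                   scenario: str) -> pd.DataFrame:
    """Tidy per-cycle flow table (incident cases and T2D deaths)."""
    records = []
    for t in range(trace.horizon):
        records.append({"sex": sex, "age_band": age_band, "scenario": scenario,
                        "cycle": t, "incident_cases": trace.incident_flow[t],
                        "t2d_deaths": trace.t2d_death_flow[t]})
    return pd.DataFrame.from_records(records)
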