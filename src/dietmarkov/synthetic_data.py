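"""Random-but-valid parameter sets and a Monte-Carlo microsimulation oracle.

The generator emulates the statistical shape of the national stratum tables
the pipeline consumes: per-stratum population counts, mean daily intake,
epidemiological rates per 100,000 with log-symmetric CI bounds, and annual
outpatient costs back-computed from a per-patient-year unit cost, so every
sampled set passes the full parameter validation by construction.  Default
ranges bracket the Japan-2019 fixture's values.

The microsimulation draws each individual's annual state path from the same
transition matrix the deterministic engine uses; its per-cycle state counts
(scaled to the stratum population, with binomial standard errors) are an
independent oracle for the expected-value cohort trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ModelError
from .markov_cohort import build_transition_matrix, initial_occupancy
from .params_io import (CostEntry, DoseResponse, ParameterSet, RateWithCI,
                        StratumParams)

Range = tuple[float, float]


@dataclass(frozen=True)
class SyntheticSpec:
    """Sampling ranges for one synthetic parameter set (seeded)."""

    n_strata: int = 16
    population_range: Range = (5e5, 1e7)           # persons
    intake_range: Range = (20.0, 60.0)             # g/day
    incidence_range: Range = (150.0, 700.0)        # per 100,000 / year
    prevalence_range: Range = (2_000.0, 20_000.0)  # per 100,000
    t2d_mort_range: Range = (0.3, 20.0)            # per 100,000 / year
    allcause_mort_range: Range = (80.0, 2_700.0)   # per 100,000 / year
    cost_per_patient_range: Range = (300.0, 1_200.0)  # USD / patient-year
    rr_range: Range = (0.85, 0.99)                 # per 50 g/day
    ci_halfwidth_fraction: float = 0.15            # log-scale half-width
    seed: int = 0

    def validate(self) -> None:
        for name in ("population_range", "intake_range", "incidence_range",
                     "prevalence_range", "t2d_mort_range",
                     "allcause_mort_range", "cost_per_patient_range",
                     "rr_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ModelError(f"{name} {(lo, hi)} must be positive and "
                                 "ordered")
        if self.t2d_mort_range[1] >= self.allcause_mort_range[0]:
            raise ModelError(
                "t2d_mort_range must lie strictly below allcause_mort_range "
                "so that T2D mortality never exceeds all-cause mortality")
        if self.n_strata < 1:
            raise ModelError("n_strata must be >= 1")
        if self.ci_halfwidth_fraction < 0:
            raise ModelError("ci_halfwidth_fraction must be >= 0")
        # transition rows must stay valid: incidence + net other-cause
        # mortality below 1 is guaranteed since all rates are < 100,000
        if self.incidence_range[1] + self.allcause_mort_range[1] >= 100_000:
            raise ModelError("incidence and mortality ranges admit an "
                             "invalid transition row")


def _rate_with_ci(rng: np.random.Generator, lo: float, hi: float,
                  halfwidth: float) -> RateWithCI:
    value = rng.uniform(lo, hi)
    return RateWithCI(value=value,
                      ci_low=value * float(np.exp(-halfwidth)),
                      ci_high=value * float(np.exp(halfwidth)))


def _stratum_key(index: int) -> tuple[str, str]:
    sex = ("men", "women")[index % 2]
    return sex, f"band_{index // 2:02d}"


def sample_parameter_set(spec: SyntheticSpec) -> ParameterSet:
    """Draw one valid ParameterSet; deterministic in ``spec.seed``.

    Each stratum consumes its own counter-based RNG stream keyed by
    (seed, stratum index), so enlarging ``n_strata`` never reshuffles
    the strata already drawn.
    """
    spec.validate()
    hw = spec.ci_halfwidth_fraction
    strata = []
    costs = []
    for i in range(spec.n_strata):
        rng = np.random.default_rng([spec.seed, i])
        sex, band = _stratum_key(i)
        population = float(np.floor(rng.uniform(*spec.population_range)))
        t2d_mort = _rate_with_ci(rng, *spec.t2d_mort_range, hw)
        all_cause = _rate_with_ci(rng, *spec.allcause_mort_range, hw)
        prevalence = _rate_with_ci(rng, *spec.prevalence_range, hw)
        strata.append(StratumParams(
            sex=sex, age_band=band, population=population,
            mean_intake=float(rng.uniform(*spec.intake_range)),
            incidence=_rate_with_ci(rng, *spec.incidence_range, hw),
            prevalence=prevalence,
            t2d_mortality=t2d_mort,
            all_cause_mortality=all_cause,
        ))
        unit_cost = rng.uniform(*spec.cost_per_patient_range)
        patients = population * prevalence.value / 100_000.0
        costs.append(CostEntry(sex, band, float(unit_cost * patients)))

    rng = np.random.default_rng([spec.seed, spec.n_strata])
    rr = float(rng.uniform(*spec.rr_range))
    dr = DoseResponse(rr_per_increment=rr, increment=50.0,
                      ci_low=rr * float(np.exp(-hw)),
                      ci_high=min(rr * float(np.exp(hw)), 0.9999))
    return ParameterSet(strata=tuple(strata), costs=tuple(costs),
                        dose_response=dr)


@dataclass(frozen=True)
class MicrosimResult:
    """Per-cycle state counts from an individual-level simulation, scaled to
    the stratum population, with binomial standard errors on the same scale."""

    occupancy: np.ndarray       # (horizon+1, 4) persons
    standard_error: np.ndarray  # (horizon+1, 4) persons
    n_individuals: int


def microsim_oracle(stratum: StratumParams, rr_multiplier: float,
                    horizon: int, n_individuals: int,
                    seed: int) -> MicrosimResult:
    """Simulate n individual state paths through the stratum's transition
    matrix and return occupancy estimates for the full population."""
    if n_individuals < 1:
        raise ModelError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    matrix = build_transition_matrix(stratum, rr_multiplier)
    population = stratum.population
    scale = population / n_individuals

    p_chronic = stratum.prevalence.value / 100_000.0
    counts = np.zeros((horizon + 1, 4), dtype=np.int64)
    chronic0 = rng.binomial(n_individuals, p_chronic)
    counts[0] = (n_individuals - chronic0, chronic0, 0, 0)
    for t in range(horizon):
        for state in range(4):
            n_state = counts[t, state]
            if n_state == 0:
                continue
            counts[t + 1] += rng.multinomial(n_state, matrix[state])

    # binomial SE of each state share around the deterministic expectation
    expected = initial_occupancy(stratum)
    se = np.empty_like(counts, dtype=float)
    occ = np.empty_like(counts, dtype=float)
    for t in range(horizon + 1):
        share = expected / population
        se[t] = np.sqrt(np.clip(share * (1 - share), 0.0, None)
                        / n_individuals) * population
        occ[t] = counts[t] * scale
        expected = expected @ matrix
    return MicrosimResult(occupancy=occ, standard_error=se,
                          n_individuals=n_individuals)
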