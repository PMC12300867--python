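"""Dose-response relative risk for intake scenarios.

A dose-response meta-analytic relative risk (RR per fixed g/day increment)
is extrapolated log-linearly: an intake increase of ``delta`` g/day
multiplies the T2D incidence probability by ``rr ** (delta / increment)``.
This power-law reading makes the multiplier multiplicative in the intake
change, the standard interpretation of "RR per 50 g/day" slopes.

A scenario raises every stratum's mean intake to a common target; strata
already at or above the target are left unchanged (the intervention never
forces intake down), so the intake delta is floored at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ModelError
from .params_io import DoseResponse, ParameterSet, StratumParams

RRTable = dict[tuple[str, str], float]


@dataclass(frozen=True)
class Scenario:
    """A named intake target; ``target_intake=None`` is the baseline
    (current intake maintained, no risk change)."""

    name: str
    target_intake: float | None = None  # g/day

    def __post_init__(self) -> None:
        if self.target_intake is not None and self.target_intake < 0:
            raise ModelError(f"target_intake {self.target_intake} must be >= 0")

    @property
    def is_baseline(self) -> bool:
        return self.target_intake is None


BASELINE = Scenario("baseline")
SCENARIO_1 = Scenario("scenario1", 160.0)  # two servings of yogurt per day
SCENARIO_2 = Scenario("scenario2", 80.0)   # one serving per day

PREDEFINED_SCENARIOS = {s.name: s for s in (BASELINE, SCENARIO_1, SCENARIO_2)}


def intake_delta(stratum: StratumParams, scenario: Scenario) -> float:
    """Daily intake increase (g/day) the scenario imposes on the stratum."""
    if scenario.is_baseline:
        return 0.0
    return max(0.0, scenario.target_intake - stratum.mean_intake)


def rr_for_intake_change(delta: float, dr: DoseResponse,
                         bound: str = "point") -> float:
    """Relative-risk multiplier on T2D incidence for a ``delta`` g/day
    intake increase.

    ``bound`` selects the point estimate or a CI bound of the per-increment
    RR ("point", "low", "high") before extrapolation.
    """
    if delta < 0:
        raise ModelError(f"negative intake delta {delta}: decreases in intake "
                         "are outside the modelled domain")
    rr = {"point": dr.rr_per_increment,
          "low": dr.ci_low,
          "high": dr.ci_high}[bound]
    return math.exp((delta / dr.increment) * math.log(rr))


def scenario_rr_table(ps: ParameterSet, scenario: Scenario,
                      bound: str = "point") -> RRTable:
    """Per-stratum incidence multipliers for a scenario (all 1.0 at baseline)."""
    return {
        s.key: rr_for_intake_change(intake_delta(s, scenario),
                                    ps.dose_response, bound=bound)
        for s in ps.strata
    }
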