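import pytest

from dietmarkov import builtin_japan_2019
from dietmarkov.params_io import RateWithCI, StratumParams


@pytest.fixture(scope="session")
def japan():
    return builtin_japan_2019()


def make_stratum(sex="men", age_band="40-49", population=1_000_000.0,
                 mean_intake=30.0, incidence=400.0, prevalence=5000.0,
                 t2d_mortality=2.0, all_cause_mortality=200.0):
    """A single-stratum building block with degenerate (point) CIs."""
    rate = lambda v: RateWithCI(v, v, v)  # noqa: E731
    return StratumParams(
        sex=sex, age_band=age_band, population=population,
        mean_intake=mean_intake, incidence=rate(incidence),
        prevalence=rate(prevalence), t2d_mortality=rate(t2d_mortality),
        all_cause_mortality=rate(all_cause_mortality))
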