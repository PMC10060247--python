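import numpy as np
import pandas as pd
import pytest

from riskstrat.cohort import StudySpec, build_study_population
from riskstrat.simulate import (
    OutcomeModel,
    SimulationScenario,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_scenario() -> SimulationScenario:
    """Confounded two-outcome study, protective effect on o1, null on o2."""
    return SimulationScenario(
        n=4000,
        bin_prevalences=(0.4, 0.25),
        n_continuous=2,
        treat_intercept=-0.2,
        treat_coefs=(("b1", 0.5), ("c1", 0.4)),
        outcomes=(
            OutcomeModel("o1", log_rate=-8.6, coefs=(("b1", 0.5), ("c1", 0.8)), gamma0=float(np.log(0.8))),
            OutcomeModel("o2", log_rate=-9.0, coefs=(("c2", 0.5),)),
        ),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_scenario):
    return simulate_cohort(small_scenario)


@pytest.fixture(scope="session")
def small_population(small_scenario, small_study):
    spec = StudySpec("target", "comparator", ("o1", "o2"))
    return build_study_population(small_study.cohorts, small_study.outcomes, spec)


@pytest.fixture()
def toy_cohorts() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": ["s1", "s2", "s3", "s4", "s5"],
            "arm": ["target", "target", "comparator", "comparator", "comparator"],
            "obs_end": [730, 365, 50, 730, 730],
            "prior_cvd": [1, 0, 0, 1, 0],
        }
    )
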