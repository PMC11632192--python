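import warnings

import numpy as np
import pytest

from mwtbio.simstudy import (
    CohortSpec,
    SimSessionConfig,
    StudyDesign,
    TrajectoryParams,
    simulate_session,
    simulate_study,
)

# statsmodels emits convergence chatter on boundary fits; the fits under
# test carry explicit convergence flags instead.
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture()
def noiseless_session():
    """A deterministic session reaching sleep onset mid-trial."""
    params = TrajectoryParams(intercept_a=-2.0, slope_b=0.1, noise_sd=0.0)
    cfg = SimSessionConfig(seed=7)
    record, truth = simulate_session(params, cfg)
    return record, truth, params, cfg


@pytest.fixture(scope="session")
def small_study():
    """Two-arm study small enough for repeated statistical fits."""
    design = StudyDesign(
        cohorts=(
            CohortSpec(
                "P", 6, {"baseline": 0.12, "day1": 0.12, "day7": 0.12},
                treatment="placebo",
            ),
            CohortSpec(
                "A", 6, {"baseline": 0.12, "day1": 0.05, "day7": 0.06},
                treatment="drug",
            ),
        )
    )
    return simulate_study(design, seed=42)


@pytest.fixture(scope="session")
def small_endpoints(small_study):
    from mwtbio.session_metrics import compile_endpoints

    return compile_endpoints(small_study)
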