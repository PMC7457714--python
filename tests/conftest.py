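import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cautionmeta import (
    DatasetSpec,
    DDMParams,
    simulate_ddm,
    StudyDesign,
    SynthConfig,
    TaskSpec,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_design() -> StudyDesign:
    """Two tiny datasets: a conflict task and a two-session diffusion task."""
    return StudyDesign((
        DatasetSpec("dsA", 8, (
            TaskSpec("conflict", "dmc", ("congruent", "incongruent"), 40, "single"),
        )),
        DatasetSpec("dsB", 6, (
            TaskSpec("dots", "ddm", ("motion_left", "motion_right"), 40, "single"),
        ), n_sessions=2),
    ))


@pytest.fixture(scope="session")
def small_config(small_design) -> SynthConfig:
    return SynthConfig(design=small_design, seed=11)


@pytest.fixture(scope="session")
def ddm_trials_480() -> pd.DataFrame:
    """One participant's worth of standard-diffusion trials."""
    params = DDMParams(boundary_a=0.12, drift_v=0.35, nondecision_ter=0.3)
    return simulate_ddm(params, 480, seed=421)
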