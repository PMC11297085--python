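import numpy as np
import pandas as pd
import pytest

from vmswc.bayes_opt import BayesOptConfig
from vmswc.data_model import SurveyCouplet, CohortTable
from vmswc.synthetic_data import GeneratorConfig, generate


@pytest.fixture
def small_opt() -> BayesOptConfig:
    """Reduced optimization budget for unit tests."""
    return BayesOptConfig(n_init_points=10, n_iterations=10, n_repeats=1, seed=123)


@pytest.fixture
def tiny_opt() -> BayesOptConfig:
    return BayesOptConfig(n_init_points=6, n_iterations=6, n_repeats=1, seed=7)


@pytest.fixture
def default_cohort() -> CohortTable:
    return generate(GeneratorConfig(n_couplets=200, seed=11))


def make_couplet(
    cid="c1",
    baseline=(4.0, 5.0, 6.0),
    followup=(2.0, 3.0, 4.0),
    likert="agree",
    intervention="cam",
    **kwargs,
) -> SurveyCouplet:
    return SurveyCouplet(
        couplet_id=cid,
        patient_id=f"p-{cid}",
        baseline_domains=baseline,
        followup_domains=followup,
        likert_raw=likert,
        intervention=intervention,
        **kwargs,
    )
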