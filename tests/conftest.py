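import numpy as np
import pytest

from traceret.cascade import MLPSpec, train_cascade
from traceret.core import MembershipCenters, TraceElement
from traceret.fuzzy import build_rule_base
from traceret.pipeline import CALIBRATION_TEMPLATE, run_calibration
from traceret.synth import GeneratorConfig, generate_cohort, worked_example_fixtures


@pytest.fixture(scope="session")
def centers():
    return MembershipCenters.default()


@pytest.fixture(scope="session")
def rulebase():
    return build_rule_base()


@pytest.fixture(scope="session")
def calibrated_config():
    cfg, _ = run_calibration(CALIBRATION_TEMPLATE)
    return cfg


@pytest.fixture(scope="session")
def fixtures():
    return worked_example_fixtures()


@pytest.fixture(scope="session")
def zn_cohort():
    """Seeded 2000-subject zinc cohort with 5% relative noise."""
    return generate_cohort(GeneratorConfig(n_subjects=2000, seed=7, elements=(TraceElement.Zn,)))


@pytest.fixture(scope="session")
def zn_cascade(zn_cohort):
    return train_cascade(zn_cohort.records, TraceElement.Zn, MLPSpec(seed=7))


@pytest.fixture(scope="session")
def noiseless_cohort():
    return generate_cohort(
        GeneratorConfig(
            n_subjects=1200,
            seed=11,
            elements=(TraceElement.Zn,),
            noise_serum=0.0,
            noise_urine=0.0,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
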