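import numpy as np
import pytest
from hypothesis import settings

from silicofem.phantom import (
    CohortConfig,
    TemplateConfig,
    generate_paired_cohort,
    make_template,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


COARSE = TemplateConfig(nx=3, ny=3, nz=12)


@pytest.fixture(scope="session")
def coarse_config() -> TemplateConfig:
    return COARSE


@pytest.fixture(scope="session")
def template():
    """Default-resolution phantom template (~2000 elements)."""
    return make_template()


@pytest.fixture(scope="session")
def coarse_template():
    return make_template(COARSE)


@pytest.fixture(scope="session")
def small_cohort():
    """Eight-subject paired cohort on the coarse template."""
    cfg = CohortConfig(template=COARSE)
    subjects, table, tpl = generate_paired_cohort(4, cfg, seed=11)
    return subjects, table, tpl


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
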