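"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import pytest

from helpers import make_cohort
from panelmmc.mmc import MetropolisConfig
from panelmmc.simulate import (
    GeneratorConfig,
    generate_cohort,
    null_marker_specs,
    planted_pair_specs,
)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size prediagnostic cohort with the default marker preset."""
    cohort, truth = generate_cohort(GeneratorConfig(seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def planted_cohort():
    """135/540 cohort with 2 informative markers of 10, no duplicates."""
    cfg = GeneratorConfig(
        marker_specs=planted_pair_specs(10),
        seed=7,
        n_duplicates_case=0,
        n_duplicates_control=0,
    )
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no case/control differences at all."""
    cfg = GeneratorConfig(
        marker_specs=null_marker_specs(10),
        seed=9,
        n_duplicates_case=0,
        n_duplicates_control=0,
    )
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


@pytest.fixture()
def fast_cfg():
    """Reduced Metropolis settings for unit tests."""
    return MetropolisConfig(
        n_iterations=120, n_splits_objective=8, n_cv=40, seed=5
    )


@pytest.fixture()
def tiny_cohort_factory():
    return make_cohort
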