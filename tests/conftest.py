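"""Shared fixtures: synthetic surveys and trained signature sets.

The expensive end-to-end build (five sources, reduced forest sizes) is
session-scoped so classification, evaluation and acceptance tests reuse
one trained signature set.
"""

import numpy as np
import pytest

from fecalsig import RunConfig, run_build
from fecalsig.synth import default_design, generate_cohorts


@pytest.fixture(scope="session")
def small_design():
    """Desk-scale survey: 5 sources x 25 samples, ~10^4 reads each, V6."""
    return default_design(seed=3)


@pytest.fixture(scope="session")
def survey(small_design):
    """(reads_per_sample, truth labels, ASV pool) for the default design."""
    return generate_cohorts(small_design)


@pytest.fixture(scope="session")
def reduced_config():
    """Reduced forest sizes for desk-scale runs (10 x 100 throughout)."""
    return RunConfig(
        region="V6",
        seed=7,
        ranking_replicates=10,
        ranking_trees=100,
        ensemble_replicates=10,
        ensemble_trees=100,
    )


@pytest.fixture(scope="session")
def build(survey, reduced_config):
    """Full pipeline build over the default synthetic survey."""
    reads, truth, _ = survey
    return run_build(reduced_config, reads, truth)


@pytest.fixture(scope="session")
def signatures(build):
    return {sig.source: sig for sig in build.signatures}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
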