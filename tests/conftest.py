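"""Shared fixtures: one default synthetic cohort, simulated and analysed once.

The 100-subject cohort at seed 0 is the package's reference study condition;
simulating and extracting it is the expensive step, so the pipeline result is
session-scoped and reused by the end-to-end, invariant and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import ataxkit as ak


@pytest.fixture(scope="session")
def cohort100():
    cfg = ak.GeneratorConfig(n_subjects=100, seed=0)
    subjects, recordings = ak.simulate_subjects(cfg)
    return cfg, subjects, recordings


@pytest.fixture(scope="session")
def pipeline100(cohort100):
    _, subjects, recordings = cohort100
    return subjects, ak.run_pipeline(subjects, recordings, model="QDA", seed=0)


@pytest.fixture(scope="session")
def features100(pipeline100):
    subjects, result = pipeline100
    return subjects, result.features


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
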