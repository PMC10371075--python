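"""Shared fixtures: small synthetic sessions and cohorts."""

import numpy as np
import pytest

from babykin import synthetic as syn

#: reduced per-stage frame counts for fast unit tests (same 100 Hz rate)
SMALL_STAGES = {"B1": 3000, "B2": 3000, "CR1": 2000, "CR2": 2000, "DC": 3000}


@pytest.fixture(scope="session")
def small_session():
    cfg = syn.SyntheticConfig(n_frames=dict(SMALL_STAGES), seed=7)
    return syn.generate_session(cfg)


@pytest.fixture(scope="session")
def default_session():
    """Full-length default session (48 000 frames)."""
    return syn.generate_session(syn.SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    spec = syn.CohortSpec(
        n_subjects=3,
        base_config=syn.SyntheticConfig(n_frames=dict(SMALL_STAGES)),
        seed=11,
    )
    return syn.generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
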