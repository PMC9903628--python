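"""Shared fixtures.

The full-scale simulation (`study_result`) is expensive (~3–5 min) and is
session-scoped; only the acceptance tests use it.  Unit tests build their
own small fixtures.
"""

from __future__ import annotations

import numpy as np
import pytest

from gbsquant.pipeline import SimulationConfig, run_pipeline


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_result():
    """A fast, reduced-scale end-to-end run shared by integration tests."""
    config = SimulationConfig(
        genome_length=20_000,
        reads_monoclonal=2000,
        reads_calibration=1200,
        reads_mock=1000,
        min_reads=200,
    )
    return run_pipeline(config, seed=7)


@pytest.fixture(scope="session")
def study_result():
    """Full-scale study emulation used by the acceptance criteria."""
    config = SimulationConfig()  # paper-shaped defaults: 100 kb, ~2e5 reads
    return run_pipeline(config, seed=20230206)
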