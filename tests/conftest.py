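"""Shared fixtures: small synthetic cohorts and transcript models."""

from __future__ import annotations

import pytest

from gpitrio.filters import run_filter_pipeline
from gpitrio.model import PipelineConfig
from gpitrio.simulate import build_cohort, pigl_like_transcript


@pytest.fixture(scope="session")
def pigl_tx():
    return pigl_like_transcript()


@pytest.fixture(scope="session")
def planted_cohort():
    """50 background trios + the shipped family specs + all decoys, seed 1."""
    return build_cohort(n_background_trios=50, seed=1, n_sites=5000)


@pytest.fixture(scope="session")
def planted_cohort_result(planted_cohort):
    return run_filter_pipeline(planted_cohort, PipelineConfig())
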