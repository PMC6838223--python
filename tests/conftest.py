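"""Shared fixtures.

Session-scoped phantom cases are cached so independent tests don't repeat the
(expensive) generation, and the 22-case cohort pipeline run is computed once
and shared by the classification-related acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from evarstrain import PhantomSpec, generate_case


@pytest.fixture(scope="session")
def unfavorable_case():
    """One default unfavorable phantom pair with ground truth."""
    return generate_case(PhantomSpec(seed=11, label="unfavorable"))


@pytest.fixture(scope="session")
def favorable_case():
    return generate_case(PhantomSpec(seed=12, label="favorable"))


@pytest.fixture(scope="session")
def clean_case():
    """Noise-free unfavorable phantom with identity rigid (fixed amplitude)."""
    spec = PhantomSpec(seed=13, label="unfavorable", noise_sd=0.0,
                       rotation_max_deg=0.0, translation_max_mm=0.0,
                       bulge_amplitude=4.0)
    return generate_case(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def cohort_result():
    """The 22-case / 9-unfavorable full-pipeline cohort (seed 42).

    Shared by the end-to-end classification and null-sanity acceptance tests;
    this is the expensive fixture of the suite.
    """
    from evarstrain.phantom import generate_cohort
    from evarstrain.pipeline import PipelineConfig, run_cohort

    specs = generate_cohort(22, 9, seed=42)
    config = PipelineConfig(seed=42)
    return run_cohort(specs, config, modes=("tensile", "compressive", "both"))
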