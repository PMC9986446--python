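import dataclasses

import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dehtp_pbpk import build_model, GlobalParams, LocalParams, Physiology
from dehtp_pbpk.synth import (
    REFERENCE_GLOBALS,
    REFERENCE_LOCALS,
    StudyDesign,
    generate_study,
    reference_truth,
)


@pytest.fixture(scope="session")
def default_ctx():
    return build_model(Physiology(), GlobalParams(), LocalParams())


@pytest.fixture(scope="session")
def volunteer_b_ctx():
    """Calibrated reference set for the lymph-dominant volunteer."""
    return build_model(
        Physiology(body_weight=85.0), REFERENCE_GLOBALS, REFERENCE_LOCALS[1]
    )


@pytest.fixture(scope="session")
def zero_noise_study():
    design = dataclasses.replace(
        StudyDesign(), noise_sd={"5OH": 0.0, "2cx": 0.0, "5cx": 0.0}
    )
    data, truth, voids = generate_study(design, seed=1)
    return design, data, truth, voids


@pytest.fixture(scope="session")
def noisy_study():
    design = StudyDesign()
    data, truth, voids = generate_study(design, seed=42)
    return design, data, truth, voids
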