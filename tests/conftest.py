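import pytest

from whitecast.synthetic_data import (
    DEFAULT_MODEL,
    generate_in_vitro,
    generate_in_vivo,
)

#: Seed of the default synthetic study used across the suite.
STUDY_SEED = 0

#: Generating truth for parameter-recovery checks.
TRUE_SLOPES = dict(DEFAULT_MODEL.category_slope)


@pytest.fixture(scope="session")
def vivo_study():
    """Default-seed in vivo study: (measurements, subject profiles)."""
    return generate_in_vivo(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def vitro_study():
    """Default-seed in vitro study over both acrylic backgrounds."""
    return generate_in_vitro(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def vivo_with_category(vivo_study):
    """Measurements joined with each subject's realized category."""
    measurements, profiles = vivo_study
    return measurements.merge(
        profiles[["subject_id", "category", "subtype"]],
        left_on="substrate_id",
        right_on="subject_id",
    )
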