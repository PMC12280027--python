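import pytest

from isletmorph import SectionParams, analyze_section, generate_section


@pytest.fixture(scope="session")
def clean_section():
    """Default noise-free section with ground truth (seed 1)."""
    return generate_section(SectionParams(seed=1, noise_sd=0))


@pytest.fixture(scope="session")
def noisy_section():
    """Default section at the default noise level (seed 1)."""
    return generate_section(SectionParams(seed=1))


@pytest.fixture(scope="session")
def analyzed_clean(clean_section):
    """(metrics, compartments) of the clean section, nuclei included."""
    section, _ = clean_section
    return analyze_section(section)
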