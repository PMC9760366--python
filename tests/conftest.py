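import pytest

import exomod


@pytest.fixture(scope="session")
def reference_screen():
    return exomod.generate_reference_screen()


@pytest.fixture(scope="session")
def reference_analysis():
    return exomod.analyze_reference_screen(seed=1)


@pytest.fixture(scope="session")
def default_field():
    """One default synthetic field plus its ground truth."""
    return exomod.generate_field_image(exomod.ImageSimConfig(seed=7))
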