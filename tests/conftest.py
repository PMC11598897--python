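import pytest

from ctermotif import FamilyConfig, generate_family, parse_prosite

DDX3EQ = "[DEP]-D-{P}-{P}-{P}-E-Q>"


@pytest.fixture(scope="session")
def ddx3eq_pattern():
    return parse_prosite(DDX3EQ)


@pytest.fixture(scope="session")
def clean_family():
    """Noise-free 50-member synthetic ortholog family (fixed seed)."""
    return generate_family(FamilyConfig(seed=0))
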