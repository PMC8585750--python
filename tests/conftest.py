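import pytest

from nbs_profiler.motifs import load_default_library
from nbs_profiler.synthetic_data import SimConfig, generate_genome


@pytest.fixture(scope="session")
def default_genome():
    """One default synthetic genome (73 NBS genes, paper-like composition)."""
    return generate_genome(SimConfig(seed=1))


@pytest.fixture(scope="session")
def library():
    return load_default_library()
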