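import pytest

from rhinopfc.io import load_study_census
from rhinopfc.pipeline import analyze_census
from rhinopfc.simulate import SimulationConfig


@pytest.fixture(scope="session")
def study_census():
    return load_study_census()


@pytest.fixture(scope="session")
def study_analysis(study_census):
    """Full rain-free pipeline on the packaged study census."""
    return analyze_census(study_census)


@pytest.fixture(scope="session")
def base_config():
    return SimulationConfig(seed=123)
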