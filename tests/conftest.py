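import dataclasses

import pytest

from leafdiffuse import AnalysisConfig, KineticConstants
from leafdiffuse.synthetic_data import make_preset


@pytest.fixture(scope="session")
def kin() -> KineticConstants:
    """Default Rubisco kinetics at 25 degC."""
    return KineticConstants()


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def colwt_leaf():
    """High-gm wild-type ground truth (many small chloroplasts)."""
    return make_preset("colwt")


@pytest.fixture(scope="session")
def arc12_leaf():
    """Few-large-chloroplast mutant ground truth."""
    return make_preset("arc12")


@pytest.fixture(scope="session")
def lowgm_leaf(colwt_leaf):
    """Wild-type biochemistry with a low (well-identified) mesophyll conductance."""
    return dataclasses.replace(colwt_leaf, gm=0.03, label="lowgm")
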