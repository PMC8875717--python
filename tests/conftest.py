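import numpy as np
import pytest

import terpsol as ts
from terpsol.pipeline import run_analysis


@pytest.fixture(scope="session")
def fixtures():
    return ts.builtin_fixtures()


@pytest.fixture(scope="session")
def alpha_pinene(fixtures):
    return fixtures["(-)-alpha-pinene"]


@pytest.fixture(scope="session")
def p_cymene(fixtures):
    return fixtures["p-cymene"]


@pytest.fixture(scope="session")
def solute():
    return ts.DEHYDROABIETIC_ACID


@pytest.fixture(scope="session")
def full_report():
    """One complete analysis of the built-in study data, shared by the
    model-selection and acceptance tests (the NRTL/UNIQUAC multistart fits
    dominate its ~1 min runtime)."""
    return run_analysis()


# Mole-fraction solubility of dehydroabietic acid in (−)-α-pinene as printed:
# temperature (K), measured x, and the tabulated Apelblat-calculated x.
ALPHA_PINENE_APELBLAT_XCAL = np.array(
    [0.09402, 0.10209, 0.11017, 0.11926, 0.12445, 0.13560,
     0.14690, 0.15617, 0.16538, 0.17270, 0.18111, 0.19721]
)


@pytest.fixture(scope="session")
def apelblat_xcal_column():
    return ALPHA_PINENE_APELBLAT_XCAL
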