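import numpy as np
import pytest

from bpcredence import preset


@pytest.fixture(scope="session")
def sbp_params():
    return preset("iso81060_2_sbp")[0]


@pytest.fixture(scope="session")
def dbp_params():
    return preset("iso81060_2_dbp")[0]


@pytest.fixture(scope="session")
def sbp_tails():
    return preset("iso81060_2_sbp")[1]


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


# Published evaluation results for the ten demo studies, as percentages
# (credence SBP, credence DBP, P(tolerable) SBP, P(tolerable) DBP).
# Values below 0.1% are recorded as 0.1 and checked one-sidedly.
PUBLISHED_RESULTS = {
    "CR17": (6.50, 99.20, 78.40, 93.00),
    "CR14": (96.80, 94.10, 91.30, 90.30),
    "CR18": (25.20, 87.60, 83.70, 93.40),
    "CR19": (0.1, 0.1, 61.00, 60.50),
    "CR20": (33.40, 18.50, 82.50, 80.80),
    "CR21": (0.1, 99.90, 67.60, 86.40),
    "CR22": (0.10, 0.20, 64.10, 66.10),
    "CR15": (35.00, 75.20, 85.40, 91.20),
    "CR23": (46.00, 90.20, 90.20, 98.00),
    "CR24": (95.50, 99.90, 90.50, 96.50),
}

# Studies whose credence was published as "<0.1%" (one-sided check).
BELOW_DISPLAY_FLOOR = {"CR19": ("sbp", "dbp"), "CR21": ("sbp",)}
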