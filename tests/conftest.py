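import numpy as np
import pytest

import meatshift as ms

# Published parameter table, transcribed independently of the packaged
# YAML file (subgroup → column values).
PUBLISHED_TABLE = {
    "white_male": {
        "probs": (0.03, 0.24, 0.38, 0.35),
        "meat": (0.178, 0.158, 0.198),
        "util": (0.90, 0.87, 0.85),
        "rr": (1.37, 1.31, 1.12, 1.00, 1.01, 1.11, 1.30, 1.63, 1.92),
        "inc": 5.7,
    },
    "black_male": {
        "probs": (0.04, 0.28, 0.30, 0.39),
        "meat": (0.229, 0.204, 0.253),
        "util": (0.88, 0.89, 0.83),
        "rr": (1.58, 1.58, 1.14, 1.00, 1.02, 1.03, 1.18, 1.31, 1.31),
        "inc": 12.3,
    },
    "white_female": {
        "probs": (0.04, 0.35, 0.27, 0.34),
        "meat": (0.153, 0.133, 0.173),
        "util": (0.88, 0.87, 0.83),
        "rr": (1.42, 1.10, 1.00, 1.00, 1.07, 1.16, 1.30, 1.60, 2.06),
        "inc": 4.7,
    },
    "black_female": {
        "probs": (0.03, 0.17, 0.26, 0.53),
        "meat": (0.215, 0.192, 0.238),
        "util": (0.85, 0.85, 0.74),
        "rr": (1.52, 1.21, 1.07, 1.00, 1.09, 1.19, 1.27, 1.49, 1.69),
        "inc": 8.7,
    },
}


@pytest.fixture(scope="session")
def published_table():
    return PUBLISHED_TABLE


@pytest.fixture(scope="session")
def params():
    return ms.default_params()


@pytest.fixture(scope="session")
def demographics():
    return ms.default_demographics()


@pytest.fixture(scope="session")
def life_table():
    return ms.default_life_table()


@pytest.fixture(scope="session")
def cohort_small(params, demographics):
    """Shared 5,000-person cohort for engine-level tests."""
    return ms.sample_population(5_000, demographics, params, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20130)
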