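import numpy as np
import pytest

from qbdspace import load_study

# Term sets of the six published models (stepwise at alpha = 0.35) and the
# printed coefficients/criteria they are checked against.
STUDY_TERM_SETS = {
    "danshensu": ("X1", "X2", "X3", "X1X3", "X2X3", "X3^2"),
    "hydroxysafflor_yellow_A": ("X2", "X3", "X1X2", "X1^2", "X2^2", "X3^2"),
    "rosmarinic_acid": ("X2", "X3", "X1^2", "X2^2", "X3^2"),
    "lithospermic_acid": ("X1", "X2", "X3", "X2X3", "X1^2", "X2^2", "X3^2"),
    "salvianolic_acid_B": ("X1", "X2", "X3", "X1X3", "X2X3", "X2^2", "X3^2"),
    "dry_matter": ("X1", "X2", "X3", "X1X2", "X1X3", "X2X3", "X2^2", "X3^2"),
}

STUDY_COEFS = {
    "danshensu": {
        "Constant": 2.166, "X1": 1.012, "X2": 0.153, "X3": 0.795,
        "X1X3": 0.373, "X2X3": -0.065, "X3^2": -0.274,
    },
    "hydroxysafflor_yellow_A": {
        "Constant": 6.569, "X2": 0.855, "X3": 1.273, "X1X2": -0.365,
        "X1^2": -1.797, "X2^2": -0.676, "X3^2": -0.409,
    },
    "rosmarinic_acid": {
        "Constant": 2.024, "X2": 0.193, "X3": 0.332, "X1^2": 0.059,
        "X2^2": -0.145, "X3^2": -0.304,
    },
    "lithospermic_acid": {
        "Constant": 2.329, "X1": 0.214, "X2": 0.227, "X3": 0.555,
        "X2X3": -0.067, "X1^2": -0.115, "X2^2": -0.143, "X3^2": -0.253,
    },
    "salvianolic_acid_B": {
        "Constant": 38.030, "X1": -2.330, "X2": 2.989, "X3": 8.181,
        "X1X3": -0.968, "X2X3": -1.709, "X2^2": -2.399, "X3^2": -3.402,
    },
    "dry_matter": {
        "Constant": 474.39, "X1": 26.88, "X2": 32.98, "X3": 109.65,
        "X1X2": -13.31, "X1X3": 17.50, "X2X3": -19.38, "X2^2": -22.12,
        "X3^2": -40.24,
    },
}

STUDY_R2 = {
    "danshensu": (0.993, 0.987),
    "hydroxysafflor_yellow_A": (0.957, 0.924),
    "rosmarinic_acid": (0.946, 0.915),
    "lithospermic_acid": (0.992, 0.985),
    "salvianolic_acid_B": (0.992, 0.983),
    "dry_matter": (0.983, 0.961),
}

#: The verified operating point in uncoded units: 1.6 h, 8.3 g/g, 2 extractions.
VERIFICATION_POINT = (1.6, 8.3, 2.0)


@pytest.fixture(scope="session")
def study():
    return load_study()


@pytest.fixture(scope="session")
def design(study):
    return study[0]


@pytest.fixture(scope="session")
def limits(study):
    return study[1]


@pytest.fixture(scope="session")
def factors(study):
    return study[2]


@pytest.fixture(scope="session")
def coded_verification_point(factors):
    from qbdspace import code_factors

    return code_factors(np.array(VERIFICATION_POINT), factors)
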