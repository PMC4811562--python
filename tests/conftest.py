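import numpy as np
import pytest

import choicemix as cm


@pytest.fixture(scope="session")
def attrs():
    return cm.default_attributes()


@pytest.fixture(scope="session")
def candidates(attrs):
    return cm.build_candidate_set(attrs)


@pytest.fixture(scope="session")
def design():
    """The standard 16-situation, two-block design (cached by the package)."""
    return cm.default_design()


@pytest.fixture(scope="session")
def table1_pair(attrs):
    """The printed example choice card: 100 cattle + full lease vs 40 cattle
    + half lease + 5 acres cultivated; equal wage, small stock and access."""
    opt1 = {"access": "prohibited", "cattle": 100, "cons": "full",
            "cult": "none", "smlstk": 0, "wage": 6000}
    opt2 = {"access": "prohibited", "cattle": 40, "cons": "half",
            "cult": "5acres", "smlstk": 0, "wage": 6000}
    return cm.ChoicePair(opt1, opt2)


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study shared across tests (30 individuals)."""
    truth = cm.default_truth(seed=42, n_respondents=30)
    respondents, choices, panel = cm.simulate_study(truth)
    return truth, respondents, choices, panel


#: fitted Model 1 population means (intercept, access, cattle per 100,
#: cons150, cons75, cult, smlstk per 200, wage per 10,000)
TABLE3_MEANS = np.array([-0.20, 1.11, 1.86, 0.16, 1.59, 0.83, 1.99, 0.48])
TABLE3_SDS = np.array([0.18, 0.29, 1.79, 0.96, 1.28, 0.64, 2.12, 0.29])


@pytest.fixture(scope="session")
def table3_params():
    return cm.Parameters(m=TABLE3_MEANS.copy(), s=TABLE3_SDS.copy())
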