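import numpy as np
import pytest

from memnet import preprocess, synthetic


@pytest.fixture(scope="session")
def tiny_cohort():
    return synthetic.make_fixture("tiny", seed=1)


@pytest.fixture(scope="session")
def paper_cohort():
    return synthetic.make_fixture("paper_like", seed=1)


@pytest.fixture(scope="session")
def paper_matrix(paper_cohort):
    matrix, _ = preprocess.build_analysis_matrix(paper_cohort)
    return matrix


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
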