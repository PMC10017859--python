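import numpy as np
import pytest
from hypothesis import settings

from semharm import QuestionRecord, sample_vmf_mixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def education_records():
    """The three section-title/wording variants of the highest-grade question."""
    return [
        QuestionRecord("a", "F1", "economic/Education/", "What Is The Highest Grade You Have Completed"),
        QuestionRecord("b", "F2", "Educational Data/", "What Is The Highest Grade You Have Completed"),
        QuestionRecord("c", "F3", "social/Education History/", "Highest grade attained"),
    ]


@pytest.fixture(scope="session")
def planted6():
    """Well-separated 6-component spherical mixture (n=600, d=10, kappa=40)."""
    return sample_vmf_mixture(n=600, d=10, k=6, kappa=40.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
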