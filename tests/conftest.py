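import pytest

from cpdscreen.simulate import generate_cohort, paper_like_config


@pytest.fixture(scope="session")
def paper_like_cohort():
    """Reference-conditions synthetic cohort (1348 samples), fixed seed."""
    return generate_cohort(paper_like_config(seed=1))


@pytest.fixture(scope="session")
def paper_like_frame(paper_like_cohort):
    return paper_like_cohort.to_frame().set_index("sample_id")
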