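import numpy as np
import pytest

from ampedit.app_synthetic import (
    APP659_CUT_NT,
    app_cterm_cds,
    example_assay,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def human_context():
    return app_cterm_cds("human").seq


@pytest.fixture
def mouse_context():
    return app_cterm_cds("mouse").seq


@pytest.fixture
def assay():
    """Assay over the synthetic APP context with a low filter threshold."""
    return example_assay("human", min_count=1)


@pytest.fixture
def cut_site():
    return APP659_CUT_NT


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
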