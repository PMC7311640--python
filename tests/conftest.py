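import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from hydbeta import SubstitutionScheme, make_reference_scaffold


@pytest.fixture(scope="session")
def scaffold():
    return make_reference_scaffold(length=600, seed=11)


@pytest.fixture(scope="session")
def blosum():
    return SubstitutionScheme.blosum62()


@pytest.fixture(scope="session")
def linear_scheme():
    # match +1, mismatch -1, linear gap -2
    return SubstitutionScheme.simple(match=1, mismatch=-1, gap_open=-2, gap_extend=-2)
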