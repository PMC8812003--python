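import numpy as np
import pytest

from cnnfold.core import RnaSequence, SecondaryStructure

# The 31-nt hairpin-in-hairpin example used throughout the docs: a nested
# two-stem structure with no pseudoknot.
WORKED_SEQUENCE = "CGUGUCAGGUCCGGAAGGAAGCAGCACUAAC"
WORKED_PAIRS = frozenset(
    {(2, 27), (3, 26), (4, 25), (5, 24), (10, 19), (11, 18), (12, 17)}
)
WORKED_DOTBRACKET = ".((((....(((....)))....))))...."


@pytest.fixture
def worked_sequence() -> RnaSequence:
    return RnaSequence("worked_example", WORKED_SEQUENCE)


@pytest.fixture
def worked_structure() -> SecondaryStructure:
    return SecondaryStructure(len(WORKED_SEQUENCE), WORKED_PAIRS)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
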