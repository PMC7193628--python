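import numpy as np
import pytest

from hdrscreen import GuideEntry, GuideLibrary, SequenceRead
from hdrscreen.io_formats import CONTROL_GENE
from hdrscreen.synthetic_data import example_amplicon_spec


def make_read(bases: str, read_id: str = "r", qual: int = 37) -> SequenceRead:
    return SequenceRead(read_id, bases, (qual,) * len(bases))


@pytest.fixture
def amplicon_spec():
    """Canonical 72-nt synthetic amplicon with two donor SNP flags."""
    return example_amplicon_spec()


@pytest.fixture
def small_library():
    """Two targeting guides and two controls with distinct 20-mers."""
    return GuideLibrary(
        [
            GuideEntry("g1", "GENE1", "ACGTACGTACGTACGTACGT", False),
            GuideEntry("g2", "GENE2", "TTTTCCCCGGGGAAAATTTT", False),
            GuideEntry("c1", CONTROL_GENE, "GATCGATCGATCGATCGATC", True),
            GuideEntry("c2", CONTROL_GENE, "CCGGAATTCCGGAATTCCGG", True),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)
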