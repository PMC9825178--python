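import random

import pytest

from sirnasort.catalog import P4RNA
from sirnasort.seqio import SmallRNARead


@pytest.fixture
def toy_catalog():
    """Four species at distinct anchors with known prefixes."""

    def mk(i, seq, count):
        return P4RNA(
            id=f"c{i}:0:+", sequence=seq, cluster=f"c{i}", position=0, strand="+",
            read_count=count,
        )

    return [
        mk(1, "A" * 16 + "C" * 16, 100),
        mk(2, "ACGT" * 8, 200),
        mk(3, "G" * 20 + "T" * 12, 80),
        mk(4, "T" * 35, 60),
    ]


@pytest.fixture
def rng():
    return random.Random(42)


def random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))
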