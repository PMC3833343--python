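import sys
from pathlib import Path

import pytest

# make the sibling oracle helpers importable regardless of invocation dir
sys.path.insert(0, str(Path(__file__).parent))

from olfdiverge.divergence import CodonAlignedPair, DayhoffPartition


def make_pair(codons_a, codons_b) -> CodonAlignedPair:
    """Pair two gap-free codon lists with identity positions."""
    n = len(codons_a)
    return CodonAlignedPair(
        gene_id_a="a",
        gene_id_b="b",
        codons_a=tuple(codons_a),
        codons_b=tuple(codons_b),
        positions_a=tuple(range(n)),
        positions_b=tuple(range(n)),
    )


@pytest.fixture(scope="session")
def dayhoff() -> DayhoffPartition:
    return DayhoffPartition()
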