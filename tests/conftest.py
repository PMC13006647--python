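import pytest

from osckit import synthetic_data as sd
from osckit.sequence_core import CodingSequence

# 13-codon toy gene: M A E L K Q N K I Q A A *
# The L-K junction (codons 4-5) hides a +1-frame TGA; codons 6-8 contain
# di-adenine runs; the gene ends in its natural TAA.
TOY_WT_NT = "ATGGCAGAGCTGAAACAAAACAAAATTCAGGCAGCTTAA"


@pytest.fixture(scope="session")
def toy_wt() -> CodingSequence:
    return CodingSequence("toy", TOY_WT_NT)


@pytest.fixture(scope="session")
def toy_pair(toy_wt):
    """(+OSC construct, -OSC construct, synonymous pair), both carrying a +1 T
    inserted after codon 6 (Q) so that codon 7 reads TAA."""
    return sd.build_frameshifted_pair(toy_wt, region=(3, 6), frameshift_codon=6)
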