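import pytest
from hypothesis import settings

from mirqpcr import DesignConfig, design_target, parse_targets

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

LET7A_FASTA = ">ssc-let-7a\nTGAGGTAGTAGGTTGTATAGTT\n"

# Ten-target example listing (mixed case, RNA and DNA spellings).
EXAMPLE_FASTA = """\
>ssc-let-7a
TGAGGTAGTAGGTTGTATAGTT
>ssc-miR-21
tagcttatcagactgatgttga
>hsa-miR-25-3p
CATTGCACTTGTCTCGGTCTGA
>ssc-mir30a-3p
CUUUCAGUCGGAUGUUUGCAGC
>ssc-miR-106a
AAAAGTGCTTACAGTGCAGGTAGC
>gga-miR146c-5p
UGAGAACUGAAUUCCAUGGACUG
>ssc-mir-148a-3p
TCAGTGCACTACAGAACTTTGT
>hsa-miR-223-3p
UGUCAGUUUGUCAAAUACCCCA
>mmu-miR-667-3p
ugacaccugccacccagcccaag
>ssc-miR-7134-3p
tgcggaacctgcggatacgg
"""


@pytest.fixture(scope="session")
def config():
    return DesignConfig()


@pytest.fixture(scope="session")
def let7a_record():
    return parse_targets(LET7A_FASTA)[0]


@pytest.fixture(scope="session")
def let7a_result(let7a_record, config):
    return design_target(let7a_record, config)


@pytest.fixture(scope="session")
def example_fasta():
    return EXAMPLE_FASTA
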