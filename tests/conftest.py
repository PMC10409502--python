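import pytest

from arti.seqcore import DegenerateMatrix

# The six published, experimentally validated ARTi entries:
# name -> (target site, miR-E 97-mer cloning oligo).  Guides are the
# reverse complements of the target sites.
GOLDEN_ENTRIES = {
    "ARTi.6588": (
        "TCCGGATGAAGTTTATATCGAA",
        "TGCTGTTGACAGTGAGCGCCCGGATGAAGTTTATATCGAATAGTGAAGCCACAGATGTATTCGATATAAACTTCATCCGGATGCCTACTGCCTCGGA",
    ),
    "ARTi.6570": (
        "TCCGGATGATATTGTTATCGAA",
        "TGCTGTTGACAGTGAGCGCCCGGATGATATTGTTATCGAATAGTGAAGCCACAGATGTATTCGATAACAATATCATCCGGATGCCTACTGCCTCGGA",
    ),
    "ARTi.6634": (
        "TCCGGATGATGTTTTAATCGAA",
        "TGCTGTTGACAGTGAGCGCCCGGATGATGTTTTAATCGAATAGTGAAGCCACAGATGTATTCGATTAAAACATCATCCGGATGCCTACTGCCTCGGA",
    ),
    "ARTi.6786": (
        "TCCGGATGATATTGTATACGAA",
        "TGCTGTTGACAGTGAGCGCCCGGATGATATTGTATACGAATAGTGAAGCCACAGATGTATTCGTATACAATATCATCCGGATGCCTACTGCCTCGGA",
    ),
    "ARTi.6834": (
        "TCCGGATGATATTGCATACGAA",
        "TGCTGTTGACAGTGAGCGCCCGGATGATATTGCATACGAATAGTGAAGCCACAGATGTATTCGTATGCAATATCATCCGGATGCCTACTGCCTCGGA",
    ),
    "ARTi.6516": (
        "TCCGGATGAAGTTTAATTCGAA",
        "TGCTGTTGACAGTGAGCGCCCGGATGAAGTTTAATTCGAATAGTGAAGCCACAGATGTATTCGAATTAAACTTCATCCGGATGCCTACTGCCTCGGA",
    ),
}

# Published cassettes used for experimental validation.
GOLDEN_CDS_CASSETTE = "ATCCGGATGATATTGTATACGAATCCGGATGATATTGTTATCGAA"  # 6786+6570, A-padded
GOLDEN_UTR_CASSETTE = (
    "TCCGGATGATATTGTATACGAATCCGGATGATGTTTTAATCGAATCCGGATGATATTGTTATCGAA"
)  # 6786+6634+6570


@pytest.fixture(scope="session")
def golden_entries():
    return GOLDEN_ENTRIES


@pytest.fixture(scope="session")
def arti_matrix():
    return DegenerateMatrix.arti()
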