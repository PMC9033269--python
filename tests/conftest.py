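import pytest

from bedesign import builtin_profiles
from bedesign.fixtures import make_fixture_gene

# protospacers printed with their PAMs in the study's guide table, used as
# worked examples throughout the suite
OCA2_Q333 = ("GAAACCCAGGTGGCCATTGC", "AGG")
TNNT2A_Q114 = ("AGAGCGCCAAAAACGTCTTG", "AGG")
KCNH6A_R512 = ("ACTGCTCAGGTTGGTGCGAG", "TGG")
GFP_C71 = ("AGCACTGCACGCCGTAGGTC", "AGG")
DR_OCA2_L293 = ("GTACAGCGACTGGTTAGTCA", "TGG")


@pytest.fixture(scope="session")
def profiles():
    return builtin_profiles()


@pytest.fixture(scope="session")
def gene_fixture():
    """Two-exon gene with a 200-nt intron and stop-free CDS."""
    return make_fixture_gene(42)
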