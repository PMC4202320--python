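import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mitocomp import datasets
from mitocomp.simulate import SimSpec, sim_genome

GB_LINEAR = """\
LOCUS       TEST30                    30 bp    DNA     linear   UNA 01-JAN-2000
DEFINITION  toy linear record.
FEATURES             Location/Qualifiers
     source          1..30
     CDS             10..18
                     /gene="g1"
ORIGIN
        1 atgcatgcat gcatgcatgc atgcatgcat
//
"""

GB_CIRCULAR = """\
LOCUS       TESTC30                   30 bp    DNA     circular UNA 01-JAN-2000
DEFINITION  toy circular record.
FEATURES             Location/Qualifiers
     source          1..30
     CDS             complement(join(1..6,25..30))
                     /gene="g2"
     CDS             join(28..30,1..3)
                     /gene="g3"
ORIGIN
        1 atgcccgggt ttaaacccgg gtttaaaccc
//
"""


@pytest.fixture
def gb_linear(tmp_path):
    p = tmp_path / "linear.gb"
    p.write_text(GB_LINEAR)
    return p


@pytest.fixture
def gb_circular(tmp_path):
    p = tmp_path / "circular.gb"
    p.write_text(GB_CIRCULAR)
    return p


@pytest.fixture(scope="session")
def sim():
    """One simulated genome under the default study conditions, with a
    planted edit at codon 240 of an atp6-like gene and planted acceptor-stem
    mismatches in two tRNAs."""
    spec = SimSpec(seed=11, edits=(("atp6", 240),),
                   trna_mismatches=(("trnB", (2,)), ("trnC", (1, 3))))
    return sim_genome(spec)


@pytest.fixture(scope="session")
def curated():
    return {
        "matrix": datasets.load_discoba_presence(),
        "tree": datasets.load_discoba_tree(),
        "ancestral": datasets.load_jakobid_ancestral_genes(),
        "synonyms": datasets.load_gene_synonyms(),
    }
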