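from __future__ import annotations

import pytest

from plastdeg import RunConfig, build_degradation_matrix, simulate

GENBANK_TOY = """\
LOCUS       TOY1                     200 bp    DNA     circular PLN 01-JAN-2020
DEFINITION  toy plastome for parser tests.
ACCESSION   TOY1
VERSION     TOY1.1
SOURCE      Toyus plantus
  ORGANISM  Toyus plantus
FEATURES             Location/Qualifiers
     source          1..200
                     /organism="Toyus plantus"
     gene            11..90
                     /gene="geneA"
     CDS             join(11..30,51..90)
                     /gene="geneA"
     gene            complement(101..160)
                     /gene="trnX-ABC"
     tRNA            complement(101..160)
                     /gene="trnX-ABC"
     gene            171..190
                     /gene="psbZ"
                     /pseudo
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
       61 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
      121 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
      181 acgtacgtac gtacgtacgt
//
"""


@pytest.fixture(scope="session")
def toy_gb(tmp_path_factory):
    path = tmp_path_factory.mktemp("gb") / "toy.gb"
    path.write_text(GENBANK_TOY)
    return path


@pytest.fixture(scope="session")
def small_config():
    """Config sized for the ~6 kb toy genomes."""
    return RunConfig(min_ir_length=200)


@pytest.fixture(scope="session")
def toy_clade():
    return simulate.generate_clade(simulate.toy_spec(1))


@pytest.fixture(scope="session")
def toy_matrix(toy_clade, small_config):
    targets = [r for label, r in toy_clade.records.items() if label != "REF"]
    return build_degradation_matrix(toy_clade.reference, targets, small_config)
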