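import pytest

from zipperscan.io_formats import FamilyCatalogEntry, ProteinRecord
from zipperscan.synthetic_data import PlantedZipperSpec, gen_zipper_set


@pytest.fixture(scope="session")
def planted_family():
    """A small planted zipper family with perfect d-leucines (recoverable
    registers) and its ground truth."""
    spec = PlantedZipperSpec(n_proteins=40, n_heptads=(3, 10), p_leu_d=1.0, seed=11)
    return gen_zipper_set(spec)


@pytest.fixture()
def toy_catalog():
    return [
        FamilyCatalogEntry(gene_name="gA1", locus_id="L1", group="A"),
        FamilyCatalogEntry(gene_name="gA2", locus_id="L2", group="A"),
        FamilyCatalogEntry(gene_name="gS1", locus_id="L3", group="S"),
    ]


@pytest.fixture()
def simple_protein():
    return ProteinRecord(id="p1", residues="M" + "A" * 10 + "NAAAAAAAR" + "KAALLLELLLELKP")
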