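import pytest

from htract.genome_io import GeneRecord, GeneSet


@pytest.fixture
def toy_geneset() -> GeneSet:
    """Three small genes with distinctive runs and codons."""
    return GeneSet("toy", [
        GeneRecord("geneA", "AAACGTTTTTTT"),
        GeneRecord("geneB", "AAAAAGAAA"),
        GeneRecord("geneC", "ATGCCCGGGTAA"),
    ])


@pytest.fixture
def labelled_geneset() -> GeneSet:
    return GeneSet("lab", [
        GeneRecord("g1", "AAACGT", group_label="regulatory functions"),
        GeneRecord("g2", "CCGGTT", group_label="regulatory functions"),
        GeneRecord("g3", "ATATAT", group_label="transport"),
        GeneRecord("g4", "GCGCGC"),
    ])
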