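import pytest

from somaclass.config import LabConfig
from somaclass.knowledge import KnowledgeBase
from somaclass.model import Consequence, TumourCategory, VariantRecord


@pytest.fixture(scope="session")
def kb() -> KnowledgeBase:
    return KnowledgeBase.load()


@pytest.fixture()
def config() -> LabConfig:
    return LabConfig()


def make_record(
    gene="KRAS",
    transcript="NM_004985.4",
    cdna="c.35G>A",
    protein="p.(Gly12Asp)",
    consequence=Consequence.MISSENSE,
    category=TumourCategory.SOLID,
    vaf=0.25,
    depth=900,
    exon=None,
    sample_id="S1",
    chrom="chr12",
    pos=25245350,
    ref="C",
    alt="T",
) -> VariantRecord:
    return VariantRecord(
        sample_id=sample_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        vaf=vaf,
        depth=depth,
        gene=gene,
        transcript=transcript,
        cdna_hgvs=cdna,
        protein_hgvs=protein,
        consequence=consequence,
        exon=exon,
        tumour_category=category,
    )
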