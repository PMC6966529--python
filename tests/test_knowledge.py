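"""Hotspot-list loading, matching semantics and gene-role resolution."""

import pandas as pd
import pytest

from somaclass.knowledge import (
    GeneRoleKind,
    KnowledgeBaseError,
    MatchKind,
    default_kb_dir,
    load_cpv_list,
    lookup_role,
    match_cpv,
    write_cpv_list,
)
from somaclass.model import Consequence, TumourCategory

from conftest import make_record


class TestLoading:
    def test_every_curated_cell_maps_to_entries(self, kb):
        # every non-'none' table cell must be represented by >=1 entry
        for cpv, path in [
            (kb.cpv_solid, default_kb_dir() / "cpv_solid.tsv"),
            (kb.cpv_hemato, default_kb_dir() / "cpv_hemato.tsv"),
        ]:
            df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
            curated = df[~df["match_kind"].isin(["none", "see_solid"])]
            labels = {e.label for e in cpv.entries}
            for _, row in curated.iterrows():
                assert row["label"] in labels

    def test_none_genes_listed_with_zero_entries(self, kb):
        for gene in ("ASXL1", "CEBPA", "RUNX1", "TET2", "WT1"):
            assert gene in kb.cpv_hemato.listed_genes
            assert kb.cpv_hemato.for_gene(gene) == []

    def test_kit_haematological_redirects_to_solid_entries(self, kb):
        hemato_kit = kb.cpv_hemato.for_gene("KIT")
        solid_kit = kb.cpv_solid.for_gene("KIT")
        assert hemato_kit == solid_kit
        assert len(hemato_kit) == 12

    def test_braf_row_expansion(self, kb):
        entries = kb.cpv_solid.for_gene("BRAF")
        v600 = [e for e in entries if e.match_kind is MatchKind.EXACT_AA and e.position == 600]
        assert len(v600) == 1
        assert v600[0].allowed_alts == frozenset("EKMR")
        regions = [e for e in entries if e.match_kind is MatchKind.AA_REGION]
        assert regions[0].position == 599 and regions[0].end_position == 601

    def test_brca_rows_are_single_clear_lof_entries(self, kb):
        for gene in ("BRCA1", "BRCA2"):
            entries = kb.cpv_solid.for_gene(gene)
            assert len(entries) == 1
            assert entries[0].match_kind is MatchKind.ANY_CLEAR_LOF

    def test_exact_span_cells_detected(self, kb):
        pdgfra = {e.label: e for e in kb.cpv_solid.for_gene("PDGFRA")}
        assert pdgfra["S566_E577 if-del"].span_exact
        kit = {e.label: e for e in kb.cpv_solid.for_gene("KIT")}
        assert not kit["K550-V560 if-indel"].span_exact

    def test_duplicate_exact_entry_rejected(self, tmp_path, kb):
        path = tmp_path / "dup.tsv"
        header = "gene\ttranscript\tmatch_kind\tposition\tend_position\texon\tallowed_alts\tevent_class\tlabel\n"
        row = "BRAF\tNM_004333.5\texact_aa\t600\t.\t.\tE\tsubstitution\tV600E\n"
        path.write_text(header + row + row)
        with pytest.raises(KnowledgeBaseError):
            load_cpv_list(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "gene\ttranscript\tmatch_kind\tposition\tend_position\texon\tallowed_alts\tevent_class\tlabel\n"
            "BRAF\tNM_004333.5\texact_aa\t.\t.\t.\tE\tsubstitution\tV600E\n"
        )
        with pytest.raises(KnowledgeBaseError, match="row 2"):
            load_cpv_list(path)

    def test_round_trip_write_load(self, tmp_path, kb):
        out = tmp_path / "solid.tsv"
        write_cpv_list(kb.cpv_solid, out)
        reloaded = load_cpv_list(out)
        assert reloaded.entries == kb.cpv_solid.entries
        assert reloaded.listed_genes == kb.cpv_solid.listed_genes


class TestMatching:
    @pytest.mark.parametrize(
        "gene, protein, category, expect",
        [
            ("BRAF", "p.(Val600Met)", TumourCategory.SOLID, True),
            ("BRAF", "p.(Val600Ala)", TumourCategory.SOLID, False),  # A not allowed
            ("EGFR", "p.(Leu858Arg)", TumourCategory.SOLID, True),
            ("EGFR", "p.(Leu747Pro)", TumourCategory.SOLID, False),
            ("SF3B1", "p.(Lys666Asn)", TumourCategory.HAEMATOLOGICAL, True),
            ("JAK2", "p.(Val617Phe)", TumourCategory.HAEMATOLOGICAL, True),
        ],
    )
    def test_exact_aa_matching(self, kb, gene, protein, category, expect):
        record = make_record(
            gene=gene, transcript="NM_000000.1", protein=protein, category=category
        )
        hit = match_cpv(record, kb.cpv_for(category))
        assert (hit is not None) is expect

    def test_region_containment(self, kb):
        record = make_record(
            gene="KIT", protein="p.(Lys558_Val560del)",
            consequence=Consequence.INFRAME_DELETION, exon=11,
        )
        hit = match_cpv(record, kb.cpv_solid)
        assert hit is not None and hit.label == "K550-V560 if-indel"

    def test_region_rejects_overhang(self, kb):
        record = make_record(
            gene="KIT", protein="p.(Lys546_Val560del)",
            consequence=Consequence.INFRAME_DELETION, exon=11,
        )
        assert match_cpv(record, kb.cpv_solid) is None

    def test_exact_span_requires_both_endpoints(self, kb):
        inside = make_record(
            gene="PDGFRA", protein="p.(Ser566_Glu577del)",
            consequence=Consequence.INFRAME_DELETION,
        )
        partial = make_record(
            gene="PDGFRA", protein="p.(Ser566_Arg570del)",
            consequence=Consequence.INFRAME_DELETION,
        )
        assert match_cpv(inside, kb.cpv_solid).label == "S566_E577 if-del"
        assert match_cpv(partial, kb.cpv_solid) is None

    def test_exon_event_matching(self, kb):
        record = make_record(
            gene="EGFR", protein="p.(Glu746_Ala750del)",
            consequence=Consequence.INFRAME_DELETION, exon=19,
        )
        hit = match_cpv(record, kb.cpv_solid)
        assert hit is not None and hit.label == "ex19if-del/ins"

    def test_met_exon14_splice_event(self, kb):
        record = make_record(
            gene="MET", protein=None, cdna="c.3028+2T>C",
            consequence=Consequence.SPLICE_CORE, exon=14,
        )
        hit = match_cpv(record, kb.cpv_solid)
        assert hit is not None and hit.match_kind is MatchKind.SPLICE_EVENT

    def test_specificity_exact_beats_exon_event(self, kb):
        # EGFR T790M sits in exon 20; the exact residue entry must win over
        # the exon-20 insertion rule by specificity
        record = make_record(
            gene="EGFR", protein="p.(Thr790Met)", exon=20,
        )
        hit = match_cpv(record, kb.cpv_solid)
        assert hit.match_kind is MatchKind.EXACT_AA and hit.label == "T790M"

    def test_mpl_any_missense_excludes_nonsense(self, kb):
        missense = make_record(
            gene="MPL", protein="p.(Trp515Leu)",
            category=TumourCategory.HAEMATOLOGICAL,
        )
        nonsense = make_record(
            gene="MPL", protein="p.(Trp515*)",
            consequence=Consequence.NONSENSE,
            category=TumourCategory.HAEMATOLOGICAL,
        )
        assert match_cpv(missense, kb.cpv_hemato).label == "W515any ms"
        assert match_cpv(nonsense, kb.cpv_hemato) is None

    def test_match_independent_of_entry_order(self, kb):
        record = make_record(gene="EGFR", protein="p.(Thr790Met)", exon=20)
        shuffled = kb.cpv_solid
        reversed_list = type(shuffled)(
            entries=list(reversed(shuffled.entries)),
            listed_genes=shuffled.listed_genes,
        )
        assert match_cpv(record, shuffled) == match_cpv(record, reversed_list)


class TestRoles:
    @pytest.mark.parametrize(
        "gene, category, role",
        [
            ("TET2", TumourCategory.HAEMATOLOGICAL, GeneRoleKind.TUMOUR_SUPPRESSOR),
            ("KRAS", TumourCategory.SOLID, GeneRoleKind.ONCOGENE),
            ("BRCA2", TumourCategory.SOLID, GeneRoleKind.TUMOUR_SUPPRESSOR),
            ("JAK2", TumourCategory.HAEMATOLOGICAL, GeneRoleKind.ONCOGENE),
        ],
    )
    def test_role_lookup(self, kb, gene, category, role):
        resolved = lookup_role(gene, category, kb.roles)
        assert resolved is not None and resolved.role is role

    def test_unknown_gene_returns_none(self, kb):
        assert lookup_role("STAG2", TumourCategory.HAEMATOLOGICAL, kb.roles) is None
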