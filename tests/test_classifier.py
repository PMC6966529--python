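"""Evidence scoring, LoF routing and the gene-specific exception handlers."""

import itertools

import pytest

from somaclass.classifier import (
    RULE_EXC_BRCA_DB,
    RULE_EXC_BRCA_LOF,
    RULE_EXC_CALR_EX9,
    RULE_EXC_CEBPA_BZIP,
    RULE_EXC_MET_EX14,
    RULE_EXC_NPM1_EX11,
    RULE_EXC_TP53_DB,
    RULE_EXC_TP53_SPLICE,
    OverrideRecord,
    ScoreBreakdown,
    apply_exceptions,
    classify_lof,
    cosmic_score,
    insilico_score,
    is_clear_lof,
    score_variant,
    scoring_class,
)
from somaclass.config import LabConfig
from somaclass.knowledge import (
    EvidenceBundle,
    FunctionalEvidence,
    GeneRole,
    GeneRoleKind,
    GenomicDbVerdict,
    TriState,
)
from somaclass.model import BiologicalClass, Consequence, SomaclassError, TumourCategory

from conftest import make_record

SOLID = TumourCategory.SOLID
HEMATO = TumourCategory.HAEMATOLOGICAL


class TestCosmicParameter:
    @pytest.mark.parametrize(
        "count, category, expected",
        [
            # published worked examples
            (265, SOLID, 2),   # EGFR Ser768Ile
            (15, HEMATO, 2),   # SF3B1 Gly740Glu
            (35, SOLID, 1),    # BRAF Leu597Arg
            (7, HEMATO, 1),    # SRSF2 Pro107His
            (7, SOLID, 0),     # KRAS Asp57Asn
            (2, HEMATO, 0),    # TET2 Thr822Pro
            # band boundaries
            (50, SOLID, 2), (49, SOLID, 1), (11, SOLID, 1), (10, SOLID, 0),
            (10, HEMATO, 2), (9, HEMATO, 1), (6, HEMATO, 1), (5, HEMATO, 0),
            (0, SOLID, 0), (None, SOLID, 0),
        ],
    )
    def test_entry_count_bands(self, count, category, expected):
        assert cosmic_score(count, category) == expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            cosmic_score(-1, SOLID)


class TestInsilicoParameter:
    @pytest.mark.parametrize(
        "sift, mt, expected",
        [
            (TriState.YES, TriState.YES, 0.5),
            (TriState.YES, TriState.NO, 0),
            (TriState.NO, TriState.YES, 0),
            (TriState.UNKNOWN, TriState.YES, 0),
        ],
    )
    def test_both_tools_required(self, sift, mt, expected):
        assert insilico_score(sift, mt) == expected


class TestScoringTable:
    def test_worked_example_egfr_s768i(self):
        evidence = EvidenceBundle(
            cosmic_count=265,
            sift_damaging=TriState.YES,
            mutationtaster_damaging=TriState.YES,
        )
        score = score_variant(evidence, SOLID)
        assert (score.cosmic_score, score.insilico_score) == (2, 0.5)
        assert score.total == 2.5

    def test_worked_example_tet2_t822p(self):
        score = score_variant(EvidenceBundle(cosmic_count=2), HEMATO)
        assert score.total == 0

    def test_negative_evidence_sums(self):
        evidence = EvidenceBundle(
            cosmic_count=35,
            sift_damaging=TriState.YES,
            functional_evidence=FunctionalEvidence.SHOWN_BENIGN,
            genomic_db_verdict=GenomicDbVerdict.LIKELY_BENIGN_OR_BENIGN,
        )
        assert score_variant(evidence, SOLID).total == -1

    def test_exhaustive_grid_against_direct_enumeration(self):
        # brute-force closure of the table: 54 combinations per category
        totals = set()
        lp_totals = []
        for c, ins, fn, db in itertools.product(
            (2, 1, 0), (0.5, 0), (0.5, 0, -1), (0.5, 0, -1)
        ):
            score = ScoreBreakdown(c, ins, fn, db)
            totals.add(score.total)
            cls, _ = scoring_class(score, gene_is_cpv_listed=True)
            expected = (
                BiologicalClass.LIKELY_PATHOGENIC
                if score.total >= 2
                else BiologicalClass.VUS
            )
            assert cls is expected
            if cls is BiologicalClass.LIKELY_PATHOGENIC:
                lp_totals.append(score.total)
        assert max(totals) == 3.5
        assert min(totals) == -2
        assert min(lp_totals) == 2

    def test_monotone_in_each_parameter(self):
        # upgrading any parameter toward its pathogenic pole never lowers the class
        ladder = {
            "cosmic_score": (0, 1, 2),
            "insilico_score": (0, 0.5),
            "functional_score": (-1, 0, 0.5),
            "genomicdb_score": (-1, 0, 0.5),
        }
        base = dict(cosmic_score=1, insilico_score=0, functional_score=0, genomicdb_score=0)
        for param, values in ladder.items():
            prev_rank = -1
            for v in values:
                cls, _ = scoring_class(
                    ScoreBreakdown(**{**base, param: v}), gene_is_cpv_listed=True
                )
                assert cls.rank >= prev_rank
                prev_rank = cls.rank

    def test_max_score_promotion_only_outside_cpv_lists(self):
        top = ScoreBreakdown(2, 0.5, 0.5, 0.5)
        assert scoring_class(top, gene_is_cpv_listed=False)[0] is BiologicalClass.PATHOGENIC
        assert (
            scoring_class(top, gene_is_cpv_listed=True)[0]
            is BiologicalClass.LIKELY_PATHOGENIC
        )

    def test_override_raises_only_upward(self):
        low = ScoreBreakdown(0, 0, 0, 0)
        up = OverrideRecord("TET2", "c.1A>C", BiologicalClass.LIKELY_PATHOGENIC, "", "")
        cls, overruled = scoring_class(low, True, up)
        assert cls is BiologicalClass.LIKELY_PATHOGENIC and overruled
        down = OverrideRecord("TET2", "c.1A>C", BiologicalClass.VUS, "", "")
        high = ScoreBreakdown(2, 0.5, 0, 0)
        with pytest.raises(SomaclassError):
            scoring_class(high, True, down)


class TestLofRouting:
    @pytest.mark.parametrize(
        "consequence, expect",
        [
            (Consequence.FRAMESHIFT, True),
            (Consequence.NONSENSE, True),
            (Consequence.SPLICE_CORE, True),
            (Consequence.INFRAME_DELETION, False),
            (Consequence.MISSENSE, False),
        ],
    )
    def test_clear_lof_definition(self, consequence, expect):
        record = make_record(consequence=consequence, protein=None)
        assert is_clear_lof(record) is expect

    def test_routing_by_role(self):
        ts = GeneRole("TET2", GeneRoleKind.TUMOUR_SUPPRESSOR, "haematological")
        onc = GeneRole("KRAS", GeneRoleKind.ONCOGENE, "solid")
        assert classify_lof(ts) is BiologicalClass.LIKELY_PATHOGENIC
        assert classify_lof(onc) is BiologicalClass.VUS

    def test_lof_routing_never_reaches_extremes(self):
        for role_kind in GeneRoleKind:
            cls = classify_lof(GeneRole("X", role_kind, "solid"))
            assert cls in {BiologicalClass.LIKELY_PATHOGENIC, BiologicalClass.VUS}


class TestExceptions:
    def run(self, record, evidence=None, kb=None, config=None, log=None):
        return apply_exceptions(
            record, evidence or EvidenceBundle(), kb, config or LabConfig(), log
        )

    def test_tp53_splice_likely_pathogenic(self, kb):
        record = make_record(
            gene="TP53", transcript="NM_000546.5", cdna="c.375+1G>A", protein=None,
            consequence=Consequence.SPLICE_CORE, exon=4, category=HEMATO,
        )
        outcome = self.run(record, kb=kb)
        assert outcome.rule_id == RULE_EXC_TP53_SPLICE
        assert outcome.biological_class is BiologicalClass.LIKELY_PATHOGENIC

    def test_tp53_database_consensus_used(self, kb):
        record = make_record(
            gene="TP53", transcript="NM_000546.5", cdna="c.722C>T",
            protein="p.(Ser241Phe)", category=HEMATO,
        )
        evidence = EvidenceBundle(
            tp53_iarc_class=BiologicalClass.PATHOGENIC,
            tp53_seshat_class=BiologicalClass.PATHOGENIC,
        )
        outcome = self.run(record, evidence, kb=kb)
        assert outcome.rule_id == RULE_EXC_TP53_DB
        assert outcome.biological_class is BiologicalClass.PATHOGENIC

    def test_tp53_discordant_databases_fall_through_flagged(self, kb):
        record = make_record(
            gene="TP53", transcript="NM_000546.5", cdna="c.722C>T",
            protein="p.(Ser241Phe)", category=HEMATO,
        )
        evidence = EvidenceBundle(
            tp53_iarc_class=BiologicalClass.PATHOGENIC,
            tp53_seshat_class=BiologicalClass.VUS,
        )
        outcome = self.run(record, evidence, kb=kb)
        assert outcome.biological_class is None
        assert "manual_review" in outcome.flags

    def test_tp53_hotspot_left_to_cpv_stage(self, kb):
        record = make_record(
            gene="TP53", transcript="NM_000546.5", cdna="c.524G>A",
            protein="p.(Arg175His)", category=HEMATO,
        )
        assert self.run(record, kb=kb) is None

    def test_brca_clear_lof_pathogenic(self, kb):
        record = make_record(
            gene="BRCA2", transcript="NM_000059.3", cdna="c.9382C>T",
            protein="p.(Arg3128*)", consequence=Consequence.NONSENSE,
        )
        outcome = self.run(record, kb=kb)
        assert outcome.rule_id == RULE_EXC_BRCA_LOF
        assert outcome.biological_class is BiologicalClass.PATHOGENIC

    def test_brca_non_lof_takes_database_verdict(self, kb):
        record = make_record(
            gene="BRCA1", transcript="NM_007294.3", cdna="c.5096G>A",
            protein="p.(Arg1699Gln)",
        )
        evidence = EvidenceBundle(
            brca_db_verdict=GenomicDbVerdict.LIKELY_PATHOGENIC_OR_PATHOGENIC
        )
        outcome = self.run(record, evidence, kb=kb)
        assert outcome.rule_id == RULE_EXC_BRCA_DB
        assert outcome.biological_class is BiologicalClass.LIKELY_PATHOGENIC
        missing = self.run(record, kb=kb)
        assert missing.biological_class is None and "manual_review" in missing.flags

    def test_calr_exon9_out_of_frame_pathogenic(self, kb):
        record = make_record(
            gene="CALR", transcript="NM_004343.3", cdna="c.1099_1150del",
            protein="p.(Leu367Thrfs*46)", consequence=Consequence.FRAMESHIFT,
            exon=9, category=HEMATO,
        )
        outcome = self.run(record, kb=kb)
        assert outcome.rule_id == RULE_EXC_CALR_EX9
        assert outcome.biological_class is BiologicalClass.PATHOGENIC

    def test_calr_other_exon_not_claimed(self, kb):
        record = make_record(
            gene="CALR", transcript="NM_004343.3", cdna="c.100del",
            protein="p.(Leu34Serfs*10)", consequence=Consequence.FRAMESHIFT,
            exon=2, category=HEMATO,
        )
        assert self.run(record, kb=kb) is None

    def test_npm1_exon11_insertion_pathogenic(self, kb):
        record = make_record(
            gene="NPM1", transcript="NM_002520.6", cdna="c.860_863dup",
            protein="p.(Trp288Cysfs*12)", consequence=Consequence.FRAMESHIFT,
            exon=11, category=HEMATO,
        )
        outcome = self.run(record, kb=kb)
        assert outcome.rule_id == RULE_EXC_NPM1_EX11
        assert outcome.biological_class is BiologicalClass.PATHOGENIC

    def test_cebpa_bzip_inframe_indel(self, kb):
        record = make_record(
            gene="CEBPA", transcript="NM_004364.3", cdna="c.937_939dup",
            protein="p.(Lys313dup)", consequence=Consequence.INFRAME_INSERTION,
            category=HEMATO,
        )
        outcome = self.run(record, kb=kb)
        assert outcome.rule_id == RULE_EXC_CEBPA_BZIP
        assert outcome.biological_class is BiologicalClass.LIKELY_PATHOGENIC

    def test_cebpa_outside_bzip_not_claimed(self, kb):
        record = make_record(
            gene="CEBPA", transcript="NM_004364.3", cdna="c.250_252del",
            protein="p.(Ala84del)", consequence=Consequence.INFRAME_DELETION,
            category=HEMATO,
        )
        assert self.run(record, kb=kb) is None

    def test_met_exon14_splice_pathogenic(self, kb):
        record = make_record(
            gene="MET", transcript="NM_001127500.3", cdna="c.3028+2T>C",
            protein=None, consequence=Consequence.SPLICE_CORE, exon=14,
        )
        outcome = self.run(record, kb=kb)
        assert outcome.rule_id == RULE_EXC_MET_EX14
        assert outcome.biological_class is BiologicalClass.PATHOGENIC
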