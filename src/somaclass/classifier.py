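"""Biological classification: hotspot calls, LoF routing, evidence scoring.

Implements the decision stages downstream of filtering: consensus-hotspot
(CPV) assignment to Pathogenic, routing of clear loss-of-function variants by
gene role (tumour suppressor → Likely Pathogenic, oncogene → VUS), the
four-parameter additive scoring table for non-evident-LoF variants, and the
gene-specific exception handlers (TP53, BRCA1/2, CALR, NPM1, CEBPA, MET,
regional-benign) that bypass the general workflow.

Scores are half-unit rationals represented as floats; every reachable value
is a multiple of 0.5 and therefore exact in binary floating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .config import LabConfig
from .filters import ObservationLog, regional_benign_check
from .knowledge import (
    CpvEntry,
    EvidenceBundle,
    FunctionalEvidence,
    GeneRole,
    GeneRoleKind,
    GenomicDbVerdict,
    KnowledgeBase,
    TriState,
    match_cpv,
)
from .model import (
    INFRAME_INDEL_CONSEQUENCES,
    BiologicalClass,
    Consequence,
    SomaclassError,
    TumourCategory,
    VariantRecord,
)

#: stable rule identifiers used in audit trails and fixture ground truth
RULE_BOX1_DROP = "BOX1-DROP"
RULE_BOX2_POPULATION = "BOX2-POPULATION"
RULE_BOX3_CPV = "BOX3-CPV"
RULE_BOX4_TS_LOF = "BOX4-TS-LOF"
RULE_BOX4_ONCO_LOF = "BOX4-ONCO-LOF"
RULE_BOX5_SCORE = "BOX5-SCORE"
RULE_EXC_TP53_DB = "EXC-TP53-DB"
RULE_EXC_TP53_SPLICE = "EXC-TP53-SPLICE"
RULE_EXC_BRCA_LOF = "EXC-BRCA-LOF"
RULE_EXC_BRCA_DB = "EXC-BRCA-DB"
RULE_EXC_CALR_EX9 = "EXC-CALR-EX9"
RULE_EXC_NPM1_EX11 = "EXC-NPM1-EX11"
RULE_EXC_CEBPA_BZIP = "EXC-CEBPA-BZIP"
RULE_EXC_MET_EX14 = "EXC-MET-EX14"
RULE_EXC_REGIONAL_BENIGN = "EXC-REGIONAL-BENIGN"
RULE_OVERRIDE = "OVERRIDE"

TERMINAL_RULES = frozenset(
    {
        RULE_BOX2_POPULATION,
        RULE_BOX3_CPV,
        RULE_BOX4_TS_LOF,
        RULE_BOX4_ONCO_LOF,
        RULE_BOX5_SCORE,
        RULE_EXC_TP53_DB,
        RULE_EXC_TP53_SPLICE,
        RULE_EXC_BRCA_LOF,
        RULE_EXC_BRCA_DB,
        RULE_EXC_CALR_EX9,
        RULE_EXC_NPM1_EX11,
        RULE_EXC_CEBPA_BZIP,
        RULE_EXC_MET_EX14,
        RULE_EXC_REGIONAL_BENIGN,
        RULE_OVERRIDE,
    }
)


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-parameter scores from the four-parameter evidence table."""

    cosmic_score: float
    insilico_score: float
    functional_score: float
    genomicdb_score: float

    def __post_init__(self) -> None:
        if self.cosmic_score not in (2, 1, 0):
            raise ValueError("cosmic_score must be 2, 1 or 0")
        if self.insilico_score not in (0.5, 0):
            raise ValueError("insilico_score must be 0.5 or 0")
        if self.functional_score not in (0.5, 0, -1):
            raise ValueError("functional_score must be 0.5, 0 or -1")
        if self.genomicdb_score not in (0.5, 0, -1):
            raise ValueError("genomicdb_score must be 0.5, 0 or -1")

    @property
    def total(self) -> float:
        return (
            self.cosmic_score
            + self.insilico_score
            + self.functional_score
            + self.genomicdb_score
        )


def cosmic_score(count: Optional[int], tumour_category: TumourCategory) -> float:
    """COSMIC entry-count parameter.

    Solid tumours: ≥50 → +2, 10 < n < 50 → +1, n ≤ 10 → 0.
    Haematological: ≥10 → +2, 5 < n < 10 → +1, n ≤ 5 → 0.
    An unknown count scores 0 — missing evidence is never rewarded.
    """
    if count is None:
        return 0
    if count < 0:
        raise ValueError("cosmic_count must be non-negative")
    if tumour_category is TumourCategory.SOLID:
        hi, lo = 50, 10
    else:
        hi, lo = 10, 5
    if count >= hi:
        return 2
    if count > lo:
        return 1
    return 0


def insilico_score(sift: TriState, mutationtaster: TriState) -> float:
    """+0.5 only when both predictors call the change damaging/deleterious."""
    return 0.5 if (sift is TriState.YES and mutationtaster is TriState.YES) else 0


_FUNCTIONAL_SCORE = {
    FunctionalEvidence.HARMFUL: 0.5,
    FunctionalEvidence.NOT_REPORTED: 0,
    FunctionalEvidence.SHOWN_BENIGN: -1,
}

_GENOMICDB_SCORE = {
    GenomicDbVerdict.LIKELY_PATHOGENIC_OR_PATHOGENIC: 0.5,
    GenomicDbVerdict.NOT_DESCRIBED: 0,
    GenomicDbVerdict.LIKELY_BENIGN_OR_BENIGN: -1,
}


def score_variant(
    evidence: EvidenceBundle, tumour_category: TumourCategory
) -> ScoreBreakdown:
    """Score a non-evident-LoF variant against the four evidence parameters."""
    return ScoreBreakdown(
        cosmic_score=cosmic_score(evidence.cosmic_count, tumour_category),
        insilico_score=insilico_score(
            evidence.sift_damaging, evidence.mutationtaster_damaging
        ),
        functional_score=_FUNCTIONAL_SCORE[evidence.functional_evidence],
        genomicdb_score=_GENOMICDB_SCORE[evidence.genomic_db_verdict],
    )


@dataclass(frozen=True)
class OverrideRecord:
    """Curated upward class override with provenance."""

    gene: str
    cdna_hgvs: str
    new_class: BiologicalClass
    justification: str
    source: str


def scoring_class(
    score: ScoreBreakdown,
    gene_is_cpv_listed: bool,
    override: Optional[OverrideRecord] = None,
) -> tuple[BiologicalClass, bool]:
    """Map a total score to a class; returns (class, overruled).

    Total ≥ 2 → Likely Pathogenic, < 2 → VUS. A gene absent from the CPV
    lists is additionally promoted to Pathogenic at the maximal total of
    +3.5. A curated override may only raise the class; an override that
    would lower it is rejected.
    """
    total = score.total
    if total >= 2:
        cls = BiologicalClass.LIKELY_PATHOGENIC
    else:
        cls = BiologicalClass.VUS
    if not gene_is_cpv_listed and total == 3.5:
        cls = BiologicalClass.PATHOGENIC
    if override is not None:
        if override.new_class <= cls:
            raise SomaclassError(
                f"override for {override.gene} {override.cdna_hgvs} does not raise "
                f"the class ({cls.value} → {override.new_class.value}); only upward "
                "overrides are sanctioned"
            )
        return override.new_class, True
    return cls, False


# --- Box 3 / Box 4 ----------------------------------------------------------


def classify_cpv(record: VariantRecord, kb: KnowledgeBase) -> Optional[CpvEntry]:
    """Consensus-hotspot check; a hit means Pathogenic."""
    return match_cpv(record, kb.cpv_for(record.tumour_category))


CLEAR_LOF_CONSEQUENCES = frozenset(
    {Consequence.FRAMESHIFT, Consequence.NONSENSE, Consequence.SPLICE_CORE}
)


def is_clear_lof(record: VariantRecord) -> bool:
    """Frameshift, nonsense or AG/GT core splice-site change."""
    return record.consequence in CLEAR_LOF_CONSEQUENCES


def classify_lof(role: GeneRole) -> BiologicalClass:
    """Route a clear LoF variant by gene role.

    Tumour suppressor → Likely Pathogenic (haploinsufficiency; deliberately
    not Pathogenic because driver status is rarely functionally proven, and
    last-exon LoF is treated the same way). Oncogene → VUS, since oncogenes
    need activation, not loss.
    """
    if role.role is GeneRoleKind.TUMOUR_SUPPRESSOR:
        return BiologicalClass.LIKELY_PATHOGENIC
    return BiologicalClass.VUS


# --- exception handlers -----------------------------------------------------


@dataclass
class ExceptionOutcome:
    biological_class: Optional[BiologicalClass]
    rule_id: str
    detail: str = ""
    flags: set[str] = field(default_factory=set)


def _tp53_handler(
    record: VariantRecord, evidence: EvidenceBundle, kb: KnowledgeBase
) -> Optional[ExceptionOutcome]:
    if record.gene != "TP53":
        return None
    # hotspot residues stay on the general path so a CPV hit keeps Pathogenic
    if classify_cpv(record, kb) is not None:
        return None
    if record.consequence is Consequence.SPLICE_CORE:
        return ExceptionOutcome(
            BiologicalClass.LIKELY_PATHOGENIC,
            RULE_EXC_TP53_SPLICE,
            "TP53 ±1/±2 exon-flanking splice variant",
        )
    iarc, seshat = evidence.tp53_iarc_class, evidence.tp53_seshat_class
    if iarc is not None and seshat is not None and iarc == seshat:
        return ExceptionOutcome(
            iarc, RULE_EXC_TP53_DB, "consensus of the two dedicated TP53 databases"
        )
    if record.consequence is Consequence.SYNONYMOUS:
        # synonymous TP53 changes are retained for database checking; with no
        # consensus available they stay VUS pending review
        return ExceptionOutcome(
            BiologicalClass.VUS,
            RULE_EXC_TP53_DB,
            "TP53 synonymous change without database consensus",
            flags={"manual_review"},
        )
    return ExceptionOutcome(
        None, RULE_EXC_TP53_DB,
        "TP53 database classes absent or discordant; general workflow applies",
        flags={"manual_review"},
    )


def _brca_handler(
    record: VariantRecord, evidence: EvidenceBundle
) -> Optional[ExceptionOutcome]:
    if record.gene not in {"BRCA1", "BRCA2"}:
        return None
    if is_clear_lof(record):
        return ExceptionOutcome(
            BiologicalClass.PATHOGENIC,
            RULE_EXC_BRCA_LOF,
            f"clear LoF in {record.gene}",
        )
    verdict = evidence.brca_db_verdict
    if verdict is GenomicDbVerdict.LIKELY_PATHOGENIC_OR_PATHOGENIC:
        return ExceptionOutcome(
            BiologicalClass.LIKELY_PATHOGENIC, RULE_EXC_BRCA_DB,
            "dedicated BRCA database verdict: (Likely) Pathogenic",
        )
    if verdict is GenomicDbVerdict.LIKELY_BENIGN_OR_BENIGN:
        return ExceptionOutcome(
            BiologicalClass.LIKELY_BENIGN, RULE_EXC_BRCA_DB,
            "dedicated BRCA database verdict: (Likely) Benign",
        )
    return ExceptionOutcome(
        None, RULE_EXC_BRCA_DB,
        "no BRCA database verdict; general workflow applies",
        flags={"manual_review"},
    )


def _calr_handler(record: VariantRecord) -> Optional[ExceptionOutcome]:
    if record.gene != "CALR" or record.exon != 9:
        return None
    if record.consequence is Consequence.FRAMESHIFT:
        return ExceptionOutcome(
            BiologicalClass.PATHOGENIC,
            RULE_EXC_CALR_EX9,
            "out-of-frame indel in CALR exon 9 (type I/II pattern)",
        )
    return None


def _npm1_handler(record: VariantRecord) -> Optional[ExceptionOutcome]:
    if record.gene != "NPM1" or record.exon != 11:
        return None
    is_insertion = "ins" in record.cdna_hgvs or "dup" in record.cdna_hgvs
    if record.consequence is Consequence.FRAMESHIFT and is_insertion:
        return ExceptionOutcome(
            BiologicalClass.PATHOGENIC,
            RULE_EXC_NPM1_EX11,
            "out-of-frame insertion in NPM1 exon 11",
        )
    return None


def _cebpa_handler(
    record: VariantRecord, config: LabConfig
) -> Optional[ExceptionOutcome]:
    if record.gene != "CEBPA":
        return None
    if record.consequence not in INFRAME_INDEL_CONSEQUENCES:
        return None
    change = record.protein_change
    if change is None:
        return None
    lo, hi = config.cebpa_bzip_span
    start, end = change.span
    if start <= hi and end >= lo:  # overlap with the bZIP domain
        return ExceptionOutcome(
            BiologicalClass.LIKELY_PATHOGENIC,
            RULE_EXC_CEBPA_BZIP,
            f"in-frame indel within the CEBPA bZIP domain ({lo}-{hi})",
        )
    return None


def _met_handler(record: VariantRecord) -> Optional[ExceptionOutcome]:
    if record.gene != "MET":
        return None
    if record.consequence is Consequence.SPLICE_CORE and record.exon == 14:
        return ExceptionOutcome(
            BiologicalClass.PATHOGENIC,
            RULE_EXC_MET_EX14,
            "MET exon 14 splice-site variant (consensus hotspot)",
        )
    return None


def apply_exceptions(
    record: VariantRecord,
    evidence: EvidenceBundle,
    kb: KnowledgeBase,
    config: LabConfig,
    observation_log: Optional[ObservationLog] = None,
) -> Optional[ExceptionOutcome]:
    """Evaluate the gene-specific exception handlers, most specific first.

    Returns the first outcome whose handler claims the record. An outcome
    with ``biological_class=None`` means the handler fired but must fall
    through to the general workflow (its flags still propagate). Returns
    None when no handler applies.
    """
    handlers = (
        _met_handler(record),
        _calr_handler(record),
        _npm1_handler(record),
        _cebpa_handler(record, config),
        _tp53_handler(record, evidence, kb),
        _brca_handler(record, evidence),
    )
    for outcome in handlers:
        if outcome is not None:
            return outcome
    if regional_benign_check(record.key, observation_log, config):
        return ExceptionOutcome(
            BiologicalClass.LIKELY_BENIGN,
            RULE_EXC_REGIONAL_BENIGN,
            f"seen in ≥{config.regional_benign_min_samples} regional samples "
            "at heterozygous-germline VAF",
            flags={"regional_benign_candidate"},
        )
    return None


# --- result container -------------------------------------------------------


@dataclass
class TrailEntry:
    rule_id: str
    outcome: str
    detail: str = ""

    def to_dict(self) -> dict:
        return {"rule_id": self.rule_id, "outcome": self.outcome, "detail": self.detail}


@dataclass
class ClassificationResult:
    biological_class: BiologicalClass
    rule_trail: list[TrailEntry]
    terminal_rule: str
    score: Optional[ScoreBreakdown] = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.rule_trail:
            raise ValueError("rule_trail must be non-empty")
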