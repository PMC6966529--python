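"""Clinical four-tier mapping and report rendering.

The biological class constrains the clinical tier: (Likely) Benign is always
Tier IV and never reported; VUS is always Tier III and reported only in a
separated, disclaimed section; (Likely) Pathogenic variants take Tier I with
level A/B evidence, Tier II with level C/D, and Tier III when no clinical
evidence level is supplied. The evidence level itself is clinical curation
and arrives as input — the module enforces only the hard constraints.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .classifier import ClassificationResult
from .model import BiologicalClass, ChangeKind, SomaclassError, VariantRecord


class Tier(enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


class EvidenceLevel(enum.Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    NONE = "none"


class TierConstraintError(SomaclassError):
    """Raised when a tier request violates the hard mapping constraints."""


_BENIGN = {BiologicalClass.BENIGN, BiologicalClass.LIKELY_BENIGN}
_PATHOGENIC = {BiologicalClass.PATHOGENIC, BiologicalClass.LIKELY_PATHOGENIC}


@dataclass(frozen=True)
class TierAssignment:
    tier: Tier
    evidence_level: EvidenceLevel
    rationale: str = ""


def assign_tier(
    bio_class: BiologicalClass,
    evidence_level: EvidenceLevel,
    rationale: str = "",
) -> TierAssignment:
    """Map a biological class plus curated evidence level to a clinical tier."""
    if bio_class in _BENIGN:
        if evidence_level is not EvidenceLevel.NONE:
            raise TierConstraintError(
                "(Likely) Benign variants carry no clinical evidence level"
            )
        return TierAssignment(Tier.IV, evidence_level, rationale)
    if bio_class is BiologicalClass.VUS:
        return TierAssignment(Tier.III, evidence_level, rationale)
    # (Likely) Pathogenic
    if evidence_level in (EvidenceLevel.A, EvidenceLevel.B):
        return TierAssignment(Tier.I, evidence_level, rationale)
    if evidence_level in (EvidenceLevel.C, EvidenceLevel.D):
        return TierAssignment(Tier.II, evidence_level, rationale)
    return TierAssignment(Tier.III, evidence_level, rationale)


# --- conditional tier rules -------------------------------------------------


@dataclass(frozen=True)
class ConditionalTierRule:
    """Tier depends on a co-occurring hotspot hit in the same gene.

    Models resistance variants whose clinical significance requires an
    activating variant in the same gene (e.g. an EGFR resistance change is
    Tier I only alongside an activating EGFR variant, else Tier III).
    """

    gene: str
    change: str  # one-letter shorthand
    condition: str  # currently only 'co_occurring_cpv_same_gene'
    tier_if_true: Tier
    tier_if_false: Tier


def load_conditional_tier_rules(path: Union[str, Path]) -> list[ConditionalTierRule]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        ConditionalTierRule(
            gene=row["gene"].strip(),
            change=row["change"].strip(),
            condition=row["condition"].strip(),
            tier_if_true=Tier(row["tier_if_true"].strip()),
            tier_if_false=Tier(row["tier_if_false"].strip()),
        )
        for _, row in df.iterrows()
    ]


DEFAULT_CONDITIONAL_RULES = [
    ConditionalTierRule("EGFR", "L747P", "co_occurring_cpv_same_gene", Tier.I, Tier.III),
]


def apply_conditional_tier(
    record: VariantRecord,
    assignment: TierAssignment,
    sample_results: Sequence[tuple[VariantRecord, ClassificationResult]],
    rules: Optional[Sequence[ConditionalTierRule]] = None,
) -> TierAssignment:
    """Re-tier a variant whose clinical significance is context-dependent."""
    rules = DEFAULT_CONDITIONAL_RULES if rules is None else rules
    change = record.protein_change
    if change is None or change.kind not in (ChangeKind.SUBSTITUTION, ChangeKind.NONSENSE):
        return assignment
    short = change.shorthand()
    for rule in rules:
        if rule.gene != record.gene or rule.change != short:
            continue
        if rule.condition != "co_occurring_cpv_same_gene":
            raise SomaclassError(f"unknown conditional-tier condition {rule.condition!r}")
        co_occurring = any(
            other.gene == record.gene
            and other.key != record.key
            and res.terminal_rule == "BOX3-CPV"
            for other, res in sample_results
        )
        tier = rule.tier_if_true if co_occurring else rule.tier_if_false
        return TierAssignment(
            tier,
            assignment.evidence_level,
            f"conditional rule for {rule.gene} {rule.change}: "
            + ("activating co-variant present" if co_occurring else "no activating co-variant"),
        )
    return assignment


# --- report -----------------------------------------------------------------

MANDATORY_SAMPLE_FIELDS = [
    "sample_id",
    "sampling_date",
    "received_date",
    "tumoral_stage",
    "anatomic_site",
    "sample_type",
    "procedure",
    "neoplastic_cell_pct",
    "quality",
]

VUS_DISCLAIMER = (
    "Variants of unknown significance (VUS) are listed separately; their "
    "contribution to the malignancy is currently unknown and they must not "
    "guide clinical decisions."
)

GERMLINE_DISCLAIMER = (
    "This test cannot discriminate between somatic and germline variants."
)


@dataclass(frozen=True)
class ReportedVariant:
    gene: str
    transcript: str
    cdna_hgvs: str
    protein_hgvs: str
    vaf: float
    biological_class: BiologicalClass
    tier: Optional[Tier] = None
    evidence_level: Optional[EvidenceLevel] = None
    shorthand: Optional[str] = None
    interpretation: str = ""
    references: tuple[str, ...] = ()


@dataclass
class ReportDocument:
    sample_info: dict
    reported_variants: list[ReportedVariant]
    vus_variants: list[ReportedVariant]
    failed_regions: list[str]
    method_info: dict
    absence_statements: list[str]
    validators: list[str]
    validation_date: str

    def to_dict(self) -> dict:
        def var(v: ReportedVariant) -> dict:
            return {
                "gene": v.gene,
                "transcript": v.transcript,
                "cdna_hgvs": v.cdna_hgvs,
                "protein_hgvs": v.protein_hgvs,
                "vaf_percent": round(v.vaf * 100, 2),
                "biological_class": v.biological_class.value,
                "tier": v.tier.value if v.tier else None,
                "evidence_level": v.evidence_level.value if v.evidence_level else None,
                "shorthand": v.shorthand,
                "interpretation": v.interpretation,
                "references": list(v.references),
            }

        return {
            "sample": self.sample_info,
            "test_results": {
                "variants": [var(v) for v in self.reported_variants],
                "failed_regions": self.failed_regions,
            },
            "conclusion": {
                "variants": [
                    var(v)
                    for v in self.reported_variants
                    if v.tier in (Tier.I, Tier.II)
                    or (v.tier is Tier.III and v.biological_class in _PATHOGENIC)
                ],
                "absence_statements": self.absence_statements,
            },
            "vus_annex": {
                "disclaimer": VUS_DISCLAIMER,
                "variants": [var(v) for v in self.vus_variants],
            },
            "method": dict(self.method_info, germline_disclaimer=GERMLINE_DISCLAIMER),
            "sign_off": {
                "validators": self.validators,
                "date": self.validation_date,
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    def to_markdown(self) -> str:
        lines = ["# Molecular pathology report", "", "## Sample"]
        for key in MANDATORY_SAMPLE_FIELDS:
            lines.append(f"- {key.replace('_', ' ')}: {self.sample_info[key]}")
        lines += ["", "## Test results"]
        if self.reported_variants:
            lines.append("| Gene | Transcript | cDNA | Protein | VAF | Tier |")
            lines.append("|---|---|---|---|---|---|")
            for v in self.reported_variants:
                short = f" ({v.shorthand})" if v.shorthand else ""
                tier = v.tier.value if v.tier else "-"
                lines.append(
                    f"| {v.gene} | {v.transcript} | {v.cdna_hgvs} | "
                    f"{v.protein_hgvs}{short} | {v.vaf * 100:.1f}% | {tier} |"
                )
        else:
            lines.append("No reportable variants detected.")
        if self.failed_regions:
            lines.append("")
            lines.append("Regions that could not be interpreted: "
                         + "; ".join(self.failed_regions))
        lines += ["", "## Conclusion and interpretation"]
        concluded = [
            v for v in self.reported_variants
            if v.tier in (Tier.I, Tier.II)
            or (v.tier is Tier.III and v.biological_class in _PATHOGENIC)
        ]
        if concluded:
            for v in concluded:
                level = v.evidence_level.value if v.evidence_level else "none"
                text = v.interpretation or "clinical interpretation pending"
                refs = f" [{'; '.join(v.references)}]" if v.references else ""
                lines.append(
                    f"- {v.gene} {v.cdna_hgvs}; {v.protein_hgvs} — Tier {v.tier.value} "
                    f"(level {level}): {text}{refs}"
                )
        else:
            lines.append("No variants of established clinical significance detected.")
        for stmt in self.absence_statements:
            lines.append(f"- {stmt}")
        if self.vus_variants:
            lines += ["", "## Variants of unknown significance (annex)", "", VUS_DISCLAIMER, ""]
            for v in self.vus_variants:
                lines.append(f"- {v.gene} {v.cdna_hgvs}; {v.protein_hgvs} (VAF {v.vaf * 100:.1f}%)")
        lines += ["", "## Method"]
        for key, value in self.method_info.items():
            lines.append(f"- {key.replace('_', ' ')}: {value}")
        lines.append(f"- disclaimer: {GERMLINE_DISCLAIMER}")
        lines += [
            "",
            "## Sign-off",
            f"Validated by {', '.join(self.validators)} on {self.validation_date}.",
        ]
        return "\n".join(lines) + "\n"


def render_report(
    sample_info: dict,
    results: Iterable[tuple[VariantRecord, ClassificationResult, TierAssignment]],
    failed_regions: Sequence[str] = (),
    method_info: Optional[dict] = None,
    absence_statements: Sequence[str] = (),
    validators: Sequence[str] = ("",),
    validation_date: str = "",
) -> ReportDocument:
    """Build the clinical report document from classified, tiered variants.

    Hard content rules: (Likely) Benign variants never appear anywhere in the
    document; VUS are segregated into a disclaimed annex; every reported gene
    carries its versioned transcript accession; failed regions are listed.
    """
    missing = [f for f in MANDATORY_SAMPLE_FIELDS if f not in sample_info]
    if missing:
        raise SomaclassError(f"sample information missing mandatory fields: {missing}")

    reported: list[ReportedVariant] = []
    vus: list[ReportedVariant] = []
    for record, result, assignment in results:
        if result.biological_class in _BENIGN:
            continue  # must not be reported
        change = record.protein_change
        short = None
        if change is not None and change.kind in (
            ChangeKind.SUBSTITUTION, ChangeKind.NONSENSE,
        ):
            short = change.shorthand()
        rv = ReportedVariant(
            gene=record.gene,
            transcript=record.transcript,
            cdna_hgvs=record.cdna_hgvs,
            protein_hgvs=record.protein_hgvs or ".",
            vaf=record.vaf,
            biological_class=result.biological_class,
            tier=assignment.tier,
            evidence_level=assignment.evidence_level,
            shorthand=short,
            interpretation=assignment.rationale,
        )
        if result.biological_class is BiologicalClass.VUS:
            vus.append(rv)
        else:
            reported.append(rv)

    return ReportDocument(
        sample_info=dict(sample_info),
        reported_variants=reported,
        vus_variants=vus,
        failed_regions=list(failed_regions),
        method_info=dict(method_info or {}),
        absence_statements=list(absence_statements),
        validators=list(validators),
        validation_date=validation_date,
    )
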