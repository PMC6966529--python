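"""Curated knowledge tables: hotspot (CPV) lists, gene roles, evidence snapshots.

The consensus-pathogenic-variant (CPV) lists ship as versioned TSV files inside
the package (one per tumour category) and can be replaced by the lab. Every
entry keeps the original curated cell text in ``label`` so the audit trail can
cite the source row verbatim. Per-variant evidence (COSMIC entry counts,
in-silico predictions, functional-study and genomic-database verdicts,
population frequencies) arrives as offline snapshot tables — classification
never performs a network query.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .model import (
    INFRAME_INDEL_CONSEQUENCES,
    BiologicalClass,
    ChangeKind,
    Consequence,
    ProteinChange,
    SomaclassError,
    TumourCategory,
    VariantRecord,
)


class KnowledgeBaseError(SomaclassError):
    """Raised on malformed knowledge tables."""


class MatchKind(enum.Enum):
    EXACT_AA = "exact_aa"
    AA_REGION = "aa_region"
    EXON_EVENT = "exon_event"
    ANY_CLEAR_LOF = "any_clear_lof"
    SPLICE_EVENT = "splice_event"


#: specificity order for tie-breaking: an exact residue hit beats a region
#: hit, which beats an exon-level event, and so on.
_SPECIFICITY = {
    MatchKind.EXACT_AA: 0,
    MatchKind.AA_REGION: 1,
    MatchKind.EXON_EVENT: 2,
    MatchKind.ANY_CLEAR_LOF: 3,
    MatchKind.SPLICE_EVENT: 4,
}


class EventClass(enum.Enum):
    SUBSTITUTION = "substitution"
    INFRAME_DEL = "inframe_del"
    INFRAME_INS = "inframe_ins"
    INFRAME_INDEL = "inframe_indel"
    OUT_OF_FRAME_DEL = "out_of_frame_del"
    OUT_OF_FRAME_INS = "out_of_frame_ins"
    DUPLICATION = "duplication"
    SKIPPING = "skipping"
    ANY_MISSENSE = "any_missense"
    CLEAR_LOF = "clear_lof"


class GeneRoleKind(enum.Enum):
    TUMOUR_SUPPRESSOR = "tumour_suppressor"
    ONCOGENE = "oncogene"


class TriState(enum.Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, value: object) -> "TriState":
        if isinstance(value, cls):
            return value
        if value is None:
            return cls.UNKNOWN
        key = str(value).strip().lower()
        if key in {"", ".", "na", "unknown", "nan"}:
            return cls.UNKNOWN
        if key in {"yes", "y", "true", "1", "damaging", "deleterious"}:
            return cls.YES
        if key in {"no", "n", "false", "0", "tolerated", "benign"}:
            return cls.NO
        raise ValueError(f"cannot interpret tri-state value {value!r}")


class FunctionalEvidence(enum.Enum):
    HARMFUL = "harmful"
    NOT_REPORTED = "not_reported"
    SHOWN_BENIGN = "shown_benign"


class GenomicDbVerdict(enum.Enum):
    LIKELY_PATHOGENIC_OR_PATHOGENIC = "likely_pathogenic_or_pathogenic"
    NOT_DESCRIBED = "not_described"
    LIKELY_BENIGN_OR_BENIGN = "likely_benign_or_benign"


@dataclass(frozen=True)
class CpvEntry:
    """One curated hotspot rule from the CPV lists."""

    gene: str
    transcript: str
    match_kind: MatchKind
    label: str
    position: Optional[int] = None
    end_position: Optional[int] = None
    exon: Optional[int] = None
    allowed_alts: Optional[frozenset[str]] = None
    event_class: Optional[EventClass] = None
    span_exact: bool = False  # "X_Y" cells pin both endpoints; "X-Y" is containment
    ref_aa: Optional[str] = None

    def __post_init__(self) -> None:
        if self.match_kind is MatchKind.EXACT_AA:
            if self.position is None:
                raise KnowledgeBaseError(f"exact_aa entry without position: {self.label}")
            if not self.allowed_alts and self.event_class is not EventClass.ANY_MISSENSE:
                raise KnowledgeBaseError(
                    f"exact_aa entry without allowed alternates: {self.label}"
                )
        if self.match_kind is MatchKind.AA_REGION and (
            self.position is None or self.end_position is None
        ):
            raise KnowledgeBaseError(f"aa_region entry without span: {self.label}")
        if self.match_kind is MatchKind.EXON_EVENT and (
            self.exon is None or self.event_class is None
        ):
            raise KnowledgeBaseError(f"exon_event entry without exon/class: {self.label}")

    @property
    def specificity(self) -> int:
        return _SPECIFICITY[self.match_kind]


@dataclass(frozen=True)
class GeneRole:
    gene: str
    role: GeneRoleKind
    tumour_category: str  # 'solid' | 'haematological' | 'both'


@dataclass(frozen=True)
class PopulationEntry:
    population: str
    maf: float
    allele_number: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"maf must be in [0,1], got {self.maf}")
        if self.allele_number < 0:
            raise ValueError("allele_number must be non-negative")


@dataclass(frozen=True)
class PopulationFrequencySnapshot:
    """Offline per-variant excerpt of an ethnic-stratified frequency database."""

    entries: tuple[PopulationEntry, ...] = ()
    dbsnp_listed: TriState = TriState.UNKNOWN

    def __post_init__(self) -> None:
        pops = [e.population for e in self.entries]
        if len(pops) != len(set(pops)):
            raise ValueError("duplicate population in snapshot")

    def eligible_max_maf(self, min_allele_number: int) -> Optional[float]:
        """Maximum MAF over populations with enough interrogated alleles."""
        eligible = [e.maf for e in self.entries if e.allele_number >= min_allele_number]
        return max(eligible) if eligible else None


@dataclass(frozen=True)
class EvidenceBundle:
    """Offline evidence snapshot for one variant.

    Every field defaults to its "unknown / not described" state; absence of
    database coverage must degrade the classification towards VUS, never
    towards Pathogenic.
    """

    cosmic_count: Optional[int] = None
    sift_damaging: TriState = TriState.UNKNOWN
    mutationtaster_damaging: TriState = TriState.UNKNOWN
    functional_evidence: FunctionalEvidence = FunctionalEvidence.NOT_REPORTED
    genomic_db_verdict: GenomicDbVerdict = GenomicDbVerdict.NOT_DESCRIBED
    tp53_iarc_class: Optional[BiologicalClass] = None
    tp53_seshat_class: Optional[BiologicalClass] = None
    brca_db_verdict: Optional[GenomicDbVerdict] = None

    def __post_init__(self) -> None:
        if self.cosmic_count is not None and self.cosmic_count < 0:
            raise ValueError("cosmic_count must be non-negative")


# --- CPV list I/O -----------------------------------------------------------

_CPV_COLUMNS = [
    "gene", "transcript", "match_kind", "position", "end_position",
    "exon", "allowed_alts", "event_class", "label",
]

_EXACT_SPAN_RE = re.compile(r"[A-Z*]\d+_[A-Z*]?\d+")


def _opt_int(value: object) -> Optional[int]:
    s = str(value).strip()
    if s in {"", ".", "nan"}:
        return None
    return int(float(s))


def default_kb_dir() -> Path:
    """Directory of the packaged knowledge tables."""
    return Path(resources.files("somaclass") / "data")


@dataclass
class CpvList:
    """Parsed CPV list for one tumour category."""

    entries: list[CpvEntry]
    listed_genes: frozenset[str]  # includes 'none' genes with zero entries

    def for_gene(self, gene: str) -> list[CpvEntry]:
        return [e for e in self.entries if e.gene == gene]


def load_cpv_list(
    path: Union[str, Path],
    solid_path: Optional[Union[str, Path]] = None,
) -> CpvList:
    """Load and validate a CPV list TSV.

    ``see_solid`` rows (the myeloid KIT entry defers to the solid list) are
    resolved against ``solid_path`` when given, otherwise against the packaged
    solid table. ``none`` rows yield zero entries but keep the gene flagged as
    CPV-listed, which matters for the hotspot exemption in technical filtering
    and for the maximal-score Pathogenic promotion.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _CPV_COLUMNS if c not in df.columns]
    if missing:
        raise KnowledgeBaseError(f"{path}: missing columns {missing}")

    entries: list[CpvEntry] = []
    listed: set[str] = set()
    seen_exact: set[tuple[str, int, frozenset[str]]] = set()
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # header is line 1
        gene = row["gene"].strip()
        kind_raw = row["match_kind"].strip()
        listed.add(gene)
        if kind_raw == "none":
            continue
        if kind_raw == "see_solid":
            solid = load_cpv_list(solid_path or default_kb_dir() / "cpv_solid.tsv")
            redirected = solid.for_gene(gene)
            if not redirected:
                raise KnowledgeBaseError(
                    f"{path} row {rownum}: see_solid for {gene} resolves to nothing"
                )
            entries.extend(redirected)
            continue
        try:
            kind = MatchKind(kind_raw)
            alts_raw = row["allowed_alts"].strip()
            alts = (
                frozenset(a.strip() for a in alts_raw.split(",") if a.strip())
                if alts_raw not in {"", "."}
                else None
            )
            ec_raw = row["event_class"].strip()
            event_class = EventClass(ec_raw) if ec_raw not in {"", "."} else None
            label = row["label"].strip()
            entry = CpvEntry(
                gene=gene,
                transcript=row["transcript"].strip(),
                match_kind=kind,
                position=_opt_int(row["position"]),
                end_position=_opt_int(row["end_position"]),
                exon=_opt_int(row["exon"]),
                allowed_alts=alts,
                event_class=event_class,
                label=label,
                span_exact=bool(_EXACT_SPAN_RE.search(label)),
                ref_aa=label[0] if kind is MatchKind.EXACT_AA and label[:1].isalpha() else None,
            )
        except (ValueError, KnowledgeBaseError) as exc:
            raise KnowledgeBaseError(f"{path} row {rownum}: {exc}") from exc
        if kind is MatchKind.EXACT_AA and entry.allowed_alts is not None:
            key = (gene, entry.position, entry.allowed_alts)
            if key in seen_exact:
                raise KnowledgeBaseError(
                    f"{path} row {rownum}: duplicate exact_aa entry for {gene} {entry.position}"
                )
            seen_exact.add(key)
        entries.append(entry)
    return CpvList(entries=entries, listed_genes=frozenset(listed))


def write_cpv_list(cpv: CpvList, path: Union[str, Path]) -> None:
    """Write a CPV list back to TSV (round-trips the packaged tables)."""
    rows = []
    emitted = set()
    for e in cpv.entries:
        emitted.add(e.gene)
        rows.append(
            {
                "gene": e.gene,
                "transcript": e.transcript,
                "match_kind": e.match_kind.value,
                "position": "." if e.position is None else str(e.position),
                "end_position": "." if e.end_position is None else str(e.end_position),
                "exon": "." if e.exon is None else str(e.exon),
                "allowed_alts": ",".join(sorted(e.allowed_alts)) if e.allowed_alts else ".",
                "event_class": e.event_class.value if e.event_class else ".",
                "label": e.label,
            }
        )
    for gene in sorted(cpv.listed_genes - emitted):
        rows.append(
            {
                "gene": gene, "transcript": ".", "match_kind": "none",
                "position": ".", "end_position": ".", "exon": ".",
                "allowed_alts": ".", "event_class": ".", "label": "none",
            }
        )
    pd.DataFrame(rows, columns=_CPV_COLUMNS).to_csv(path, sep="\t", index=False)


# --- CPV matching -----------------------------------------------------------

_INFRAME_EVENT_FOR_CONSEQUENCE = {
    Consequence.INFRAME_DELETION: {EventClass.INFRAME_DEL, EventClass.INFRAME_INDEL},
    Consequence.INFRAME_INSERTION: {
        EventClass.INFRAME_INS,
        EventClass.INFRAME_INDEL,
        EventClass.DUPLICATION,
    },
    Consequence.INFRAME_DELINS: {EventClass.INFRAME_INDEL},
    Consequence.FRAMESHIFT: {EventClass.OUT_OF_FRAME_DEL, EventClass.OUT_OF_FRAME_INS},
}


def _record_event_classes(record: VariantRecord) -> set[EventClass]:
    classes = set(_INFRAME_EVENT_FOR_CONSEQUENCE.get(record.consequence, set()))
    if record.consequence is Consequence.FRAMESHIFT:
        # distinguish out-of-frame del vs ins from the cDNA description
        cdna = record.cdna_hgvs
        has_ins = "ins" in cdna or "dup" in cdna
        has_del = "del" in cdna
        if has_ins and not has_del:
            classes = {EventClass.OUT_OF_FRAME_INS}
        elif has_del and not has_ins:
            classes = {EventClass.OUT_OF_FRAME_DEL}
    change = record.protein_change
    if change is not None and change.kind is ChangeKind.DUPLICATION:
        classes |= {EventClass.DUPLICATION, EventClass.INFRAME_INS, EventClass.INFRAME_INDEL}
    return classes


def _entry_matches(entry: CpvEntry, record: VariantRecord) -> bool:
    if entry.gene != record.gene:
        return False
    change = record.protein_change
    kind = entry.match_kind

    if kind is MatchKind.EXACT_AA:
        if change is None:
            return False
        if entry.event_class is EventClass.ANY_MISSENSE:
            return (
                record.consequence is Consequence.MISSENSE
                and change.kind is ChangeKind.SUBSTITUTION
                and change.position == entry.position
            )
        if change.kind is not ChangeKind.SUBSTITUTION:
            return False
        if change.position != entry.position:
            return False
        if entry.ref_aa and change.ref_aa != entry.ref_aa:
            return False
        return change.alt_aa in (entry.allowed_alts or frozenset())

    if kind is MatchKind.AA_REGION:
        if change is None:
            return False
        wanted = entry.event_class
        ok_kind = {
            EventClass.INFRAME_DEL: {ChangeKind.INFRAME_DEL, ChangeKind.INFRAME_DELINS},
            EventClass.INFRAME_INS: {ChangeKind.INFRAME_INS, ChangeKind.DUPLICATION},
            EventClass.INFRAME_INDEL: {
                ChangeKind.INFRAME_DEL,
                ChangeKind.INFRAME_INS,
                ChangeKind.INFRAME_DELINS,
                ChangeKind.DUPLICATION,
            },
        }.get(wanted, set())
        if change.kind not in ok_kind:
            return False
        lo, hi = change.span
        if entry.span_exact:
            return lo == entry.position and hi == entry.end_position
        return entry.position <= lo and hi <= entry.end_position

    if kind is MatchKind.EXON_EVENT:
        if record.exon != entry.exon:
            return False
        return bool(_record_event_classes(record) & {entry.event_class})

    if kind is MatchKind.ANY_CLEAR_LOF:
        return record.consequence in {
            Consequence.NONSENSE,
            Consequence.FRAMESHIFT,
            Consequence.SPLICE_CORE,
        }

    if kind is MatchKind.SPLICE_EVENT:
        return (
            record.consequence is Consequence.SPLICE_CORE
            and record.exon == entry.exon
        )

    return False  # pragma: no cover


def match_cpv(record: VariantRecord, cpv: CpvList) -> Optional[CpvEntry]:
    """Return the most specific CPV entry matching the record, or None.

    Deterministic and independent of file order: candidates are ranked by
    match-kind specificity, then by label for stability.
    """
    candidates = [e for e in cpv.for_gene(record.gene) if _entry_matches(e, record)]
    if not candidates:
        return None
    return min(candidates, key=lambda e: (e.specificity, e.label))


# --- gene roles -------------------------------------------------------------


def load_gene_roles(path: Union[str, Path]) -> list[GeneRole]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    roles = []
    seen: set[tuple[str, str]] = set()
    for idx, row in df.iterrows():
        gene = row["gene"].strip()
        cat = row["tumour_category"].strip()
        cats = (
            ["solid", "haematological"] if cat == "both" else [cat]
        )
        for c in cats:
            if (gene, c) in seen:
                raise KnowledgeBaseError(
                    f"{path} row {int(idx) + 2}: duplicate role for ({gene}, {c})"
                )
            seen.add((gene, c))
        roles.append(
            GeneRole(gene=gene, role=GeneRoleKind(row["role"].strip()), tumour_category=cat)
        )
    return roles


def lookup_role(
    gene: str, tumour_category: TumourCategory, roles: Iterable[GeneRole]
) -> Optional[GeneRole]:
    """Resolve a gene's role for a tumour category; None when unknown.

    Dual-role genes carry one row per category; an unknown gene returns None
    and the engine routes the variant to the scoring table with a
    manual-review flag rather than guessing.
    """
    cat = tumour_category.value
    best = None
    for r in roles:
        if r.gene != gene:
            continue
        if r.tumour_category == cat:
            return r
        if r.tumour_category == "both":
            best = GeneRole(gene=gene, role=r.role, tumour_category=cat)
    return best


# --- evidence / population snapshot tables ----------------------------------


def _opt_class(value: str) -> Optional[BiologicalClass]:
    s = value.strip()
    if s in {"", "."}:
        return None
    return BiologicalClass.from_label(s)


def _verdict(value: str, default: Optional[GenomicDbVerdict]) -> Optional[GenomicDbVerdict]:
    s = value.strip()
    if s in {"", "."}:
        return default
    return GenomicDbVerdict(s)


def load_evidence_table(path: Union[str, Path]) -> dict[tuple[str, str], EvidenceBundle]:
    """Load per-variant evidence snapshots keyed by (gene, cdna_hgvs)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[tuple[str, str], EvidenceBundle] = {}
    for _, row in df.iterrows():
        key = (row["gene"].strip(), row["cdna_hgvs"].strip())
        count = _opt_int(row.get("cosmic_count", "."))
        func = row.get("functional_evidence", "").strip()
        out[key] = EvidenceBundle(
            cosmic_count=count,
            sift_damaging=TriState.parse(row.get("sift_damaging", ".")),
            mutationtaster_damaging=TriState.parse(row.get("mutationtaster_damaging", ".")),
            functional_evidence=(
                FunctionalEvidence(func) if func not in {"", "."}
                else FunctionalEvidence.NOT_REPORTED
            ),
            genomic_db_verdict=_verdict(
                row.get("genomic_db_verdict", ""), GenomicDbVerdict.NOT_DESCRIBED
            ),
            tp53_iarc_class=_opt_class(row.get("tp53_iarc_class", "")),
            tp53_seshat_class=_opt_class(row.get("tp53_seshat_class", "")),
            brca_db_verdict=_verdict(row.get("brca_db_verdict", ""), None),
        )
    return out


def load_population_table(
    path: Union[str, Path],
) -> dict[tuple[str, str], PopulationFrequencySnapshot]:
    """Load population snapshots: one row per (variant, population)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    grouped: dict[tuple[str, str], list[PopulationEntry]] = {}
    dbsnp: dict[tuple[str, str], TriState] = {}
    for _, row in df.iterrows():
        key = (row["gene"].strip(), row["cdna_hgvs"].strip())
        pop = row["population"].strip()
        if pop not in {"", "."}:
            grouped.setdefault(key, []).append(
                PopulationEntry(
                    population=pop,
                    maf=float(row["maf"]),
                    allele_number=int(float(row["allele_number"])),
                )
            )
        else:
            grouped.setdefault(key, [])
        dbsnp[key] = TriState.parse(row.get("dbsnp_listed", "."))
    return {
        key: PopulationFrequencySnapshot(entries=tuple(entries), dbsnp_listed=dbsnp[key])
        for key, entries in grouped.items()
    }


# --- aggregate container ----------------------------------------------------


@dataclass
class KnowledgeBase:
    """All knowledge tables needed by the classification engine."""

    cpv_solid: CpvList
    cpv_hemato: CpvList
    roles: list[GeneRole]
    versions: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def load(cls, kb_dir: Optional[Union[str, Path]] = None) -> "KnowledgeBase":
        base = Path(kb_dir) if kb_dir is not None else default_kb_dir()
        solid_path = base / "cpv_solid.tsv"
        return cls(
            cpv_solid=load_cpv_list(solid_path),
            cpv_hemato=load_cpv_list(base / "cpv_hemato.tsv", solid_path=solid_path),
            roles=load_gene_roles(base / "gene_roles.tsv"),
            versions={
                "cpv_solid": "2019.1",
                "cpv_hemato": "2019.1",
                "gene_roles": "2019.1",
            },
        )

    def cpv_for(self, category: TumourCategory) -> CpvList:
        return self.cpv_solid if category is TumourCategory.SOLID else self.cpv_hemato

    def is_cpv_listed_gene(self, gene: str, category: TumourCategory) -> bool:
        return gene in self.cpv_for(category).listed_genes

    def role_of(self, gene: str, category: TumourCategory) -> Optional[GeneRole]:
        return lookup_role(gene, category, self.roles)
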