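"""Core domain types for somatic variant classification.

Holds the observed-variant record, the five-class biological outcome, and a
small parser for HGVS protein descriptions (three-letter amino-acid codes,
optional prediction parentheses). The three-letter ↔ one-letter conversion is
deliberately strict: hotspot lists are keyed on one-letter shorthand such as
``V600E`` and a silent mis-conversion (e.g. rendering Trp as ``T``) would
corrupt every downstream lookup.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from functools import total_ordering
from typing import Optional


class SomaclassError(Exception):
    """Base class for package errors."""


class HgvsParseError(SomaclassError):
    """Raised when a protein HGVS string cannot be parsed."""


@total_ordering
class BiologicalClass(enum.Enum):
    """Five-class, tumour-type-independent biological classification.

    Totally ordered by increasing pathogenicity:
    Benign < LikelyBenign < VUS < LikelyPathogenic < Pathogenic.
    """

    BENIGN = "Benign"
    LIKELY_BENIGN = "Likely Benign"
    VUS = "VUS"
    LIKELY_PATHOGENIC = "Likely Pathogenic"
    PATHOGENIC = "Pathogenic"

    @property
    def rank(self) -> int:
        return _CLASS_ORDER[self]

    def __lt__(self, other: "BiologicalClass") -> bool:
        if not isinstance(other, BiologicalClass):
            return NotImplemented
        return self.rank < other.rank

    @classmethod
    def from_label(cls, label: str) -> "BiologicalClass":
        key = label.strip().lower().replace("_", " ")
        for member in cls:
            if member.value.lower() == key:
                return member
        aliases = {
            "lb": cls.LIKELY_BENIGN,
            "b": cls.BENIGN,
            "lp": cls.LIKELY_PATHOGENIC,
            "p": cls.PATHOGENIC,
            "likelybenign": cls.LIKELY_BENIGN,
            "likelypathogenic": cls.LIKELY_PATHOGENIC,
            "variant of unknown significance": cls.VUS,
            "vus": cls.VUS,
        }
        if key in aliases:
            return aliases[key]
        raise ValueError(f"unknown biological class label: {label!r}")


_CLASS_ORDER = {
    BiologicalClass.BENIGN: 0,
    BiologicalClass.LIKELY_BENIGN: 1,
    BiologicalClass.VUS: 2,
    BiologicalClass.LIKELY_PATHOGENIC: 3,
    BiologicalClass.PATHOGENIC: 4,
}


class Consequence(enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_DELETION = "inframe_deletion"
    INFRAME_INSERTION = "inframe_insertion"
    INFRAME_DELINS = "inframe_delins"
    SYNONYMOUS = "synonymous"
    SPLICE_CORE = "splice_core"
    INTRONIC = "intronic"
    OTHER = "other"


#: consequences that count as an in-frame indel for hotspot-region matching
INFRAME_INDEL_CONSEQUENCES = frozenset(
    {
        Consequence.INFRAME_DELETION,
        Consequence.INFRAME_INSERTION,
        Consequence.INFRAME_DELINS,
    }
)


class TumourCategory(enum.Enum):
    SOLID = "solid"
    HAEMATOLOGICAL = "haematological"

    @classmethod
    def from_label(cls, label: str) -> "TumourCategory":
        key = label.strip().lower()
        if key in {"solid"}:
            return cls.SOLID
        if key in {"haematological", "hematological", "hemato", "haemato", "myeloid"}:
            return cls.HAEMATOLOGICAL
        raise ValueError(f"unknown tumour category: {label!r}")


class ChangeKind(enum.Enum):
    SUBSTITUTION = "substitution"
    INFRAME_DEL = "inframe_del"
    INFRAME_INS = "inframe_ins"
    INFRAME_DELINS = "inframe_delins"
    FRAMESHIFT = "frameshift"
    NONSENSE = "nonsense"
    DUPLICATION = "duplication"


# --- amino-acid code tables -------------------------------------------------

AA_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}

AA_ONE_TO_THREE = {one: three for three, one in AA_THREE_TO_ONE.items()}


def aa_three_to_one(code3: str) -> str:
    """Convert a three-letter amino-acid code (or ``Ter``) to one-letter.

    Strict lookup: unknown codes raise rather than guess, because fuzzy
    matching is exactly how Asp/Asn become ``A`` and Trp becomes ``T`` in
    hand-curated spreadsheets.
    """
    try:
        return AA_THREE_TO_ONE[code3]
    except KeyError:
        raise ValueError(f"unknown three-letter amino-acid code: {code3!r}") from None


def aa_one_to_three(code1: str) -> str:
    """Convert a one-letter amino-acid code (or ``*``) to three-letter."""
    try:
        return AA_ONE_TO_THREE[code1]
    except KeyError:
        raise ValueError(f"unknown one-letter amino-acid code: {code1!r}") from None


# --- protein change ---------------------------------------------------------


@dataclass(frozen=True)
class ProteinChange:
    """Structured protein-level change parsed from an HGVS p. description."""

    ref_aa: str
    position: int
    kind: ChangeKind
    alt_aa: Optional[str] = None
    end_position: Optional[int] = None
    end_ref_aa: Optional[str] = None
    fs_ter: Optional[int] = None
    predicted: bool = True  # HGVS parentheses present

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("protein position must be >= 1")
        if self.end_position is not None and self.end_position < self.position:
            raise ValueError("end_position must be >= position")
        if (self.kind is ChangeKind.NONSENSE) != (self.alt_aa == "*"):
            raise ValueError("kind=nonsense iff alt_aa='*'")

    @property
    def span(self) -> tuple[int, int]:
        return (self.position, self.end_position or self.position)

    def shorthand(self) -> str:
        """One-letter shorthand (e.g. ``L858R``) used for hotspot lookup.

        Only substitutions and nonsense changes have a canonical shorthand;
        indels and frameshifts are matched structurally instead.
        """
        if self.kind not in (ChangeKind.SUBSTITUTION, ChangeKind.NONSENSE):
            raise ValueError(
                f"no one-letter shorthand for change kind {self.kind.value!r}"
            )
        return f"{self.ref_aa}{self.position}{self.alt_aa}"

    def render(self) -> str:
        """Render back to HGVS p. notation with three-letter codes."""
        r3 = aa_one_to_three(self.ref_aa)
        body: str
        if self.kind in (ChangeKind.SUBSTITUTION, ChangeKind.NONSENSE):
            body = f"{r3}{self.position}{aa_one_to_three(self.alt_aa)}"
        elif self.kind is ChangeKind.FRAMESHIFT:
            suffix = "fs" if self.fs_ter is None else f"fs*{self.fs_ter}"
            alt = aa_one_to_three(self.alt_aa) if self.alt_aa else ""
            body = f"{r3}{self.position}{alt}{suffix}"
        else:
            tag = {
                ChangeKind.INFRAME_DEL: "del",
                ChangeKind.INFRAME_INS: "ins",
                ChangeKind.INFRAME_DELINS: "delins",
                ChangeKind.DUPLICATION: "dup",
            }[self.kind]
            if self.end_position is not None:
                e3 = aa_one_to_three(self.end_ref_aa) if self.end_ref_aa else ""
                body = f"{r3}{self.position}_{e3}{self.end_position}{tag}"
            else:
                body = f"{r3}{self.position}{tag}"
        return f"p.({body})" if self.predicted else f"p.{body}"


_AA3 = "|".join(AA_THREE_TO_ONE)
_RE_SUB = re.compile(rf"^(?P<ref>{_AA3})(?P<pos>\d+)(?P<alt>{_AA3}|\*)$")
_RE_FS = re.compile(
    rf"^(?P<ref>{_AA3})(?P<pos>\d+)(?P<alt>{_AA3})?fs(?:\*(?P<ter>\d+|\?))?$"
)
_RE_RANGE = re.compile(
    rf"^(?P<ref>{_AA3})(?P<pos>\d+)(?:_(?P<eref>{_AA3})(?P<epos>\d+))?"
    r"(?P<tag>delins|del|ins|dup)(?P<ins>[A-Za-z]*)$"
)

_TAG_KIND = {
    "del": ChangeKind.INFRAME_DEL,
    "ins": ChangeKind.INFRAME_INS,
    "delins": ChangeKind.INFRAME_DELINS,
    "dup": ChangeKind.DUPLICATION,
}


def parse_protein_change(protein_hgvs: str) -> ProteinChange:
    """Parse an HGVS protein description into a :class:`ProteinChange`.

    Accepts three-letter codes with an optional ``p.`` prefix and optional
    enclosing parentheses (predicted consequence), e.g. ``p.(Leu858Arg)``,
    ``p.(Asn140Metfs*5)``, ``p.(Ser1870*)``, ``p.(Glu746_Ala750del)``.

    Raises
    ------
    HgvsParseError
        If the text does not match the supported grammar; the message names
        the offending token. The caller must never coerce a parse failure
        into a VUS classification.
    """
    text = protein_hgvs.strip()
    if not text:
        raise HgvsParseError("empty protein HGVS string")
    body = text
    if body.startswith("p."):
        body = body[2:]
    predicted = False
    if body.startswith("(") and body.endswith(")"):
        predicted = True
        body = body[1:-1]
    if not body:
        raise HgvsParseError(f"no change body in {protein_hgvs!r}")

    m = _RE_SUB.match(body)
    if m:
        ref1 = aa_three_to_one(m.group("ref"))
        alt_raw = m.group("alt")
        alt1 = "*" if alt_raw == "*" else aa_three_to_one(alt_raw)
        kind = ChangeKind.NONSENSE if alt1 == "*" else ChangeKind.SUBSTITUTION
        return ProteinChange(
            ref_aa=ref1, position=int(m.group("pos")), alt_aa=alt1,
            kind=kind, predicted=predicted,
        )

    m = _RE_FS.match(body)
    if m:
        ter = m.group("ter")
        return ProteinChange(
            ref_aa=aa_three_to_one(m.group("ref")),
            position=int(m.group("pos")),
            alt_aa=aa_three_to_one(m.group("alt")) if m.group("alt") else None,
            kind=ChangeKind.FRAMESHIFT,
            fs_ter=int(ter) if ter and ter != "?" else None,
            predicted=predicted,
        )

    m = _RE_RANGE.match(body)
    if m:
        epos = m.group("epos")
        return ProteinChange(
            ref_aa=aa_three_to_one(m.group("ref")),
            position=int(m.group("pos")),
            end_position=int(epos) if epos else None,
            end_ref_aa=aa_three_to_one(m.group("eref")) if m.group("eref") else None,
            kind=_TAG_KIND[m.group("tag")],
            predicted=predicted,
        )

    raise HgvsParseError(f"cannot parse protein HGVS token {body!r}")


def shorthand(change: ProteinChange) -> str:
    """Module-level convenience for :meth:`ProteinChange.shorthand`."""
    return change.shorthand()


# --- variant record ---------------------------------------------------------

_DNA_RE = re.compile(r"^[ACGTN]*$")


@dataclass
class VariantRecord:
    """One observed somatic call joined to its transcript-level annotation."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    depth: int
    gene: str
    transcript: str
    cdna_hgvs: str
    consequence: Consequence
    tumour_category: TumourCategory
    protein_hgvs: Optional[str] = None
    exon: Optional[int] = None
    tumour_type: str = ""
    _protein_change: Optional[ProteinChange] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0,1], got {self.vaf}")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if "." not in self.transcript:
            raise ValueError(
                f"transcript accession must carry a version suffix: {self.transcript!r}"
            )
        if self.ref and not _DNA_RE.match(self.ref):
            raise ValueError(f"ref is not a DNA string: {self.ref!r}")
        if self.alt and not _DNA_RE.match(self.alt):
            raise ValueError(f"alt is not a DNA string: {self.alt!r}")
        if self.exon is not None and self.exon < 1:
            raise ValueError("exon must be a positive integer")

    @property
    def key(self) -> str:
        """Variant key used for stores, evidence joins and blacklists."""
        return f"{self.gene}|{self.transcript}|{self.cdna_hgvs}"

    @property
    def protein_change(self) -> Optional[ProteinChange]:
        """Parsed protein change, or None when no p. description exists."""
        if self.protein_hgvs is None or self.protein_hgvs in {"", "."}:
            return None
        if self._protein_change is None:
            object.__setattr__(
                self, "_protein_change", parse_protein_change(self.protein_hgvs)
            )
        return self._protein_change
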