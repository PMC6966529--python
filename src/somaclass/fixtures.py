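"""Deterministic synthetic variant batches with construction-time truth labels.

Generates annotated calls, population snapshots, evidence bundles, lab config,
observation logs and override tables that exercise every branch of the
classification workflow, so the whole engine is testable without any database
download. The expected class of each case is fixed by the branch that built
it — never by running the engine — so engine-agreement tests cannot
self-confirm. The generator seeds every well-known worked example (the ALK
Pro1599His population case, the EGFR Ser768Ile / Leu858Arg / Leu747Pro trio,
KRAS Asp57Asn and Gly115*, TET2 Ser1870* and Thr822Pro, the type-I CALR
deletion, the ASXL1 c.1934dup stutter, ...) verbatim alongside randomized
cases whose VAF, depth and MAF are drawn uniformly inside branch-legal ranges.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .classifier import (
    RULE_BOX1_DROP,
    RULE_BOX2_POPULATION,
    RULE_BOX3_CPV,
    RULE_BOX4_ONCO_LOF,
    RULE_BOX4_TS_LOF,
    RULE_BOX5_SCORE,
    RULE_EXC_BRCA_DB,
    RULE_EXC_BRCA_LOF,
    RULE_EXC_CALR_EX9,
    RULE_EXC_CEBPA_BZIP,
    RULE_EXC_MET_EX14,
    RULE_EXC_NPM1_EX11,
    RULE_EXC_REGIONAL_BENIGN,
    RULE_EXC_TP53_DB,
    RULE_EXC_TP53_SPLICE,
    RULE_OVERRIDE,
)
from .config import LabConfig, SiteOverride
from .filters import ObservationLog
from .knowledge import (
    EvidenceBundle,
    FunctionalEvidence,
    GenomicDbVerdict,
    PopulationEntry,
    PopulationFrequencySnapshot,
    TriState,
)
from .model import BiologicalClass, Consequence, TumourCategory, VariantRecord


@dataclass(frozen=True)
class FixtureCase:
    record: VariantRecord
    snapshot: PopulationFrequencySnapshot
    evidence: EvidenceBundle
    expected_keep: bool
    expected_rule: str
    expected_class: Optional[BiologicalClass] = None
    expected_reason: Optional[str] = None  # filter reason for dropped cases
    expected_flags: frozenset[str] = frozenset()
    note: str = ""


@dataclass
class FixtureSpec:
    seed: int = 1
    n_per_branch: int = 8
    branches: Optional[list[str]] = None  # None = all


@dataclass
class FixtureBatch:
    cases: list[FixtureCase]
    config: LabConfig
    observation_log: ObservationLog
    overrides: list[dict]
    spec: FixtureSpec

    def write(self, out_dir: Union[str, Path]) -> None:
        write_batch_files(self, out_dir)


# --- variant templates ------------------------------------------------------


@dataclass(frozen=True)
class _Template:
    gene: str
    transcript: str
    cdna: str
    protein: Optional[str]
    consequence: Consequence
    category: TumourCategory
    exon: Optional[int] = None
    tumour_type: str = ""


_SOLID = TumourCategory.SOLID
_HEMATO = TumourCategory.HAEMATOLOGICAL

# well-known worked examples, transcribed with their published accessions
T_ALK_P1599H = _Template("ALK", "NM_004304.4", "c.4796C>A", "p.(Pro1599His)",
                         Consequence.MISSENSE, _SOLID, tumour_type="NSCLC")
T_BRAF_V600E = _Template("BRAF", "NM_004333.5", "c.1799T>A", "p.(Val600Glu)",
                         Consequence.MISSENSE, _SOLID, tumour_type="melanoma")
T_BRAF_V600M = _Template("BRAF", "NM_004333.5", "c.1798G>A", "p.(Val600Met)",
                         Consequence.MISSENSE, _SOLID)
T_BRAF_L597R = _Template("BRAF", "NM_004333.5", "c.1790T>G", "p.(Leu597Arg)",
                         Consequence.MISSENSE, _SOLID)
T_EGFR_L858R = _Template("EGFR", "NM_005228.4", "c.2573T>G", "p.(Leu858Arg)",
                         Consequence.MISSENSE, _SOLID, tumour_type="NSCLC")
T_EGFR_S768I = _Template("EGFR", "NM_005228.4", "c.2303G>T", "p.(Ser768Ile)",
                         Consequence.MISSENSE, _SOLID)
T_EGFR_L747P = _Template("EGFR", "NM_005228.4", "c.2239_2240delinsCC", "p.(Leu747Pro)",
                         Consequence.MISSENSE, _SOLID)
T_EGFR_EX19 = _Template("EGFR", "NM_005228.4", "c.2235_2249del", "p.(Glu746_Ala750del)",
                        Consequence.INFRAME_DELETION, _SOLID, exon=19)
T_KIT_DEL = _Template("KIT", "NM_000222.2", "c.1673_1681del", "p.(Lys558_Val560del)",
                      Consequence.INFRAME_DELETION, _SOLID, exon=11, tumour_type="GIST")
T_KRAS_D57N = _Template("KRAS", "NM_004985.4", "c.169G>A", "p.(Asp57Asn)",
                        Consequence.MISSENSE, _SOLID)
T_KRAS_G115X = _Template("KRAS", "NM_004985.4", "c.343G>T", "p.(Gly115*)",
                         Consequence.NONSENSE, _SOLID)
T_SF3B1_K666N = _Template("SF3B1", "NM_012433.3", "c.1998G>C", "p.(Lys666Asn)",
                          Consequence.MISSENSE, _HEMATO, tumour_type="MDS")
T_SF3B1_G740E = _Template("SF3B1", "NM_012433.3", "c.2219G>A", "p.(Gly740Glu)",
                          Consequence.MISSENSE, _HEMATO)
T_SRSF2_P107H = _Template("SRSF2", "NM_003016.4", "c.320C>A", "p.(Pro107His)",
                          Consequence.MISSENSE, _HEMATO)
T_JAK2_V617F = _Template("JAK2", "NM_004972.3", "c.1849G>T", "p.(Val617Phe)",
                         Consequence.MISSENSE, _HEMATO, tumour_type="MPN")
T_MPL_W515L = _Template("MPL", "NM_005373.2", "c.1544G>T", "p.(Trp515Leu)",
                        Consequence.MISSENSE, _HEMATO)
T_TET2_S1870X = _Template("TET2", "NM_001127208.2", "c.5609C>G", "p.(Ser1870*)",
                          Consequence.NONSENSE, _HEMATO)
T_TET2_T822P = _Template("TET2", "NM_001127208.2", "c.2464A>C", "p.(Thr822Pro)",
                         Consequence.MISSENSE, _HEMATO)
T_TP53_R175H = _Template("TP53", "NM_000546.5", "c.524G>A", "p.(Arg175His)",
                         Consequence.MISSENSE, _HEMATO)
T_TP53_S149FS = _Template("TP53", "NM_000546.5", "c.445dup", "p.(Ser149Phefs*32)",
                          Consequence.FRAMESHIFT, _HEMATO)
T_TP53_SPLICE = _Template("TP53", "NM_000546.5", "c.375+1G>A", None,
                          Consequence.SPLICE_CORE, _HEMATO, exon=4)
T_TP53_S241F = _Template("TP53", "NM_000546.5", "c.722C>T", "p.(Ser241Phe)",
                         Consequence.MISSENSE, _HEMATO)
T_BRCA2_NONSENSE = _Template("BRCA2", "NM_000059.3", "c.9382C>T", "p.(Arg3128*)",
                             Consequence.NONSENSE, _SOLID, tumour_type="ovarian")
T_BRCA1_R1699Q = _Template("BRCA1", "NM_007294.3", "c.5096G>A", "p.(Arg1699Gln)",
                           Consequence.MISSENSE, _SOLID, tumour_type="ovarian")
T_CALR_TYPE1 = _Template("CALR", "NM_004343.3", "c.1099_1150del", "p.(Leu367Thrfs*46)",
                         Consequence.FRAMESHIFT, _HEMATO, exon=9, tumour_type="ET")
T_NPM1_INS = _Template("NPM1", "NM_002520.6", "c.860_863dup", "p.(Trp288Cysfs*12)",
                       Consequence.FRAMESHIFT, _HEMATO, exon=11, tumour_type="AML")
T_CEBPA_BZIP = _Template("CEBPA", "NM_004364.3", "c.937_939dup", "p.(Lys313dup)",
                         Consequence.INFRAME_INSERTION, _HEMATO, tumour_type="AML")
T_MET_EX14 = _Template("MET", "NM_001127500.3", "c.3028+2T>C", None,
                       Consequence.SPLICE_CORE, _SOLID, exon=14, tumour_type="NSCLC")
T_ASXL1_DUP = _Template("ASXL1", "NM_015338.5", "c.1934dup", "p.(Gly646Trpfs*12)",
                        Consequence.FRAMESHIFT, _HEMATO, tumour_type="AML")
T_RUNX1_NONSENSE = _Template("RUNX1", "NM_001754.4", "c.601C>T", "p.(Arg201*)",
                             Consequence.NONSENSE, _HEMATO)
T_FGFR3_MAX = _Template("FGFR3", "NM_000142.4", "c.742C>T", "p.(Arg248Cys)",
                        Consequence.MISSENSE, _SOLID, tumour_type="bladder")
T_STAG2_LOF = _Template("STAG2", "NM_001042749.2", "c.2044C>T", "p.(Gln682*)",
                        Consequence.NONSENSE, _HEMATO)

ASXL1_STUTTER_KEY = "ASXL1|NM_015338.5|c.1934dup"


def _vaf(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.round(rng.uniform(lo, hi), 4))


def _depth(rng: np.random.Generator, lo: int = 501, hi: int = 3000) -> int:
    return int(rng.integers(lo, hi))


class _Builder:
    """Stateful helper assigning unique genomic sites and sample ids."""

    def __init__(self, rng: np.random.Generator) -> None:
        self.rng = rng
        self.counter = itertools.count()
        self._sites: dict[tuple[str, str], tuple[str, int, str, str]] = {}

    def sample(self) -> str:
        return f"S{next(self.counter):04d}"

    def site(self, template: _Template) -> tuple[str, int, str, str]:
        key = (template.gene, template.cdna)
        if key not in self._sites:
            n = len(self._sites)
            ref, alt = ("AGC", "A") if "del" in template.cdna else ("A", "T")
            self._sites[key] = (f"chr{1 + n % 22}", 10_000 + 13 * n, ref, alt)
        return self._sites[key]

    def record(
        self,
        template: _Template,
        vaf: float,
        depth: int,
    ) -> VariantRecord:
        chrom, pos, ref, alt = self.site(template)
        return VariantRecord(
            sample_id=self.sample(),
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            vaf=vaf,
            depth=depth,
            gene=template.gene,
            transcript=template.transcript,
            cdna_hgvs=template.cdna,
            protein_hgvs=template.protein,
            consequence=template.consequence,
            exon=template.exon,
            tumour_category=template.category,
            tumour_type=template.tumour_type,
        )


_EMPTY_SNAPSHOT = PopulationFrequencySnapshot()
_NO_EVIDENCE = EvidenceBundle()

# published population snapshot for ALK c.4796C>A: total MAF 0.02%,
# African MAF 0.25% over 24,968 interrogated alleles
ALK_SNAPSHOT = PopulationFrequencySnapshot(
    entries=(
        PopulationEntry("Total", 0.0002, 251_496),
        PopulationEntry("African", 0.0025, 24_968),
    ),
    dbsnp_listed=TriState.YES,
)

_EV = {
    "EGFR_S768I": EvidenceBundle(cosmic_count=265, sift_damaging=TriState.YES,
                                 mutationtaster_damaging=TriState.YES),
    "EGFR_L747P": EvidenceBundle(cosmic_count=62, sift_damaging=TriState.YES,
                                 mutationtaster_damaging=TriState.YES),
    "SF3B1_G740E": EvidenceBundle(cosmic_count=15),
    "BRAF_L597R": EvidenceBundle(cosmic_count=35),
    "SRSF2_P107H": EvidenceBundle(cosmic_count=7),
    "KRAS_D57N": EvidenceBundle(cosmic_count=7),
    "TET2_T822P": EvidenceBundle(cosmic_count=2),
    "TP53_S241F": EvidenceBundle(
        cosmic_count=40,
        tp53_iarc_class=BiologicalClass.PATHOGENIC,
        tp53_seshat_class=BiologicalClass.PATHOGENIC,
    ),
    "BRCA1_R1699Q": EvidenceBundle(
        brca_db_verdict=GenomicDbVerdict.LIKELY_PATHOGENIC_OR_PATHOGENIC
    ),
    "FGFR3_MAX": EvidenceBundle(
        cosmic_count=265,
        sift_damaging=TriState.YES,
        mutationtaster_damaging=TriState.YES,
        functional_evidence=FunctionalEvidence.HARMFUL,
        genomic_db_verdict=GenomicDbVerdict.LIKELY_PATHOGENIC_OR_PATHOGENIC,
    ),
}


def _branch_builders():
    """Map branch name → builder(b, rng, i) -> (FixtureCase, extras).

    ``extras`` may carry observation-log rows or override rows the branch
    needs to be classifiable as intended.
    """

    def case(record, snapshot, evidence, **kw):
        return FixtureCase(record=record, snapshot=snapshot, evidence=evidence, **kw)

    def box1_intronic(b, rng, i):
        t = _Template("KRAS", "NM_004985.4", f"c.450+{8 + i}T>C", None,
                      Consequence.INTRONIC, _SOLID)
        rec = b.record(t, _vaf(rng, 0.06, 0.38), _depth(rng))
        return case(rec, _EMPTY_SNAPSHOT, _NO_EVIDENCE, expected_keep=False,
                    expected_rule=RULE_BOX1_DROP, expected_reason="intronic",
                    note="deep intronic call outside AG/GT core sites"), {}

    def box1_synonymous(b, rng, i):
        t = _Template("EGFR", "NM_005228.4", f"c.{2361 + 3 * i}G>A", None,
                      Consequence.SYNONYMOUS, _SOLID)
        rec = b.record(t, _vaf(rng, 0.06, 0.38), _depth(rng))
        return case(rec, _EMPTY_SNAPSHOT, _NO_EVIDENCE, expected_keep=False,
                    expected_rule=RULE_BOX1_DROP, expected_reason="synonymous",
                    note="stand-alone synonymous change"), {}

    def box1_low_vaf(b, rng, i):
        rec = b.record(T_EGFR_L858R, _vaf(rng, 0.006, 0.045), _depth(rng))
        return case(rec, _EMPTY_SNAPSHOT, _NO_EVIDENCE, expected_keep=False,
                    expected_rule=RULE_BOX1_DROP, expected_reason="low_vaf",
                    note="hotspot below VAF gate; re-analysis suggested"), {}

    def box1_low_depth(b, rng, i):
        t = _Template("NRAS", "NM_002524.4", f"c.{290 + i}A>G",
                      f"p.(Tyr{97 + i}Cys)", Consequence.MISSENSE, _SOLID)
        rec = b.record(t, _vaf(rng, 0.06, 0.38), _depth(rng, 50, 400))
        return case(rec, _EMPTY_SNAPSHOT, _NO_EVIDENCE, expected_keep=False,
                    expected_rule=RULE_BOX1_DROP, expected_reason="low_depth"), {}

    def box1_blacklist(b, rng, i):
        t = _Template("NOTCH1", "NM_017617.5", f"c.{4600 + i}G>A",
                      f"p.(Ala{1534 + i}Thr)", Consequence.MISSENSE, _HEMATO)
        rec = b.record(t, _vaf(rng, 0.06, 0.38), _depth(rng))
        return case(rec, _EMPTY_SNAPSHOT, _NO_EVIDENCE, expected_keep=False,
                    expected_rule=RULE_BOX1_DROP, expected_reason="recurrent_artifact",
                    note="lab recurrence blacklist"), {"blacklist": [rec.key]}

    def box1_stutter(b, rng, i):
        rec = b.record(T_ASXL1_DUP, _vaf(rng, 0.006, 0.09), _depth(rng))
        return case(rec, _EMPTY_SNAPSHOT, _NO_EVIDENCE, expected_keep=False,
                    expected_rule=RULE_BOX1_DROP, expected_reason="str_stutter",
                    note="homopolymer stutter below validated threshold"), {}

    def box2_likely_benign(b, rng, i):
        if i == 0:
            rec = b.record(T_ALK_P1599H, 0.49, 1850)
            return case(rec, ALK_SNAPSHOT, _NO_EVIDENCE, expected_keep=True,
                        expected_rule=RULE_BOX2_POPULATION,
                        expected_class=BiologicalClass.LIKELY_BENIGN,
                        note="published ALK Pro1599His African-population case"), {}
        t = _Template("ALK", "NM_004304.4", f"c.{3100 + i}C>T",
                      f"p.(Pro{1034 + i}Ser)", Consequence.MISSENSE, _SOLID)
        snap = PopulationFrequencySnapshot(
            entries=(
                PopulationEntry("European",
                                float(np.round(rng.uniform(0.0012, 0.009), 5)),
                                int(rng.integers(2001, 200_000))),
            ),
            dbsnp_listed=TriState.YES,
        )
        rec = b.record(t, _vaf(rng, 0.06, 0.38), _depth(rng))
        return case(rec, snap, _NO_EVIDENCE, expected_keep=True,
                    expected_rule=RULE_BOX2_POPULATION,
                    expected_class=BiologicalClass.LIKELY_BENIGN), {}

    def box2_benign(b, rng, i):
        t = _Template("TET2", "NM_001127208.2", f"c.{100 + i}C>G",
                      f"p.(Pro{34 + i}Ala)", Consequence.MISSENSE, _HEMATO)
        snap = PopulationFrequencySnapshot(
            entries=(
                PopulationEntry("East Asian",
                                float(np.round(rng.uniform(0.011, 0.2), 5)),
                                int(rng.integers(2001, 200_000))),
            ),
            dbsnp_listed=TriState.YES,
        )
        rec = b.record(t, _vaf(rng, 0.40, 0.60), _depth(rng))
        return case(rec, snap, _NO_EVIDENCE, expected_keep=True,
                    expected_rule=RULE_BOX2_POPULATION,
                    expected_class=BiologicalClass.BENIGN), {}

    def germline_suspect_flag(b, rng, i):
        t = _Template("DNMT3A", "NM_175629.2", f"c.{955 + i}G>A",
                      f"p.(Ala{319 + i}Thr)", Consequence.MISSENSE, _HEMATO)
        snap = PopulationFrequencySnapshot(dbsnp_listed=TriState.YES)
        rec = b.record(t, _vaf(rng, 0.41, 0.59), _depth(rng))
        return case(rec, snap, _NO_EVIDENCE, expected_keep=True,
                    expected_rule=RULE_BOX5_SCORE,
                    expected_class=BiologicalClass.VUS,
                    expected_flags=frozenset({"germline_suspect"}),
                    note="frequency-database-negative call at heterozygous VAF"), {}

    def exc_tp53_splice(b, rng, i):
        rec = b.record(T_TP53_SPLICE, _vaf(rng, 0.06, 0.38), _depth(rng))
        return case(rec, _EMPTY_SNAPSHOT, _NO_EVIDENCE, expected_keep=True,
                    expected_rule=RULE_EXC_TP53_SPLICE,
                    expected_class=BiologicalClass.LIKELY_PATHOGENIC), {}

    def exc_tp53_db(b, rng, i):
        rec = b.record(T_TP53_S241F, _vaf(rng, 0.06, 0.38), _depth(rng))
        return case(rec, _EMPTY_SNAPSHOT, _EV["TP53_S241F"], expected_keep=True,
                    expected_rule=RULE_EXC_TP53_DB,
                    expected_class=BiologicalClass.PATHOGENIC,
                    note="concordant dedicated-database consensus"), {}

    def exc_brca_lof(b, rng, i):
        rec = b.record(T_BRCA2_NONSENSE, _vaf(rng, 0.06, 0.38), _depth(rng))
        return case(rec, _EMPTY_SNAPSHOT, _NO_EVIDENCE, expected_keep=True,
                    expected_rule=RULE_EXC_BRCA_LOF,
                    expected_class=BiologicalClass.PATHOGENIC), {}

    def exc_brca_db(b, rng, i):
        rec = b.record(T_BRCA1_R1699Q, _vaf(rng, 0.06, 0.38), _depth(rng))
        return case(rec, _EMPTY_SNAPSHOT, _EV["BRCA1_R1699Q"], expected_keep=True,
                    expected_rule=RULE_EXC_BRCA_DB,
                    expected_class=BiologicalClass.LIKELY_PATHOGENIC), {}

    def exc_calr(b, rng, i):
        rec = b.record(T_CALR_TYPE1, _vaf(rng, 0.06, 0.38), _depth(rng))
        return case(rec, _EMPTY_SNAPSHOT, _NO_EVIDENCE, expected_keep=True,
                    expected_rule=RULE_EXC_CALR_EX9,
                    expected_class=BiologicalClass.PATHOGENIC,
                    note="type I 52-bp out-of-frame deletion in exon 9"), {}

    def exc_npm1(b, rng, i):
        rec = b.record(T_NPM1_INS, _vaf(rng, 0.06, 0.38), _depth(rng))
        return case(rec, _EMPTY_SNAPSHOT, _NO_EVIDENCE, expected_keep=True,
                    expected_rule=RULE_EXC_NPM1_EX11,
                    expected_class=BiologicalClass.PATHOGENIC), {}

    def exc_cebpa(b, rng, i):
        rec = b.record(T_CEBPA_BZIP, _vaf(rng, 0.06, 0.38), _depth(rng))
        return case(rec, _EMPTY_SNAPSHOT, _NO_EVIDENCE, expected_keep=True,
                    expected_rule=RULE_EXC_CEBPA_BZIP,
                    expected_class=BiologicalClass.LIKELY_PATHOGENIC), {}

    def exc_met(b, rng, i):
        rec = b.record(T_MET_EX14, _vaf(rng, 0.06, 0.38), _depth(rng))
        return case(rec, _EMPTY_SNAPSHOT, _NO_EVIDENCE, expected_keep=True,
                    expected_rule=RULE_EXC_MET_EX14,
                    expected_class=BiologicalClass.PATHOGENIC), {}

    def exc_regional_benign(b, rng, i):
        t = _Template("SETBP1", "NM_015559.3", f"c.{2500 + i}G>A",
                      f"p.(Gly{834 + i}Ser)", Consequence.MISSENSE, _HEMATO)
        rec = b.record(t, _vaf(rng, 0.44, 0.56), _depth(rng))
        obs = [
            {"variant_key": rec.key, "sample_id": f"H{i:02d}{j}",
             "vaf": f"{rng.uniform(0.44, 0.56):.3f}", "date": "2019-06-01"}
            for j in range(int(rng.integers(3, 6)))
        ]
        return case(rec, _EMPTY_SNAPSHOT, _NO_EVIDENCE, expected_keep=True,
                    expected_rule=RULE_EXC_REGIONAL_BENIGN,
                    expected_class=BiologicalClass.LIKELY_BENIGN,
                    expected_flags=frozenset({"regional_benign_candidate"}),
                    note="recurrent regional germline variant"), {"observations": obs}

    def box3_cpv(b, rng, i):
        templates = [T_EGFR_L858R, T_BRAF_V600M, T_SF3B1_K666N, T_JAK2_V617F,
                     T_MPL_W515L, T_TP53_R175H]
        t = templates[i % len(templates)]
        rec = b.record(t, _vaf(rng, 0.06, 0.38), _depth(rng))
        return case(rec, _EMPTY_SNAPSHOT, _NO_EVIDENCE, expected_keep=True,
                    expected_rule=RULE_BOX3_CPV,
                    expected_class=BiologicalClass.PATHOGENIC), {}

    def box3_cpv_low_vaf_override(b, rng, i):
        rec = b.record(T_BRAF_V600E, float(np.round(rng.uniform(0.012, 0.045), 4)),
                       _depth(rng))
        return case(rec, _EMPTY_SNAPSHOT, _NO_EVIDENCE, expected_keep=True,
                    expected_rule=RULE_BOX3_CPV,
                    expected_class=BiologicalClass.PATHOGENIC,
                    note="validated low-VAF site override"), {}

    def box3_cpv_region(b, rng, i):
        t = T_KIT_DEL if i % 2 == 0 else T_EGFR_EX19
        rec = b.record(t, _vaf(rng, 0.06, 0.38), _depth(rng))
        return case(rec, _EMPTY_SNAPSHOT, _NO_EVIDENCE, expected_keep=True,
                    expected_rule=RULE_BOX3_CPV,
                    expected_class=BiologicalClass.PATHOGENIC), {}

    def box4_ts_lof(b, rng, i):
        templates = [T_TET2_S1870X, T_RUNX1_NONSENSE, T_ASXL1_DUP]
        t = templates[i % len(templates)]
        lo, hi = (0.15, 0.38) if t is T_ASXL1_DUP else (0.06, 0.38)
        rec = b.record(t, _vaf(rng, lo, hi), _depth(rng))
        return case(rec, _EMPTY_SNAPSHOT, _NO_EVIDENCE, expected_keep=True,
                    expected_rule=RULE_BOX4_TS_LOF,
                    expected_class=BiologicalClass.LIKELY_PATHOGENIC), {}

    def box4_ts_lof_tp53(b, rng, i):
        rec = b.record(T_TP53_S149FS, _vaf(rng, 0.06, 0.38), _depth(rng))
        return case(rec, _EMPTY_SNAPSHOT, _NO_EVIDENCE, expected_keep=True,
                    expected_rule=RULE_BOX4_TS_LOF,
                    expected_class=BiologicalClass.LIKELY_PATHOGENIC,
                    expected_flags=frozenset({"manual_review"}),
                    note="TP53 frameshift without database consensus"), {}

    def box4_onco_lof(b, rng, i):
        rec = b.record(T_KRAS_G115X, _vaf(rng, 0.06, 0.38), _depth(rng))
        return case(rec, _EMPTY_SNAPSHOT, _NO_EVIDENCE, expected_keep=True,
                    expected_rule=RULE_BOX4_ONCO_LOF,
                    expected_class=BiologicalClass.VUS), {}

    def box4_unknown_role(b, rng, i):
        rec = b.record(T_STAG2_LOF, _vaf(rng, 0.06, 0.38), _depth(rng))
        return case(rec, _EMPTY_SNAPSHOT, _NO_EVIDENCE, expected_keep=True,
                    expected_rule=RULE_BOX5_SCORE,
                    expected_class=BiologicalClass.VUS,
                    expected_flags=frozenset({"manual_review"}),
                    note="clear LoF in gene of uncurated role"), {}

    def box5_lp(b, rng, i):
        pairs = [(T_EGFR_S768I, "EGFR_S768I"), (T_SF3B1_G740E, "SF3B1_G740E"),
                 (T_EGFR_L747P, "EGFR_L747P")]
        t, ev = pairs[i % len(pairs)]
        rec = b.record(t, _vaf(rng, 0.06, 0.38), _depth(rng))
        return case(rec, _EMPTY_SNAPSHOT, _EV[ev], expected_keep=True,
                    expected_rule=RULE_BOX5_SCORE,
                    expected_class=BiologicalClass.LIKELY_PATHOGENIC), {}

    def box5_vus(b, rng, i):
        pairs = [(T_KRAS_D57N, "KRAS_D57N"), (T_TET2_T822P, "TET2_T822P"),
                 (T_BRAF_L597R, "BRAF_L597R"), (T_SRSF2_P107H, "SRSF2_P107H")]
        t, ev = pairs[i % len(pairs)]
        rec = b.record(t, _vaf(rng, 0.06, 0.38), _depth(rng))
        return case(rec, _EMPTY_SNAPSHOT, _EV[ev], expected_keep=True,
                    expected_rule=RULE_BOX5_SCORE,
                    expected_class=BiologicalClass.VUS), {}

    def box5_pathogenic_max(b, rng, i):
        rec = b.record(T_FGFR3_MAX, _vaf(rng, 0.06, 0.38), _depth(rng))
        return case(rec, _EMPTY_SNAPSHOT, _EV["FGFR3_MAX"], expected_keep=True,
                    expected_rule=RULE_BOX5_SCORE,
                    expected_class=BiologicalClass.PATHOGENIC,
                    note="maximal score in a gene outside the hotspot lists"), {}

    def box5_override(b, rng, i):
        t = _Template("TET2", "NM_001127208.2", f"c.{3000 + i}A>C",
                      f"p.(Thr{1000 + i}Pro)", Consequence.MISSENSE, _HEMATO)
        rec = b.record(t, _vaf(rng, 0.06, 0.38), _depth(rng))
        override = {
            "gene": t.gene, "cdna_hgvs": t.cdna,
            "new_class": "Likely Pathogenic",
            "justification": "recent functional study demonstrates loss of catalytic activity",
            "source": "expert panel curation",
        }
        return case(rec, _EMPTY_SNAPSHOT, EvidenceBundle(cosmic_count=2),
                    expected_keep=True, expected_rule=RULE_OVERRIDE,
                    expected_class=BiologicalClass.LIKELY_PATHOGENIC,
                    expected_flags=frozenset({"overruled"})), {"overrides": [override]}

    return {
        "box1_intronic": box1_intronic,
        "box1_synonymous": box1_synonymous,
        "box1_low_vaf": box1_low_vaf,
        "box1_low_depth": box1_low_depth,
        "box1_blacklist": box1_blacklist,
        "box1_stutter": box1_stutter,
        "box2_likely_benign": box2_likely_benign,
        "box2_benign": box2_benign,
        "germline_suspect_flag": germline_suspect_flag,
        "exc_tp53_splice": exc_tp53_splice,
        "exc_tp53_db": exc_tp53_db,
        "exc_brca_lof": exc_brca_lof,
        "exc_brca_db": exc_brca_db,
        "exc_calr": exc_calr,
        "exc_npm1": exc_npm1,
        "exc_cebpa": exc_cebpa,
        "exc_met": exc_met,
        "exc_regional_benign": exc_regional_benign,
        "box3_cpv": box3_cpv,
        "box3_cpv_low_vaf_override": box3_cpv_low_vaf_override,
        "box3_cpv_region": box3_cpv_region,
        "box4_ts_lof": box4_ts_lof,
        "box4_ts_lof_tp53": box4_ts_lof_tp53,
        "box4_onco_lof": box4_onco_lof,
        "box4_unknown_role": box4_unknown_role,
        "box5_lp": box5_lp,
        "box5_vus": box5_vus,
        "box5_pathogenic_max": box5_pathogenic_max,
        "box5_override": box5_override,
    }


ALL_BRANCHES = tuple(_branch_builders().keys())


def generate_fixtures(spec: FixtureSpec) -> FixtureBatch:
    """Generate a reproducible fixture batch; same spec → identical output."""
    rng = np.random.default_rng(spec.seed)
    builders = _branch_builders()
    names = spec.branches or list(builders)
    unknown = set(names) - set(builders)
    if unknown:
        raise ValueError(f"unknown fixture branches: {sorted(unknown)}")

    b = _Builder(rng)
    cases: list[FixtureCase] = []
    blacklist: list[str] = []
    observations: list[dict] = []
    overrides: list[dict] = []
    for name in names:
        for i in range(spec.n_per_branch):
            fixture, extras = builders[name](b, rng, i)
            cases.append(fixture)
            blacklist.extend(extras.get("blacklist", []))
            observations.extend(extras.get("observations", []))
            overrides.extend(extras.get("overrides", []))

    config = LabConfig(
        site_overrides=[SiteOverride(gene="BRAF", change="c.1799T>A", vaf_min=0.01)],
        recurrence_blacklist=frozenset(blacklist),
        str_stutter_thresholds={ASXL1_STUTTER_KEY: 0.10},
    )
    obs_map: dict[str, list[tuple[str, float]]] = {}
    for row in observations:
        obs_map.setdefault(row["variant_key"], []).append(
            (row["sample_id"], float(row["vaf"]))
        )
    return FixtureBatch(
        cases=cases,
        config=config,
        observation_log=ObservationLog(observations=obs_map),
        overrides=overrides,
        spec=spec,
    )


def write_batch_files(batch: FixtureBatch, out_dir: Union[str, Path]) -> None:
    """Write the batch in the flat-file formats the engine reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    calls, annos, pop_rows, ev_rows, truth = [], {}, {}, {}, []
    for case_ in batch.cases:
        r = case_.record
        calls.append(
            {"sample_id": r.sample_id, "chrom": r.chrom, "pos": r.pos,
             "ref": r.ref, "alt": r.alt, "vaf": f"{r.vaf:.4f}", "depth": r.depth}
        )
        annos[(r.chrom, r.pos)] = {
            "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
            "gene": r.gene, "transcript": r.transcript, "cdna_hgvs": r.cdna_hgvs,
            "protein_hgvs": r.protein_hgvs or ".",
            "consequence": r.consequence.value,
            "exon": r.exon if r.exon is not None else ".",
            "tumour_category": r.tumour_category.value,
            "tumour_type": r.tumour_type,
        }
        key = (r.gene, r.cdna_hgvs)
        snap = case_.snapshot
        if key not in pop_rows and (snap.entries or snap.dbsnp_listed is not TriState.UNKNOWN):
            rows = []
            if snap.entries:
                for e in snap.entries:
                    rows.append(
                        {"gene": r.gene, "cdna_hgvs": r.cdna_hgvs,
                         "population": e.population, "maf": repr(e.maf),
                         "allele_number": e.allele_number,
                         "dbsnp_listed": snap.dbsnp_listed.value}
                    )
            else:
                rows.append(
                    {"gene": r.gene, "cdna_hgvs": r.cdna_hgvs, "population": ".",
                     "maf": "0", "allele_number": "0",
                     "dbsnp_listed": snap.dbsnp_listed.value}
                )
            pop_rows[key] = rows
        ev = case_.evidence
        if key not in ev_rows and ev != _NO_EVIDENCE:
            ev_rows[key] = {
                "gene": r.gene, "cdna_hgvs": r.cdna_hgvs,
                "cosmic_count": "." if ev.cosmic_count is None else ev.cosmic_count,
                "sift_damaging": ev.sift_damaging.value,
                "mutationtaster_damaging": ev.mutationtaster_damaging.value,
                "functional_evidence": ev.functional_evidence.value,
                "genomic_db_verdict": ev.genomic_db_verdict.value,
                "tp53_iarc_class": ev.tp53_iarc_class.value if ev.tp53_iarc_class else ".",
                "tp53_seshat_class": ev.tp53_seshat_class.value if ev.tp53_seshat_class else ".",
                "brca_db_verdict": ev.brca_db_verdict.value if ev.brca_db_verdict else ".",
            }
        truth.append(
            {"sample_id": r.sample_id, "variant_key": r.key,
             "expected_keep": str(case_.expected_keep).lower(),
             "expected_reason": case_.expected_reason or ".",
             "expected_class": case_.expected_class.value if case_.expected_class else ".",
             "expected_rule": case_.expected_rule,
             "expected_flags": ",".join(sorted(case_.expected_flags)) or ".",
             "note": case_.note}
        )

    pd.DataFrame(calls).to_csv(out / "calls.tsv", sep="\t", index=False)
    pd.DataFrame(list(annos.values())).to_csv(out / "annotations.tsv", sep="\t", index=False)
    pop_flat = [row for rows in pop_rows.values() for row in rows]
    pd.DataFrame(
        pop_flat,
        columns=["gene", "cdna_hgvs", "population", "maf", "allele_number", "dbsnp_listed"],
    ).to_csv(out / "popfreq.tsv", sep="\t", index=False)
    pd.DataFrame(
        list(ev_rows.values()),
        columns=["gene", "cdna_hgvs", "cosmic_count", "sift_damaging",
                 "mutationtaster_damaging", "functional_evidence",
                 "genomic_db_verdict", "tp53_iarc_class", "tp53_seshat_class",
                 "brca_db_verdict"],
    ).to_csv(out / "evidence.tsv", sep="\t", index=False)
    pd.DataFrame(truth).to_csv(out / "truth.tsv", sep="\t", index=False)
    obs_rows = [
        {"variant_key": key, "sample_id": sample, "vaf": f"{vaf:.3f}", "date": "2019-06-01"}
        for key, pairs in sorted(batch.observation_log.observations.items())
        for sample, vaf in pairs
    ]
    pd.DataFrame(
        obs_rows, columns=["variant_key", "sample_id", "vaf", "date"]
    ).to_csv(out / "observations.tsv", sep="\t", index=False)
    pd.DataFrame(
        batch.overrides,
        columns=["gene", "cdna_hgvs", "new_class", "justification", "source"],
    ).to_csv(out / "overrides.tsv", sep="\t", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(batch.config.to_dict(), fh, sort_keys=True)


# --- scoring grid oracle ----------------------------------------------------


def enumerate_scoring_grid() -> pd.DataFrame:
    """Exhaustive closure of the four-parameter scoring table.

    108 rows: both tumour categories × 3 COSMIC bands × 2 in-silico ×
    3 functional × 3 genomic-database outcomes, each with a representative
    COSMIC entry count, the arithmetic total and the class the published
    rule implies. Kept deliberately independent of the scoring code so it
    can serve as a brute-force oracle in tests.
    """
    cosmic_examples = {
        "solid": {2: 265, 1: 35, 0: 7},
        "haematological": {2: 15, 1: 7, 0: 2},
    }
    rows = []
    for category in ("solid", "haematological"):
        for c in (2, 1, 0):
            for ins in (0.5, 0):
                for fn in (0.5, 0, -1):
                    for db in (0.5, 0, -1):
                        total = c + ins + fn + db
                        rows.append(
                            {
                                "tumour_category": category,
                                "cosmic_count_example": cosmic_examples[category][c],
                                "cosmic_score": c,
                                "insilico_score": ins,
                                "functional_score": fn,
                                "genomicdb_score": db,
                                "total": total,
                                "class": "Likely Pathogenic" if total >= 2 else "VUS",
                            }
                        )
    return pd.DataFrame(rows)
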