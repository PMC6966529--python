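"""Technical filtering and population-frequency classification.

The first two stages of the workflow: discard calls that cannot be interpreted
(intronic outside the AG/GT core splice sites, stand-alone synonymous changes,
sub-threshold VAF/depth, recurrent artefacts, short-tandem-repeat stutter) and
assign (Likely) Benign to variants common in an ethnic population of a
frequency database. Variants that survive both continue to hotspot matching,
loss-of-function routing and evidence scoring.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .config import LabConfig
from .knowledge import PopulationFrequencySnapshot, TriState
from .model import BiologicalClass, Consequence, SomaclassError, VariantRecord


class FilterReason(enum.Enum):
    PASS = "pass"
    TECHNICAL_ARTIFACT = "technical_artifact"
    RECURRENT_ARTIFACT = "recurrent_artifact"
    INTRONIC = "intronic"
    SYNONYMOUS = "synonymous"
    LOW_VAF = "low_vaf"
    LOW_DEPTH = "low_depth"
    STR_STUTTER = "str_stutter"


@dataclass(frozen=True)
class FilterDecision:
    keep: bool
    reason: FilterReason
    detail: str = ""

    def __post_init__(self) -> None:
        if self.keep != (self.reason is FilterReason.PASS):
            raise ValueError("keep=True iff reason=pass")


def technical_filter(
    record: VariantRecord,
    config: LabConfig,
    cpv_listed: bool = False,
    run_recurrence: Optional[Mapping[str, float]] = None,
    suppress_synonymous_drop: bool = False,
) -> FilterDecision:
    """Quality gate for one call.

    Checks, in order: recurrence blacklist / per-run recurrence matrix
    (hotspot-listed variants are exempt), STR stutter thresholds, consequence
    class (intronic outside core splice sites, stand-alone synonymous), then
    the VAF and depth gates after applying any validated site override.

    ``suppress_synonymous_drop`` keeps synonymous calls flowing for genes
    whose synonymous changes must still be database-checked (TP53).

    Raises on a missing VAF or depth: the quality gates are mandatory.
    """
    if record.vaf is None or record.depth is None:  # defensive; model validates
        raise SomaclassError("record without vaf/depth cannot be filtered")

    key = record.key
    if not cpv_listed:
        if key in config.recurrence_blacklist:
            return FilterDecision(False, FilterReason.RECURRENT_ARTIFACT,
                                  "on lab recurrence blacklist")
        if run_recurrence is not None:
            frac = run_recurrence.get(key, 0.0)
            if frac >= config.recurrence_fraction:
                return FilterDecision(
                    False, FilterReason.RECURRENT_ARTIFACT,
                    f"seen in {frac:.0%} of run samples (≥{config.recurrence_fraction:.0%})",
                )

    stutter = config.str_stutter_thresholds.get(key)
    if stutter is not None and record.vaf <= stutter:
        return FilterDecision(
            False, FilterReason.STR_STUTTER,
            f"VAF {record.vaf:.3f} ≤ site stutter threshold {stutter:.3f}",
        )

    if record.consequence is Consequence.INTRONIC:
        return FilterDecision(False, FilterReason.INTRONIC,
                              "intronic outside AG/GT core splice sites")
    if record.consequence is Consequence.SYNONYMOUS and not suppress_synonymous_drop:
        return FilterDecision(False, FilterReason.SYNONYMOUS,
                              "stand-alone synonymous change")

    changes = [record.cdna_hgvs]
    change = record.protein_change
    if change is not None and change.kind.value in {"substitution", "nonsense"}:
        changes.append(change.shorthand())
    vaf_min, depth_min = config.gates_for(record.gene, changes)
    if record.vaf < vaf_min:
        return FilterDecision(False, FilterReason.LOW_VAF,
                              f"VAF {record.vaf:.3f} < {vaf_min:.3f}")
    if record.depth < depth_min:
        return FilterDecision(False, FilterReason.LOW_DEPTH,
                              f"depth {record.depth} < {depth_min}")
    return FilterDecision(True, FilterReason.PASS)


def population_classify(
    snapshot: PopulationFrequencySnapshot, config: LabConfig
) -> Optional[BiologicalClass]:
    """(Likely) Benign call from ethnic-stratified population frequencies.

    Only populations with at least ``min_allele_number`` interrogated alleles
    are eligible. With m the maximum eligible MAF: m ≥ 1% → Benign;
    0.1% < m < 1% → Likely Benign; otherwise None and the variant continues
    through the workflow. The 0.1% bound is strict — a MAF of exactly 0.1%
    does not qualify.
    """
    m = snapshot.eligible_max_maf(config.min_allele_number)
    if m is None:
        return None
    if m >= config.maf_benign:
        return BiologicalClass.BENIGN
    if m > config.maf_likely_benign:
        return BiologicalClass.LIKELY_BENIGN
    return None


def germline_suspect(
    record: VariantRecord,
    snapshot: PopulationFrequencySnapshot,
    config: LabConfig,
) -> bool:
    """Flag population-database-negative calls that look germline.

    True when the VAF sits in a germline band (heterozygous ~50% or
    homozygous ~100%) and the variant is not positively absent from dbSNP.
    A flag only — it never changes the biological class by itself.
    """
    return config.in_germline_band(record.vaf) and snapshot.dbsnp_listed is not TriState.NO


@dataclass
class ObservationLog:
    """Lab history of (sample, VAF) observations per variant key."""

    observations: dict[str, list[tuple[str, float]]]

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ObservationLog":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        obs: dict[str, list[tuple[str, float]]] = {}
        for _, row in df.iterrows():
            obs.setdefault(row["variant_key"], []).append(
                (row["sample_id"], float(row["vaf"]))
            )
        return cls(observations=obs)

    def samples_in_band(self, variant_key: str, band: tuple[float, float]) -> int:
        lo, hi = band
        seen = {
            sample
            for sample, vaf in self.observations.get(variant_key, [])
            if lo <= vaf <= hi
        }
        return len(seen)


def regional_benign_check(
    variant_key: str,
    observation_log: Optional[ObservationLog],
    config: LabConfig,
) -> bool:
    """Detect population-specific very rare benign variants from lab history.

    True when the variant was seen in at least ``regional_benign_min_samples``
    distinct samples at heterozygous-germline VAFs (~50%), irrespective of
    tumour content or type; the engine then assigns Likely Benign with a
    follow-up flag.
    """
    if observation_log is None:
        return False
    n = observation_log.samples_in_band(variant_key, config.germline_het_band)
    return n >= config.regional_benign_min_samples


def compute_run_recurrence(records: Iterable[VariantRecord]) -> dict[str, float]:
    """Per-run fraction of samples carrying each variant key."""
    records = list(records)
    samples = {r.sample_id for r in records}
    if not samples:
        return {}
    carriers: dict[str, set[str]] = {}
    for r in records:
        carriers.setdefault(r.key, set()).add(r.sample_id)
    return {key: len(s) / len(samples) for key, s in carriers.items()}
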