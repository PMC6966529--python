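"""End-to-end orchestration of the classification workflow over batches.

Pipeline order per record: technical filter → population-frequency check
(with germline-suspect flagging) → gene-specific exceptions → consensus
hotspot (CPV) → clear-LoF routing by gene role → evidence scoring table.
The first stage that produces a class terminates the pipeline; a full rule
trail is always emitted so each call is auditable down to the threshold
values used.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from .classifier import (
    RULE_BOX1_DROP,
    RULE_BOX2_POPULATION,
    RULE_BOX3_CPV,
    RULE_BOX4_ONCO_LOF,
    RULE_BOX4_TS_LOF,
    RULE_BOX5_SCORE,
    RULE_OVERRIDE,
    ClassificationResult,
    OverrideRecord,
    TrailEntry,
    apply_exceptions,
    classify_cpv,
    classify_lof,
    is_clear_lof,
    score_variant,
    scoring_class,
)
from .config import LabConfig
from .filters import (
    FilterDecision,
    FilterReason,
    ObservationLog,
    compute_run_recurrence,
    germline_suspect,
    population_classify,
    technical_filter,
)
from .knowledge import (
    EvidenceBundle,
    GeneRoleKind,
    KnowledgeBase,
    PopulationFrequencySnapshot,
    load_evidence_table,
    load_population_table,
)
from .model import (
    BiologicalClass,
    Consequence,
    SomaclassError,
    TumourCategory,
    VariantRecord,
)


def classify_record(
    record: VariantRecord,
    snapshot: PopulationFrequencySnapshot,
    evidence: EvidenceBundle,
    kb: KnowledgeBase,
    config: LabConfig,
    observation_log: Optional[ObservationLog] = None,
    override: Optional[OverrideRecord] = None,
    run_recurrence: Optional[Mapping[str, float]] = None,
) -> tuple[Optional[ClassificationResult], FilterDecision]:
    """Classify one joined record; returns (result, filter_decision).

    ``result`` is None when the record is dropped by the technical filter;
    the decision tells why, and the engine surfaces a re-analysis suggestion
    for sub-threshold candidates that would otherwise have been (Likely)
    Pathogenic.
    """
    trail: list[TrailEntry] = []
    flags: set[str] = set()

    cpv_hit = classify_cpv(record, kb)
    decision = technical_filter(
        record,
        config,
        cpv_listed=cpv_hit is not None,
        run_recurrence=run_recurrence,
        suppress_synonymous_drop=record.gene == "TP53",
    )
    trail.append(
        TrailEntry(RULE_BOX1_DROP, "pass" if decision.keep else decision.reason.value,
                   decision.detail)
    )
    if not decision.keep:
        return None, decision

    pop_class = population_classify(snapshot, config)
    if pop_class is not None:
        m = snapshot.eligible_max_maf(config.min_allele_number)
        trail.append(
            TrailEntry(RULE_BOX2_POPULATION, pop_class.value,
                       f"max eligible ethnic MAF {m:.4%}")
        )
        return (
            ClassificationResult(pop_class, trail, RULE_BOX2_POPULATION, flags=flags),
            decision,
        )
    trail.append(TrailEntry(RULE_BOX2_POPULATION, "none", "no eligible MAF above 0.1%"))
    if germline_suspect(record, snapshot, config):
        flags.add("germline_suspect")

    exc = apply_exceptions(record, evidence, kb, config, observation_log)
    if exc is not None:
        flags |= exc.flags
        trail.append(
            TrailEntry(
                exc.rule_id,
                exc.biological_class.value if exc.biological_class else "fall-through",
                exc.detail,
            )
        )
        if exc.biological_class is not None:
            return (
                ClassificationResult(
                    exc.biological_class, trail, exc.rule_id, flags=flags
                ),
                decision,
            )

    if cpv_hit is not None:
        trail.append(
            TrailEntry(RULE_BOX3_CPV, BiologicalClass.PATHOGENIC.value,
                       f"matched consensus hotspot: {cpv_hit.label}")
        )
        return (
            ClassificationResult(
                BiologicalClass.PATHOGENIC, trail, RULE_BOX3_CPV, flags=flags
            ),
            decision,
        )
    trail.append(TrailEntry(RULE_BOX3_CPV, "none", "no consensus hotspot match"))

    role = kb.role_of(record.gene, record.tumour_category)
    if is_clear_lof(record):
        if role is None:
            flags.add("manual_review")
            trail.append(
                TrailEntry(RULE_BOX4_TS_LOF, "role-unknown",
                           f"no curated role for {record.gene}; scoring table applies")
            )
        else:
            cls = classify_lof(role)
            rule = (
                RULE_BOX4_TS_LOF
                if role.role is GeneRoleKind.TUMOUR_SUPPRESSOR
                else RULE_BOX4_ONCO_LOF
            )
            trail.append(TrailEntry(rule, cls.value, f"clear LoF in {role.role.value}"))
            return ClassificationResult(cls, trail, rule, flags=flags), decision

    breakdown = score_variant(evidence, record.tumour_category)
    listed = kb.is_cpv_listed_gene(record.gene, record.tumour_category)
    cls, overruled = scoring_class(breakdown, listed, override)
    if overruled:
        flags.add("overruled")
    rule = RULE_OVERRIDE if overruled else RULE_BOX5_SCORE
    trail.append(
        TrailEntry(
            rule,
            cls.value,
            f"total {breakdown.total:g} "
            f"(cosmic {breakdown.cosmic_score:g}, insilico {breakdown.insilico_score:g}, "
            f"functional {breakdown.functional_score:g}, db {breakdown.genomicdb_score:g})",
        )
    )
    return (
        ClassificationResult(cls, trail, rule, score=breakdown, flags=flags),
        decision,
    )


# --- batch I/O --------------------------------------------------------------

_CALL_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "vaf", "depth"]
_ANNO_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "transcript", "cdna_hgvs",
    "protein_hgvs", "consequence", "exon", "tumour_category", "tumour_type",
]


def read_calls(path: Union[str, Path]) -> pd.DataFrame:
    """Read calls from TSV, or from a minimal VCF with DP/AF FORMAT fields."""
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return _read_vcf_calls(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _CALL_COLUMNS if c not in df.columns]
    if missing:
        raise SomaclassError(f"{path}: calls file missing columns {missing}")
    return df


def _read_vcf_calls(path: Path) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            for sample in samples:
                call = rec.samples[sample]
                dp = call.get("DP")
                af = call.get("AF")
                if af is None or dp is None:
                    continue
                af_val = af[0] if isinstance(af, tuple) else af
                rows.append(
                    {
                        "sample_id": sample,
                        "chrom": rec.chrom,
                        "pos": str(rec.pos),
                        "ref": rec.ref,
                        "alt": rec.alts[0] if rec.alts else "",
                        "vaf": str(af_val),
                        "depth": str(dp),
                    }
                )
    return pd.DataFrame(rows, columns=_CALL_COLUMNS)


def read_annotations(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ANNO_COLUMNS if c not in df.columns]
    if missing:
        raise SomaclassError(f"{path}: annotations file missing columns {missing}")
    return df


def load_overrides(path: Union[str, Path]) -> dict[tuple[str, str], OverrideRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = {}
    for _, row in df.iterrows():
        rec = OverrideRecord(
            gene=row["gene"].strip(),
            cdna_hgvs=row["cdna_hgvs"].strip(),
            new_class=BiologicalClass.from_label(row["new_class"]),
            justification=row.get("justification", ""),
            source=row.get("source", ""),
        )
        out[(rec.gene, rec.cdna_hgvs)] = rec
    return out


def _join_records(
    calls: pd.DataFrame, annotations: pd.DataFrame
) -> tuple[list[VariantRecord], list[str]]:
    anno_by_site = {
        (r["chrom"], r["pos"], r["ref"], r["alt"]): r
        for _, r in annotations.iterrows()
    }
    records: list[VariantRecord] = []
    skipped: list[str] = []
    for _, call in calls.iterrows():
        site = (call["chrom"], call["pos"], call["ref"], call["alt"])
        anno = anno_by_site.get(site)
        if anno is None:
            skipped.append(f"no annotation for {call['sample_id']} {site}")
            continue
        exon_raw = str(anno.get("exon", ".")).strip()
        try:
            records.append(
                VariantRecord(
                    sample_id=call["sample_id"],
                    chrom=call["chrom"],
                    pos=int(call["pos"]),
                    ref=call["ref"],
                    alt=call["alt"],
                    vaf=float(call["vaf"]),
                    depth=int(float(call["depth"])),
                    gene=anno["gene"],
                    transcript=anno["transcript"],
                    cdna_hgvs=anno["cdna_hgvs"],
                    protein_hgvs=anno["protein_hgvs"] or None,
                    consequence=Consequence(anno["consequence"]),
                    exon=int(exon_raw) if exon_raw not in {"", "."} else None,
                    tumour_category=TumourCategory.from_label(anno["tumour_category"]),
                    tumour_type=anno.get("tumour_type", ""),
                )
            )
        except (ValueError, SomaclassError) as exc:
            skipped.append(f"unusable record {call['sample_id']} {site}: {exc}")
    return records, skipped


@dataclass
class RunManifest:
    run_id: str
    config_digest: str
    kb_versions: dict[str, str]
    records_in: int = 0
    records_kept: int = 0
    records_classified: int = 0
    skipped: list[str] = field(default_factory=list)
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "run_id": self.run_id,
            "config_digest": self.config_digest,
            "kb_versions": self.kb_versions,
            "records_in": self.records_in,
            "records_kept": self.records_kept,
            "records_classified": self.records_classified,
            "skipped": self.skipped,
            "seed": self.seed,
        }


def config_digest(config: LabConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


class ClassificationStore:
    """Append-only local store of per-variant classification history."""

    def __init__(self, path: Optional[Union[str, Path]] = None) -> None:
        self.path = Path(path) if path else None
        self._history: dict[str, list[dict]] = {}
        if self.path and self.path.exists():
            self._history = json.loads(self.path.read_text())

    def current_class(self, variant_key: str) -> Optional[BiologicalClass]:
        entries = self._history.get(variant_key)
        if not entries:
            return None
        return BiologicalClass.from_label(entries[-1]["class"])

    def record(self, variant_key: str, result: ClassificationResult, run_id: str) -> None:
        entries = self._history.setdefault(variant_key, [])
        if entries and entries[-1]["class"] == result.biological_class.value:
            return
        entries.append(
            {
                "class": result.biological_class.value,
                "rule": result.terminal_rule,
                "run_id": run_id,
            }
        )

    def history(self, variant_key: str) -> list[dict]:
        return list(self._history.get(variant_key, []))

    def save(self) -> None:
        if self.path is None:
            raise SomaclassError("store has no backing path")
        self.path.write_text(json.dumps(self._history, indent=1, sort_keys=True))


def diff_store(
    store: ClassificationStore, new_results: Mapping[str, ClassificationResult]
) -> list[dict]:
    """Class-switch report: variants whose class changed vs the stored one."""
    switches = []
    for key in sorted(new_results):
        old = store.current_class(key)
        new = new_results[key].biological_class
        if old is None or old == new:
            continue
        switches.append(
            {
                "variant_key": key,
                "old_class": old.value,
                "new_class": new.value,
                "direction": "upgrade" if new > old else "downgrade",
                "expert_review": new < old,  # downgrades always reviewed
            }
        )
    return switches


@dataclass
class BatchResult:
    results: pd.DataFrame
    manifest: RunManifest
    review_queue: pd.DataFrame
    reanalysis: pd.DataFrame
    per_record: list[tuple[VariantRecord, Optional[ClassificationResult], FilterDecision]]


def classify_batch(
    calls_file: Union[str, Path],
    annotations_file: Union[str, Path],
    snapshots_file: Optional[Union[str, Path]],
    evidence_file: Optional[Union[str, Path]],
    kb: Optional[KnowledgeBase] = None,
    config: Optional[LabConfig] = None,
    observation_log: Optional[ObservationLog] = None,
    overrides_file: Optional[Union[str, Path]] = None,
    store: Optional[ClassificationStore] = None,
    run_id: str = "run",
) -> BatchResult:
    """Classify a batch of joined calls; deterministic and order-invariant.

    Results are sorted by (sample, gene, cdna) so a permuted input yields
    byte-identical output tables.
    """
    kb = kb or KnowledgeBase.load()
    config = config or LabConfig()
    calls = read_calls(calls_file)
    annotations = read_annotations(annotations_file)
    snapshots = load_population_table(snapshots_file) if snapshots_file else {}
    evidence_map = load_evidence_table(evidence_file) if evidence_file else {}
    overrides = load_overrides(overrides_file) if overrides_file else {}

    records, skipped = _join_records(calls, annotations)
    records.sort(key=lambda r: (r.sample_id, r.gene, r.cdna_hgvs, r.chrom, r.pos))
    recurrence = compute_run_recurrence(records)

    rows = []
    review_rows = []
    reanalysis_rows = []
    per_record = []
    latest: dict[str, ClassificationResult] = {}
    kept = 0
    for record in records:
        ev_key = (record.gene, record.cdna_hgvs)
        snapshot = snapshots.get(ev_key, PopulationFrequencySnapshot())
        evidence = evidence_map.get(ev_key, EvidenceBundle())
        result, decision = classify_record(
            record,
            snapshot,
            evidence,
            kb,
            config,
            observation_log=observation_log,
            override=overrides.get(ev_key),
            run_recurrence=recurrence,
        )
        per_record.append((record, result, decision))
        if result is None:
            if decision.reason in (FilterReason.LOW_VAF, FilterReason.LOW_DEPTH):
                candidate = classify_cpv(record, kb) is not None or (
                    is_clear_lof(record)
                    and (role := kb.role_of(record.gene, record.tumour_category))
                    is not None
                    and role.role is GeneRoleKind.TUMOUR_SUPPRESSOR
                )
                if candidate:
                    reanalysis_rows.append(
                        {
                            "sample_id": record.sample_id,
                            "variant_key": record.key,
                            "reason": decision.reason.value,
                            "detail": decision.detail,
                        }
                    )
            continue
        kept += 1
        latest[record.key] = result
        if store is not None:
            store.record(record.key, result, run_id)
        rows.append(
            {
                "sample_id": record.sample_id,
                "gene": record.gene,
                "transcript": record.transcript,
                "cdna_hgvs": record.cdna_hgvs,
                "protein_hgvs": record.protein_hgvs or ".",
                "vaf": f"{record.vaf:.4f}",
                "depth": record.depth,
                "biological_class": result.biological_class.value,
                "terminal_rule": result.terminal_rule,
                "score_total": "." if result.score is None else f"{result.score.total:g}",
                "flags": ",".join(sorted(result.flags)) or ".",
            }
        )
        if result.flags:
            review_rows.append(
                {
                    "sample_id": record.sample_id,
                    "variant_key": record.key,
                    "biological_class": result.biological_class.value,
                    "flags": ",".join(sorted(result.flags)),
                }
            )

    manifest = RunManifest(
        run_id=run_id,
        config_digest=config_digest(config),
        kb_versions=dict(kb.versions),
        records_in=len(records),
        records_kept=kept,
        records_classified=kept,
        skipped=skipped,
    )
    results_df = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "gene", "transcript", "cdna_hgvs", "protein_hgvs",
            "vaf", "depth", "biological_class", "terminal_rule", "score_total",
            "flags",
        ],
    )
    review_df = pd.DataFrame(
        review_rows, columns=["sample_id", "variant_key", "biological_class", "flags"]
    )
    reanalysis_df = pd.DataFrame(
        reanalysis_rows, columns=["sample_id", "variant_key", "reason", "detail"]
    )
    return BatchResult(results_df, manifest, review_df, reanalysis_df, per_record)


def write_batch_outputs(batch: BatchResult, out_dir: Union[str, Path]) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    batch.results.to_csv(out / "results.tsv", sep="\t", index=False)
    records = batch.results.to_dict(orient="records")
    (out / "results.json").write_text(json.dumps(records, indent=1, sort_keys=True))
    (out / "manifest.json").write_text(
        json.dumps(batch.manifest.to_dict(), indent=1, sort_keys=True)
    )
    batch.review_queue.to_csv(out / "review_queue.tsv", sep="\t", index=False)
    batch.reanalysis.to_csv(out / "reanalysis.tsv", sep="\t", index=False)
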