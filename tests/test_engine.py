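"""End-to-end single-record pipeline, batch I/O, store diffing."""

import pandas as pd
import pytest

from somaclass.classifier import (
    RULE_BOX2_POPULATION,
    RULE_BOX3_CPV,
    RULE_BOX5_SCORE,
    ClassificationResult,
    TrailEntry,
)
from somaclass.config import LabConfig
from somaclass.engine import (
    ClassificationStore,
    classify_batch,
    classify_record,
    diff_store,
    write_batch_outputs,
)
from somaclass.filters import ObservationLog
from somaclass.fixtures import FixtureSpec, generate_fixtures
from somaclass.knowledge import (
    EvidenceBundle,
    PopulationEntry,
    PopulationFrequencySnapshot,
    TriState,
)
from somaclass.model import BiologicalClass, TumourCategory

from conftest import make_record


@pytest.fixture(scope="module")
def batch_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture_batch")
    generate_fixtures(FixtureSpec(seed=11, n_per_branch=2)).write(out)
    return out


def _run_batch(d, calls="calls.tsv"):
    return classify_batch(
        d / calls,
        d / "annotations.tsv",
        d / "popfreq.tsv",
        d / "evidence.tsv",
        config=LabConfig.from_file(d / "config.yaml"),
        observation_log=ObservationLog.from_file(d / "observations.tsv"),
        overrides_file=d / "overrides.tsv",
    )


class TestClassifyRecord:
    def test_hotspot_route(self, kb, config):
        record = make_record(
            gene="EGFR", transcript="NM_005228.4", cdna="c.2573T>G",
            protein="p.(Leu858Arg)", vaf=0.22,
        )
        result, decision = classify_record(
            record, PopulationFrequencySnapshot(), EvidenceBundle(), kb, config
        )
        assert decision.keep
        assert result.biological_class is BiologicalClass.PATHOGENIC
        assert result.terminal_rule == RULE_BOX3_CPV

    def test_population_route(self, kb, config):
        record = make_record(
            gene="ALK", transcript="NM_004304.4", cdna="c.4796C>A",
            protein="p.(Pro1599His)", vaf=0.49,
        )
        snapshot = PopulationFrequencySnapshot(
            entries=(
                PopulationEntry("Total", 0.0002, 251_496),
                PopulationEntry("African", 0.0025, 24_968),
            ),
            dbsnp_listed=TriState.YES,
        )
        result, _ = classify_record(record, snapshot, EvidenceBundle(), kb, config)
        assert result.biological_class is BiologicalClass.LIKELY_BENIGN
        assert result.terminal_rule == RULE_BOX2_POPULATION

    def test_scoring_route_l747p(self, kb, config):
        record = make_record(
            gene="EGFR", transcript="NM_005228.4", cdna="c.2239_2240delinsCC",
            protein="p.(Leu747Pro)", vaf=0.31,
        )
        evidence = EvidenceBundle(
            cosmic_count=62, sift_damaging=TriState.YES,
            mutationtaster_damaging=TriState.YES,
        )
        result, _ = classify_record(
            record, PopulationFrequencySnapshot(), evidence, kb, config
        )
        assert result.biological_class is BiologicalClass.LIKELY_PATHOGENIC
        assert result.terminal_rule == RULE_BOX5_SCORE
        assert result.score.total == 2.5

    def test_rule_trail_records_every_stage(self, kb, config):
        record = make_record(cdna="c.169G>A", protein="p.(Asp57Asn)")
        result, _ = classify_record(
            record, PopulationFrequencySnapshot(), EvidenceBundle(), kb, config
        )
        rules = [t.rule_id for t in result.rule_trail]
        assert rules[0] == "BOX1-DROP"
        assert RULE_BOX5_SCORE in rules

    def test_dropped_record_returns_decision_only(self, kb, config):
        record = make_record(vaf=0.01)
        result, decision = classify_record(
            record, PopulationFrequencySnapshot(), EvidenceBundle(), kb, config
        )
        assert result is None and not decision.keep


class TestBatch:
    def test_rerun_is_byte_identical(self, batch_dir, tmp_path):
        b1 = _run_batch(batch_dir)
        b2 = _run_batch(batch_dir)
        write_batch_outputs(b1, tmp_path / "a")
        write_batch_outputs(b2, tmp_path / "b")
        for name in ("results.tsv", "results.json", "review_queue.tsv", "reanalysis.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_row_permutation_invariance(self, batch_dir, tmp_path):
        calls = pd.read_csv(batch_dir / "calls.tsv", sep="\t", dtype=str,
                            keep_default_na=False)
        shuffled = calls.sample(frac=1, random_state=3)
        shuffled.to_csv(tmp_path / "calls_shuffled.tsv", sep="\t", index=False)
        (tmp_path / "calls_shuffled.tsv").rename(batch_dir / "calls_shuffled.tsv")
        base = _run_batch(batch_dir)
        perm = _run_batch(batch_dir, "calls_shuffled.tsv")
        assert base.results.equals(perm.results)

    def test_every_kept_record_gets_exactly_one_class(self, batch_dir):
        batch = _run_batch(batch_dir)
        classes = set(batch.results["biological_class"])
        valid = {c.value for c in BiologicalClass}
        assert classes <= valid
        assert len(batch.results) == batch.manifest.records_kept

    def test_no_synonymous_or_intronic_reaches_classifier(self, batch_dir):
        batch = _run_batch(batch_dir)
        for record, result, _ in batch.per_record:
            if result is not None and record.gene != "TP53":
                assert record.consequence.value not in {"synonymous", "intronic"}

    def test_empty_calls_file(self, batch_dir, tmp_path):
        empty = tmp_path / "empty.tsv"
        empty.write_text("sample_id\tchrom\tpos\tref\talt\tvaf\tdepth\n")
        batch = classify_batch(
            empty, batch_dir / "annotations.tsv", None, None
        )
        assert batch.manifest.records_in == 0
        assert len(batch.results) == 0

    def test_duplicate_variant_two_samples_two_results(self, batch_dir, tmp_path):
        calls = pd.read_csv(batch_dir / "calls.tsv", sep="\t", dtype=str,
                            keep_default_na=False)
        row = calls.iloc[[0]].copy()
        row["sample_id"] = "S9999"
        pd.concat([calls, row]).to_csv(tmp_path / "dup.tsv", sep="\t", index=False)
        (tmp_path / "dup.tsv").rename(batch_dir / "calls_dup.tsv")
        base = _run_batch(batch_dir)
        dup = _run_batch(batch_dir, "calls_dup.tsv")
        assert dup.manifest.records_in == base.manifest.records_in + 1

    def test_unjoinable_record_logged_not_fatal(self, batch_dir, tmp_path):
        calls = pd.read_csv(batch_dir / "calls.tsv", sep="\t", dtype=str,
                            keep_default_na=False)
        orphan = calls.iloc[[0]].copy()
        orphan["chrom"] = "chrZ"
        pd.concat([calls, orphan]).to_csv(batch_dir / "calls_orphan.tsv",
                                          sep="\t", index=False)
        batch = _run_batch(batch_dir, "calls_orphan.tsv")
        assert len(batch.manifest.skipped) == 1


class TestStore:
    def _result(self, cls):
        return ClassificationResult(
            biological_class=cls,
            rule_trail=[TrailEntry("BOX5-SCORE", cls.value)],
            terminal_rule="BOX5-SCORE",
        )

    def test_upgrade_and_downgrade_reported(self, tmp_path):
        store = ClassificationStore(tmp_path / "store.json")
        store.record("K1", self._result(BiologicalClass.VUS), "r1")
        store.record("K2", self._result(BiologicalClass.PATHOGENIC), "r1")
        switches = diff_store(
            store,
            {
                "K1": self._result(BiologicalClass.LIKELY_PATHOGENIC),
                "K2": self._result(BiologicalClass.VUS),
            },
        )
        by_key = {s["variant_key"]: s for s in switches}
        assert by_key["K1"]["direction"] == "upgrade"
        assert by_key["K2"]["direction"] == "downgrade"
        assert by_key["K2"]["expert_review"]

    def test_identical_run_yields_empty_diff(self, tmp_path):
        store = ClassificationStore(tmp_path / "store.json")
        res = self._result(BiologicalClass.VUS)
        store.record("K1", res, "r1")
        assert diff_store(store, {"K1": res}) == []

    def test_history_append_only(self, tmp_path):
        path = tmp_path / "store.json"
        store = ClassificationStore(path)
        store.record("K1", self._result(BiologicalClass.VUS), "r1")
        store.record("K1", self._result(BiologicalClass.LIKELY_PATHOGENIC), "r2")
        store.record("K1", self._result(BiologicalClass.LIKELY_PATHOGENIC), "r3")
        store.save()
        reloaded = ClassificationStore(path)
        history = reloaded.history("K1")
        assert [h["class"] for h in history] == ["VUS", "Likely Pathogenic"]
        assert reloaded.current_class("K1") is BiologicalClass.LIKELY_PATHOGENIC
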