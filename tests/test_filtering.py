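"""Staged filtering, trajectories and redundancy screening."""

import pytest
import yaml

from orthoforest.filtering import (
    FilterRule,
    FilterStage,
    apply_stage,
    dedupe,
    load_stage_config,
    run_pipeline,
)
from orthoforest.io import Dataset

from conftest import make_record


def stage(label, field, mode, terms, connective="OR"):
    return FilterStage(
        label=label,
        rules=(FilterRule(field=field, mode=mode, terms=tuple(terms)),),
        connective=connective,
    )


class TestApplyStage:
    def test_has_any_go(self, small_dataset):
        out = apply_stage(small_dataset, stage("s", "go_terms", "has_any", ["GO:0016730"]))
        assert out.accessions() == ["P1", "P2"]

    def test_lacks_all_identity_when_absent(self, small_dataset):
        out = apply_stage(
            small_dataset, stage("s", "pfam_terms", "lacks_all", ["PF99999"])
        )
        assert out.accessions() == small_dataset.accessions()

    def test_text_contains_any_case_insensitive(self, small_dataset):
        out = apply_stage(
            small_dataset, stage("s", "name", "text_contains_any", ["oxidoreductase"])
        )
        assert out.accessions() == ["P1"]

    def test_keyword_matching_is_case_insensitive(self, small_dataset):
        out = apply_stage(
            small_dataset, stage("s", "keywords", "has_any", ["CHLOROPLAST"])
        )
        assert out.accessions() == ["P4"]

    def test_has_all(self, small_dataset):
        out = apply_stage(
            small_dataset,
            stage("s", "go_terms", "has_all", ["GO:0016730", "GO:0046872"]),
        )
        assert out.accessions() == ["P2"]

    def test_and_connective(self, small_dataset):
        st = FilterStage(
            label="both",
            rules=(
                FilterRule("go_terms", "has_any", ("GO:0016730",)),
                FilterRule("go_terms", "has_any", ("GO:0046872",)),
            ),
            connective="AND",
        )
        assert apply_stage(small_dataset, st).accessions() == ["P2"]

    def test_rule_validates_term_ids(self):
        with pytest.raises(ValueError, match="GO id"):
            FilterRule("go_terms", "has_any", ("GO:16117",))
        with pytest.raises(ValueError, match="non-empty"):
            FilterRule("go_terms", "has_any", ())


class TestRunPipeline:
    def test_planted_counts(self):
        # 100 records; stage 1 removes the 30 tagged drop1, stage 2 the 20 drop2
        records = []
        for i in range(100):
            go = set()
            if i >= 30:
                go.add("GO:0000001")
            if i >= 30 and i < 80:
                go.add("GO:0000002")
            records.append(make_record(f"R{i}", go_terms=go))
        ds = Dataset(records)
        stages = [
            stage("keep-1", "go_terms", "has_any", ["GO:0000001"]),
            stage("keep-2", "go_terms", "has_any", ["GO:0000002"]),
        ]
        final, traj = run_pipeline(ds, stages)
        assert traj.counts == [100, 70, 50]
        # independent set arithmetic on the planted membership
        expected = {f"R{i}" for i in range(30, 80)}
        assert set(final.accessions()) == expected

    def test_always_true_stage(self, small_dataset):
        st = stage("id", "go_terms", "lacks_all", ["GO:9999999"])
        _, traj = run_pipeline(small_dataset, [st])
        assert traj.counts == [5, 5]

    def test_empty_stage_list_forbidden(self, small_dataset):
        with pytest.raises(ValueError):
            run_pipeline(small_dataset, [])

    def test_trajectory_monotone_and_nested(self, small_dataset):
        stages = [
            stage("a", "go_terms", "lacks_all", ["GO:9999999"]),
            stage("b", "go_terms", "has_any", ["GO:0016730"]),
            stage("c", "go_terms", "has_any", ["GO:0046872"]),
        ]
        _, traj = run_pipeline(small_dataset, stages)
        traj.validate()
        for earlier, later in zip(traj.counts, traj.counts[1:]):
            assert later <= earlier

    def test_composability(self, small_dataset):
        s1 = [stage("a", "go_terms", "has_any", ["GO:0016730"])]
        s2 = [stage("b", "go_terms", "has_any", ["GO:0046872"])]
        joint, _ = run_pipeline(small_dataset, s1 + s2)
        first, _ = run_pipeline(small_dataset, s1)
        second, _ = run_pipeline(first, s2)
        assert joint.accessions() == second.accessions()


class TestDedupe:
    def test_published_pool_dedup(self):
        # 1199 merged records, 110 of which repeat an earlier sequence
        records = [make_record(f"U{i}", sequence=f"ACDE{'M' * (i % 1089)}K") for i in range(1089)]
        records += [
            make_record(f"D{i}", sequence=f"ACDE{'M' * (i % 110)}K") for i in range(110)
        ]
        ds = Dataset(records)
        assert len(ds) == 1199
        unique, removed = dedupe(ds, key="sequence")
        assert len(unique) == 1089
        assert len(removed) == 110

    def test_no_duplicates_is_identity(self, small_dataset):
        unique, removed = dedupe(small_dataset, key="sequence")
        # all fixture records share a sequence; use accession key instead
        unique2, removed2 = dedupe(small_dataset, key="accession")
        assert unique2.accessions() == small_dataset.accessions()
        assert removed2 == []

    def test_key_semantics(self):
        ds = Dataset(
            [make_record("A1", sequence="ACDE"), make_record("A2", sequence="ACDE")]
        )
        by_seq, removed = dedupe(ds, key="sequence")
        assert len(by_seq) == 1 and removed[0][0].accession == "A2"
        assert removed[0][1].accession == "A1"  # retained representative
        by_acc, _ = dedupe(ds, key="accession")
        assert len(by_acc) == 2

    def test_idempotent(self):
        ds = Dataset(
            [make_record(f"A{i}", sequence="ACDE" * (1 + i % 3)) for i in range(9)]
        )
        once, _ = dedupe(ds, key="sequence")
        twice, removed = dedupe(once, key="sequence")
        assert twice.accessions() == once.accessions()
        assert removed == []


def test_stage_config_round_trip(tmp_path):
    doc = {
        "stages": [
            {
                "label": "carotenoid GO",
                "connective": "OR",
                "rules": [
                    {"field": "go_terms", "mode": "has_any",
                     "terms": ["GO:0010436", "GO:0016117"]},
                ],
            },
            {
                "label": "domain",
                "rules": [
                    {"field": "pfam_terms", "mode": "has_any", "terms": ["PF01593"]},
                ],
            },
        ]
    }
    p = tmp_path / "stages.yaml"
    p.write_text(yaml.safe_dump(doc))
    stages = load_stage_config(p)
    assert [s.label for s in stages] == ["carotenoid GO", "domain"]
    assert stages[1].connective == "OR"
    assert stages[0].rules[0].terms == ("GO:0010436", "GO:0016117")


def test_shipped_carotenoid_config_loads():
    from importlib.resources import files

    path = files("orthoforest") / "configs" / "carotenoid_stages.yaml"
    stages = load_stage_config(str(path))
    assert len(stages) == 3
    labels = [s.label for s in stages]
    assert "carotenoid-function GO" in labels
    go_stage = stages[labels.index("carotenoid-function GO")]
    assert "GO:0010436" in go_stage.rules[0].terms
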