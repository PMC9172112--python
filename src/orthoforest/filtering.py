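"""Staged deterministic filtering of protein populations.

A filter run is a sequence of stages; each stage is a small boolean
predicate over a record's GO terms, Pfam domains, keywords or free-text
name. The run yields both the surviving records and a
:class:`FilterTrajectory` — the per-stage population counts that make the
characteristic monotone "staircase" curve of a staged annotation screen.

Stage definitions are data, not code: they can be loaded from a YAML/JSON
config (see :func:`load_stage_config`) so a published screen is a shippable
artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import yaml

from .io import Dataset, GO_RE, PFAM_RE, DatasetError, ProteinRecord

FieldName = Literal["go_terms", "pfam_terms", "keywords", "name"]
Mode = Literal["has_any", "has_all", "lacks_all", "text_contains_any"]


@dataclass(frozen=True)
class FilterRule:
    """One predicate: does a record's ``field`` relate to ``terms`` via ``mode``?

    Term fields (``go_terms``/``pfam_terms``/``keywords``) are matched by
    exact ID; ``name`` (and ``text_contains_any`` generally) by
    case-insensitive substring.
    """

    field: FieldName
    mode: Mode
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("FilterRule.terms must be non-empty")
        if self.field == "go_terms" and self.mode != "text_contains_any":
            for t in self.terms:
                if not GO_RE.match(t):
                    raise ValueError(f"not a GO id: {t!r}")
        if self.field == "pfam_terms" and self.mode != "text_contains_any":
            for t in self.terms:
                if not PFAM_RE.match(t):
                    raise ValueError(f"not a Pfam id: {t!r}")

    def matches(self, rec: ProteinRecord) -> bool:
        if self.mode == "text_contains_any":
            if self.field == "name":
                hay = rec.name.lower()
            elif self.field == "keywords":
                hay = " ".join(sorted(rec.keywords))
            else:
                hay = " ".join(sorted(getattr(rec, self.field)))
            return any(t.lower() in hay for t in self.terms)
        values = rec.name if self.field == "name" else getattr(rec, self.field)
        if self.field == "name":
            # exact-ID modes degrade to case-insensitive equality on names
            values = {rec.name.lower()}
            terms = {t.lower() for t in self.terms}
        elif self.field == "keywords":
            values = rec.keywords
            terms = {t.lower() for t in self.terms}
        else:
            terms = set(self.terms)
        if self.mode == "has_any":
            return bool(values & terms)
        if self.mode == "has_all":
            return terms <= values
        if self.mode == "lacks_all":
            return not (values & terms)
        raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class FilterStage:
    """A labelled group of rules combined by one connective (AND / OR)."""

    label: str
    rules: tuple[FilterRule, ...]
    connective: Literal["AND", "OR"] = "OR"

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError(f"stage {self.label!r} needs at least one rule")
        if self.connective not in ("AND", "OR"):
            raise ValueError(f"bad connective {self.connective!r}")

    def keeps(self, rec: ProteinRecord) -> bool:
        hits = (r.matches(rec) for r in self.rules)
        return all(hits) if self.connective == "AND" else any(hits)


@dataclass
class FilterTrajectory:
    """Per-stage population counts and surviving ID sets.

    ``counts[0]`` is the input population; ``counts[i]`` the survivors after
    stage ``i``. Counts are non-increasing and survivor sets are nested.
    """

    stage_labels: list[str] = field(default_factory=list)
    counts: list[int] = field(default_factory=list)
    surviving_ids: list[set[str]] = field(default_factory=list)

    def validate(self) -> None:
        assert len(self.counts) == len(self.surviving_ids) == len(self.stage_labels)
        for i, (c, ids) in enumerate(zip(self.counts, self.surviving_ids)):
            assert c == len(ids)
            if i:
                assert ids <= self.surviving_ids[i - 1]
                assert c <= self.counts[i - 1]

    def to_rows(self) -> list[dict[str, object]]:
        return [
            {"stage": lbl, "count": n}
            for lbl, n in zip(self.stage_labels, self.counts)
        ]


def apply_stage(d: Dataset, stage: FilterStage) -> Dataset:
    """Records of ``d`` satisfying the stage predicate, order preserved."""
    out = Dataset(
        (r for r in d if stage.keeps(r)),
        provenance=d.provenance + [f"apply_stage {stage.label}"],
    )
    return out


def run_pipeline(
    d: Dataset, stages: Sequence[FilterStage]
) -> tuple[Dataset, FilterTrajectory]:
    """Apply stages sequentially, recording the population trajectory."""
    if not stages:
        raise ValueError("at least one stage required")
    traj = FilterTrajectory(
        stage_labels=["input"],
        counts=[len(d)],
        surviving_ids=[set(d.accessions())],
    )
    current = d
    for stage in stages:
        current = apply_stage(current, stage)
        traj.stage_labels.append(stage.label)
        traj.counts.append(len(current))
        traj.surviving_ids.append(set(current.accessions()))
    traj.validate()
    return current, traj


DedupKey = Literal["accession", "sequence", "accession_or_sequence"]


def dedupe(
    d: Dataset, key: DedupKey = "sequence"
) -> tuple[Dataset, list[tuple[ProteinRecord, ProteinRecord]]]:
    """Redundancy screen: first occurrence wins; idempotent.

    Returns the deduplicated dataset and a list pairing each removed record
    with the retained representative it duplicated.
    """
    if key not in ("accession", "sequence", "accession_or_sequence"):
        raise ValueError(f"unknown dedup key {key!r}")
    seen_acc: dict[str, ProteinRecord] = {}
    seen_seq: dict[str, ProteinRecord] = {}
    removed: list[tuple[ProteinRecord, ProteinRecord]] = []
    kept: list[ProteinRecord] = []
    for rec in d:
        rep = None
        if key in ("accession", "accession_or_sequence"):
            rep = seen_acc.get(rec.accession)
        if rep is None and key in ("sequence", "accession_or_sequence"):
            rep = seen_seq.get(rec.sequence)
        if rep is not None:
            removed.append((rec, rep))
            continue
        kept.append(rec)
        seen_acc[rec.accession] = rec
        seen_seq[rec.sequence] = rec
    # a dataset may legally hold duplicate accessions only transiently here
    out = Dataset(provenance=d.provenance + [f"dedupe key={key}"])
    for rec in kept:
        out.add(rec)
    return out, removed


def load_stage_config(path: str | Path) -> list[FilterStage]:
    """Load filter stages from a YAML/JSON config.

    Schema: a mapping with key ``stages``: a list of
    ``{label, connective, rules: [{field, mode, terms}]}``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "stages" not in doc:
        raise DatasetError(f"{path}: config must contain a 'stages' list")
    stages = []
    for entry in doc["stages"]:
        rules = tuple(
            FilterRule(
                field=r["field"], mode=r["mode"], terms=tuple(map(str, r["terms"]))
            )
            for r in entry["rules"]
        )
        stages.append(
            FilterStage(
                label=str(entry["label"]),
                rules=rules,
                connective=entry.get("connective", "OR"),
            )
        )
    return stages
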