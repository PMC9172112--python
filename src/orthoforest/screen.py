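"""Functional screening and evidence combination.

Candidates are screened against a functional vocabulary of GO/Pfam terms
via a binary presence matrix (the heat-map view: one row per protein, one
column per term); all-zero rows — candidates with no annotated role in the
screened function — are discarded. The three evidence channels
(phylogenetic co-clustering, forest selection, term screen) are then
combined into the final ortholog table, and the analysis error is the
fraction of called orthologs absent from an independent reference call
set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .io import Dataset
from .trees import OrthologCluster

Status = Literal["ortholog", "needs_verification", "not_found"]


def build_presence_matrix(
    d: Dataset, vocabulary: Sequence[str], kind: Literal["GO", "Pfam"]
) -> pd.DataFrame:
    """Binary protein × term matrix over a fixed vocabulary.

    Cell (p, t) is 1 iff term t is annotated on protein p; terms outside
    the vocabulary are ignored.
    """
    if not vocabulary:
        raise ValueError("vocabulary must be non-empty")
    attr = "go_terms" if kind == "GO" else "pfam_terms"
    data = {
        rec.accession: [1 if t in getattr(rec, attr) else 0 for t in vocabulary]
        for rec in d
    }
    return pd.DataFrame.from_dict(
        data, orient="index", columns=list(vocabulary)
    ).astype(int)


def screen_by_function(matrix: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Partition rows into (kept, discarded): kept rows have ≥1 presence."""
    sums = matrix.sum(axis=1)
    kept = [str(i) for i in matrix.index[sums > 0]]
    discarded = [str(i) for i in matrix.index[sums == 0]]
    return kept, discarded


def plot_presence_heatmap(matrix: pd.DataFrame, path) -> None:
    """Two-color presence/absence heat map of the screening matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * matrix.shape[1]), max(3, 0.25 * matrix.shape[0]))
    )
    ax.imshow(matrix.values, cmap=ListedColormap(["#1f4e9c", "#ffd23f"]), aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=6)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


@dataclass
class EvidenceRecord:
    """One (reference, candidate) pair with its evidence flags."""

    candidate: str | None
    references: list[str]
    in_phylo_clusters: bool = False
    in_forest_selected: bool = False
    passed_term_screen: bool = False
    support: float | None = None
    forest_score: float | None = None

    @property
    def any_evidence(self) -> bool:
        return self.in_phylo_clusters or self.in_forest_selected or self.passed_term_screen


@dataclass
class OrthologTable:
    """Final calls: one row per (reference, candidate) pair plus a status."""

    rows: list[tuple[EvidenceRecord, Status, str]] = field(default_factory=list)

    def add(self, rec: EvidenceRecord, status: Status, note: str = "") -> None:
        assert status in ("ortholog", "needs_verification", "not_found")
        if status != "not_found":
            assert rec.any_evidence, "called rows need at least one evidence flag"
        self.rows.append((rec, status, note))

    def called(self) -> list[EvidenceRecord]:
        return [r for r, s, _ in self.rows if s in ("ortholog", "needs_verification")]

    def by_status(self, status: Status) -> list[EvidenceRecord]:
        return [r for r, s, _ in self.rows if s == status]

    def to_rows(self) -> list[dict[str, object]]:
        return [
            {
                "reference": ";".join(rec.references),
                "candidate": rec.candidate or "",
                "status": status,
                "support": "" if rec.support is None else f"{rec.support:.3f}",
                "forest_score": "" if rec.forest_score is None else rec.forest_score,
                "in_phylo": int(rec.in_phylo_clusters),
                "in_forest": int(rec.in_forest_selected),
                "in_screen": int(rec.passed_term_screen),
                "notes": note,
            }
            for rec, status, note in self.rows
        ]


@dataclass
class ErrorEstimate:
    """extras / total, as a percentage rounded half-up to one decimal."""

    extras: int
    total: int
    percent: float

    def __post_init__(self) -> None:
        assert 0 <= self.extras <= self.total
        assert 0.0 <= self.percent <= 100.0


Policy = Literal["intersection_then_rescue", "intersection", "union", "weighted"]


def combine_evidence(
    clusters: Sequence[OrthologCluster],
    forest_selected: Iterable[str],
    screened_kept: Iterable[str],
    policy: Policy = "intersection_then_rescue",
    reference_universe: Iterable[str] = (),
    forest_best_ref: Mapping[str, str] | None = None,
    forest_scores: Mapping[str, float] | None = None,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    weight_cut: float = 2.0,
) -> OrthologTable:
    """Combine phylogeny, forest and screening evidence into final calls.

    Policies
    --------
    intersection_then_rescue (default)
        ``ortholog`` when the phylogenetic cluster and the term screen
        agree; candidates carrying partial evidence (e.g. forest-only
        hits) are kept as ``needs_verification`` rather than dropped.
    intersection
        ``ortholog`` only on phylo ∧ screen agreement; nothing rescued.
    union
        any single evidence channel suffices for ``ortholog``.
    weighted
        channels scored by ``weights`` (phylo, forest, screen);
        ``ortholog`` at ≥ ``weight_cut``, anything positive below the cut
        becomes ``needs_verification``.

    Reference accessions in ``reference_universe`` with no candidate under
    any channel are reported as ``not_found`` rows.
    """
    if policy not in ("intersection_then_rescue", "intersection", "union", "weighted"):
        raise ValueError(f"unknown policy {policy!r}")
    forest_sel = set(forest_selected)
    screened = set(screened_kept)
    best_ref = dict(forest_best_ref or {})
    scores = dict(forest_scores or {})

    # one row per (reference, candidate) pair from the tree clusters
    pair_refs: dict[str, list[tuple[str, float]]] = {}
    for cl in clusters:
        for cand in cl.ortholog_members:
            pair_refs.setdefault(cand, []).append((cl.reference_member, cl.support))

    table = OrthologTable()
    covered_refs: set[str] = set()
    seen_candidates: set[str] = set()

    def status_for(rec: EvidenceRecord) -> Status:
        p, f, s = rec.in_phylo_clusters, rec.in_forest_selected, rec.passed_term_screen
        if policy == "union":
            return "ortholog"
        if policy == "weighted":
            score = weights[0] * p + weights[1] * f + weights[2] * s
            return "ortholog" if score >= weight_cut else "needs_verification"
        if p and s:
            return "ortholog"
        if policy == "intersection":
            return "needs_verification"
        return "needs_verification"

    for cand, refs in pair_refs.items():
        seen_candidates.add(cand)
        for ref, support in refs:
            covered_refs.add(ref)
            rec = EvidenceRecord(
                candidate=cand,
                references=[ref],
                in_phylo_clusters=True,
                in_forest_selected=cand in forest_sel,
                passed_term_screen=cand in screened,
                support=support,
                forest_score=scores.get(cand),
            )
            status = status_for(rec)
            if policy == "intersection" and status != "ortholog":
                continue
            table.add(rec, status)

    # forest-only candidates: flagged for verification, never silently kept
    for cand in sorted(forest_sel - seen_candidates):
        rec = EvidenceRecord(
            candidate=cand,
            references=[best_ref[cand]] if cand in best_ref else [],
            in_phylo_clusters=False,
            in_forest_selected=True,
            passed_term_screen=cand in screened,
            forest_score=scores.get(cand),
        )
        if cand in best_ref:
            covered_refs.add(best_ref[cand])
        if policy == "intersection":
            continue
        status = "ortholog" if policy == "union" else status_for(rec)
        if policy == "intersection_then_rescue":
            status = "needs_verification"
        table.add(rec, status, note="forest-only hit; needs further verification")

    for ref in sorted(set(reference_universe) - covered_refs):
        table.add(
            EvidenceRecord(candidate=None, references=[ref]),
            "not_found",
            note="no candidate in any evidence channel",
        )
    return table


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def estimate_error(
    table: OrthologTable, reference_calls: Iterable[str | tuple[str, str]]
) -> ErrorEstimate:
    """Extras over total: the share of called orthologs that an independent
    reference call set does not contain.

    ``reference_calls`` may be candidate accessions or (reference,
    candidate) pairs; comparison is on the candidate accession. The
    percentage is rounded half-up to one decimal.
    """
    called = table.called()
    if not called:
        raise ValueError("empty ortholog table")
    known = {
        c[1] if isinstance(c, tuple) else c for c in reference_calls
    }
    extras = sum(1 for rec in called if rec.candidate not in known)
    total = len(called)
    return ErrorEstimate(
        extras=extras,
        total=total,
        percent=round_half_up(100.0 * extras / total, 1),
    )
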