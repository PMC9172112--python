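"""End-to-end orchestration of the ortholog-calling flow.

Order of stages (each also available individually through the CLI):

1. annotation filtering of each species' population (trajectory logged),
2. cross-species merge + redundancy screen,
3. multiple alignment → NJ tree → bootstrap supports → ortholog clusters,
4. GO/Pfam presence-matrix screen of the candidate species,
5. forest (population) analysis of candidates against the references,
6. evidence combination into the final ortholog table,
7. error estimate against an independent reference call set (optional).

A JSON manifest (config, seed, package version, per-stage counts) makes a
run reproducible: deterministic stages are bit-identical on rerun, the
bootstrap is seed-identical.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .align import AlignmentParams
from .filtering import dedupe, load_stage_config, run_pipeline
from .forest import compute_threshold, fit_bimodal, score_forest, select_high_correlation
from .io import Dataset, merge_datasets, read_annotation_table, read_fasta, write_table
from .msa import progressive_align
from .screen import (
    OrthologTable,
    build_presence_matrix,
    combine_evidence,
    estimate_error,
    screen_by_function,
)
from .simulate import DEFAULT_VOCAB
from .trees import bootstrap_supports, extract_ortholog_clusters, write_newick


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    fasta_a: str
    fasta_b: str
    outdir: str
    species_a: str = "ARA"
    species_b: str = "RA"
    annotations_a: str | None = None
    annotations_b: str | None = None
    reference_fasta: str | None = None  # defaults to the filtered species-A set
    stages_a: str | None = None
    stages_b: str | None = None
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    threshold_override: float | None = None
    bootstrap_reps: int = 100
    seed: int = 17
    min_support: float = 0.5
    deletion: str = "pairwise"  # mixed-family alignments share few clean columns
    coverage: float = 0.8
    functional_vocab: list[str] = field(default_factory=lambda: list(DEFAULT_VOCAB))
    combine_policy: str = "intersection_then_rescue"
    reference_calls: str | None = None
    dedupe_key: str = "sequence"
    make_plots: bool = False

    def validate(self) -> None:
        for attr in ("fasta_a", "fasta_b"):
            p = getattr(self, attr)
            if not Path(p).is_file():
                raise ConfigError(f"{attr}: no such file {p!r}")
        for attr in ("annotations_a", "annotations_b", "reference_fasta",
                     "stages_a", "stages_b", "reference_calls"):
            p = getattr(self, attr)
            if p is not None and not Path(p).is_file():
                raise ConfigError(f"{attr}: no such file {p!r}")
        if self.bootstrap_reps < 1:
            raise ConfigError("bootstrap_reps must be >= 1")
        if not 0.0 <= self.min_support <= 1.0:
            raise ConfigError("min_support must be in [0, 1]")
        if not self.functional_vocab:
            raise ConfigError("functional_vocab must be non-empty")
        AlignmentParams(self.matrix, self.gap_open, self.gap_extend)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def attach_annotations(ds: Dataset, ann: Dataset) -> Dataset:
    """Copy GO/Pfam/keyword annotations onto sequence records by accession."""
    out = Dataset(provenance=ds.provenance + ["attach_annotations"])
    for rec in ds:
        if rec.accession in ann:
            a = ann[rec.accession]
            rec.go_terms = set(a.go_terms)
            rec.pfam_terms = set(a.pfam_terms)
            rec.keywords = set(a.keywords)
            if a.name and not rec.name:
                rec.name = a.name
        out.add(rec)
    return out


def run_all(config: RunConfig) -> Path:
    """Execute the whole flow; returns the output directory.

    Any stage failure aborts with the stage name; outputs written before
    the failure are retained for inspection.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "package_version": __version__,
        "python": platform.python_version(),
        "stage_counts": {},
    }
    counts = manifest["stage_counts"]
    stage = "load"
    try:
        ds_a = read_fasta(config.fasta_a, config.species_a)
        ds_b = read_fasta(config.fasta_b, config.species_b)
        if config.annotations_a:
            ds_a = attach_annotations(ds_a, read_annotation_table(config.annotations_a))
        if config.annotations_b:
            ds_b = attach_annotations(ds_b, read_annotation_table(config.annotations_b))
        counts["input_a"], counts["input_b"] = len(ds_a), len(ds_b)

        stage = "filter"
        for tag, key, ds in (("a", "stages_a", ds_a), ("b", "stages_b", ds_b)):
            spath = getattr(config, key)
            if spath:
                stages = load_stage_config(spath)
                filtered, traj = run_pipeline(ds, stages)
                write_table(traj.to_rows(), outdir / f"trajectory_{tag}.tsv")
                counts[f"filtered_{tag}"] = len(filtered)
                if tag == "a":
                    ds_a = filtered
                else:
                    ds_b = filtered

        stage = "dedupe"
        merged = merge_datasets(ds_a, ds_b)
        counts["merged"] = len(merged)
        unique, removed = dedupe(merged, key=config.dedupe_key)  # type: ignore[arg-type]
        counts["unique"] = len(unique)
        counts["duplicates_removed"] = len(removed)

        stage = "phylogeny"
        msa = progressive_align(unique, AlignmentParams(config.matrix, config.gap_open, config.gap_extend))
        # export labels carry the species suffix so the tree is self-describing
        msa = type(msa)(
            ids=[f"{i}_{s}" for i, s in zip(msa.ids, msa.species)],
            species=list(msa.species),
            rows=list(msa.rows),
        )
        tree = bootstrap_supports(
            msa,
            reps=config.bootstrap_reps,
            seed=config.seed,
            deletion=config.deletion,
            coverage=config.coverage,
        )
        write_newick(tree, str(outdir / "tree.nwk"))
        clusters, no_calls = extract_ortholog_clusters(
            tree, config.species_a, config.species_b, config.min_support
        )
        counts["clusters"] = len(clusters)
        counts["no_calls"] = len(no_calls)

        stage = "screen"
        go_vocab = [t for t in config.functional_vocab if t.startswith("GO:")]
        pf_vocab = [t for t in config.functional_vocab if t.startswith("PF")]
        kept: set[str] = set()
        for kind, vocab, name in (("GO", go_vocab, "go"), ("Pfam", pf_vocab, "pfam")):
            if not vocab:
                continue
            pm = build_presence_matrix(ds_b, vocab, kind)  # type: ignore[arg-type]
            write_table(pm.reset_index().rename(columns={"index": "accession"}),
                        outdir / f"presence_{name}.tsv")
            k, _ = screen_by_function(pm)
            kept |= set(k)
        counts["screen_kept"] = len(kept)

        stage = "forest"
        params = AlignmentParams(config.matrix, config.gap_open, config.gap_extend)
        if config.reference_fasta:
            refs = read_fasta(config.reference_fasta, config.species_a)
        else:
            refs = ds_a
        forest = score_forest(ds_b, refs, params)
        stats = compute_threshold(forest, fixed_override=config.threshold_override)
        selected = select_high_correlation(ds_b, forest, stats)
        fit = fit_bimodal(forest, stats)
        counts["forest_selected"] = len(selected)
        write_table(forest.to_rows(set(selected.accessions())), outdir / "forest.tsv")
        manifest["forest"] = {
            "score_mean": stats.score_mean,
            "score_max": stats.score_max,
            "threshold": stats.threshold,
            "fixed_override": stats.fixed_override,
            "lower_mean": fit.lower_mean,
            "lower_sd": fit.lower_sd,
            "upper_count": fit.upper_count,
        }
        if config.make_plots:
            from .forest import plot_bimodal, plot_forest

            plot_forest(forest, stats, outdir / "forest.png")
            plot_bimodal(fit, stats, outdir / "bimodal.png")

        stage = "combine"
        best_ref = dict(zip(forest.query_ids, forest.best_ref))
        scores = {q: float(s) for q, s in zip(forest.query_ids, forest.best_score)}
        table = combine_evidence(
            clusters,
            selected.accessions(),
            kept,
            policy=config.combine_policy,  # type: ignore[arg-type]
            reference_universe=refs.accessions(),
            forest_best_ref=best_ref,
            forest_scores=scores,
        )
        write_table(table.to_rows(), outdir / "ortholog_table.tsv")
        counts["orthologs"] = len(table.by_status("ortholog"))
        counts["needs_verification"] = len(table.by_status("needs_verification"))
        counts["not_found"] = len(table.by_status("not_found"))

        stage = "error"
        if config.reference_calls:
            import pandas as pd

            refcalls = pd.read_csv(config.reference_calls, sep="\t")
            pairs = list(refcalls.itertuples(index=False, name=None))
            est = estimate_error(table, [p[-1] for p in pairs])
            manifest["error_estimate"] = {
                "extras": est.extras,
                "total": est.total,
                "percent": est.percent,
            }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def call_orthologs_from_datasets(
    ds_a: Dataset,
    ds_b: Dataset,
    *,
    params: AlignmentParams | None = None,
    vocab: list[str] | None = None,
    bootstrap_reps: int = 50,
    seed: int = 17,
    min_support: float = 0.5,
    threshold_override: float | None = None,
    policy: str = "intersection_then_rescue",
) -> OrthologTable:
    """In-memory variant of :func:`run_all` for programmatic use.

    Species A is the reference side, species B the candidate side; the
    whole of A serves as the forest reference set.
    """
    params = params or AlignmentParams()
    vocab = vocab or list(DEFAULT_VOCAB)
    merged = merge_datasets(ds_a, ds_b)
    unique, _ = dedupe(merged, key="sequence")
    msa = progressive_align(unique, params)
    species = {r.accession: r.species for r in unique}
    msa = type(msa)(
        ids=[f"{i}_{species[i]}" for i in msa.ids],
        species=list(msa.species),
        rows=list(msa.rows),
    )
    sp_a = ds_a.records[0].species
    sp_b = ds_b.records[0].species
    tree = bootstrap_supports(msa, reps=bootstrap_reps, seed=seed, deletion="pairwise")
    clusters, _ = extract_ortholog_clusters(tree, sp_a, sp_b, min_support)
    go_vocab = [t for t in vocab if t.startswith("GO:")]
    pf_vocab = [t for t in vocab if t.startswith("PF")]
    kept: set[str] = set()
    if go_vocab:
        kept |= set(screen_by_function(build_presence_matrix(ds_b, go_vocab, "GO"))[0])
    if pf_vocab:
        kept |= set(screen_by_function(build_presence_matrix(ds_b, pf_vocab, "Pfam"))[0])
    forest = score_forest(ds_b, ds_a, params)
    stats = compute_threshold(forest, fixed_override=threshold_override)
    selected = select_high_correlation(ds_b, forest, stats)
    return combine_evidence(
        clusters,
        selected.accessions(),
        kept,
        policy=policy,  # type: ignore[arg-type]
        reference_universe=ds_a.accessions(),
        forest_best_ref=dict(zip(forest.query_ids, forest.best_ref)),
        forest_scores={q: float(s) for q, s in zip(forest.query_ids, forest.best_score)},
    )
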