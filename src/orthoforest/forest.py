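"""Population ("forest") analysis of local-alignment scores.

Every candidate protein is scored against every reference protein by
optimal local alignment; each candidate keeps the maximum score over the
references. Plotted per candidate, these best scores look like a forest:
a low "undergrowth" of random-match scores and a few tall "trees" — the
true homologs. The selection cutoff is

    score_threshold = score_mean + 0.5 * (score_max - score_mean),

halfway between the mean and the maximum of the best scores; a fixed
override (e.g. 200 in BLOSUM62 units) may replace it for selection while
both values are reported. The distribution of best scores is bimodal: the
sub-threshold zone resembles a Gaussian (random correlation), the
sparse supra-threshold zone holds the strongly correlated sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import AlignmentParams, batch_scores
from .io import Dataset


@dataclass
class ForestScores:
    """Per-candidate best local-alignment scores against a reference set."""

    query_ids: list[str]
    ref_ids: list[str]
    best_score: np.ndarray  # int, len == len(query_ids)
    best_ref: list[str]
    matrix: np.ndarray | None = None  # optional full (query x ref) scores

    def __post_init__(self) -> None:
        assert len(self.query_ids) == len(self.best_score) == len(self.best_ref)
        assert (self.best_score >= 0).all()

    def to_rows(self, selected: set[str] | None = None) -> list[dict[str, object]]:
        sel = selected or set()
        return [
            {
                "query": q,
                "best_ref": r,
                "best_score": int(s),
                "selected": int(q in sel),
            }
            for q, r, s in zip(self.query_ids, self.best_ref, self.best_score)
        ]


@dataclass
class ThresholdStats:
    """Mean/max of best scores, the halfway threshold, optional override."""

    score_mean: float
    score_max: float
    threshold: float
    fixed_override: float | None = None

    def __post_init__(self) -> None:
        assert self.score_mean <= self.threshold <= self.score_max

    @property
    def effective(self) -> float:
        """The value selection actually uses."""
        return self.threshold if self.fixed_override is None else self.fixed_override


@dataclass
class BimodalFit:
    """Gaussian null of the sub-threshold zone + census of the upper zone."""

    lower_mean: float | None
    lower_sd: float | None
    lower_n: int
    upper_count: int
    upper_range: tuple[float, float] | None
    hist_edges: np.ndarray = field(default_factory=lambda: np.array([]))
    hist_counts: np.ndarray = field(default_factory=lambda: np.array([]))
    fitted: bool = True


def score_forest(
    population: Dataset, references: Dataset, params: AlignmentParams | None = None
) -> ForestScores:
    """Score every population sequence against every reference.

    Ties in the per-query maximum are broken by reference input order, so
    the result is deterministic.
    """
    if len(population) == 0 or len(references) == 0:
        raise ValueError("population and references must be non-empty")
    queries = [r.sequence for r in population]
    refs = [r.sequence for r in references]
    mat = batch_scores(queries, refs, params)
    best_idx = np.argmax(mat, axis=1)  # argmax takes the first maximum
    ref_ids = references.accessions()
    return ForestScores(
        query_ids=population.accessions(),
        ref_ids=ref_ids,
        best_score=mat[np.arange(len(queries)), best_idx],
        best_ref=[ref_ids[i] for i in best_idx],
        matrix=mat,
    )


def compute_threshold(
    f: ForestScores, fixed_override: float | None = None
) -> ThresholdStats:
    """threshold = mean + 0.5 * (max - mean) over per-query best scores."""
    if len(f.best_score) == 0:
        raise ValueError("empty forest")
    mean = float(np.mean(f.best_score))
    mx = float(np.max(f.best_score))
    return ThresholdStats(
        score_mean=mean,
        score_max=mx,
        threshold=mean + 0.5 * (mx - mean),
        fixed_override=fixed_override,
    )


def fit_bimodal(f: ForestScores, t: ThresholdStats, bins: int = 30) -> BimodalFit:
    """Characterize the two zones of the best-score distribution.

    The sub-threshold ("undergrowth") scores are summarized by their sample
    mean and SD — the Gaussian null for random correlation; the
    supra-threshold zone by its count and score range. With fewer than two
    sub-threshold scores the Gaussian fit is skipped and flagged.
    """
    scores = np.asarray(f.best_score, dtype=float)
    cut = t.effective
    lower = scores[scores <= cut]
    upper = scores[scores > cut]
    edges = np.histogram_bin_edges(scores, bins=bins)
    counts, _ = np.histogram(scores, bins=edges)
    if len(lower) >= 2:
        fit = BimodalFit(
            lower_mean=float(np.mean(lower)),
            lower_sd=float(np.std(lower, ddof=1)),
            lower_n=len(lower),
            upper_count=len(upper),
            upper_range=(float(upper.min()), float(upper.max())) if len(upper) else None,
            hist_edges=edges,
            hist_counts=counts,
        )
    else:
        fit = BimodalFit(
            lower_mean=None,
            lower_sd=None,
            lower_n=len(lower),
            upper_count=len(upper),
            upper_range=(float(upper.min()), float(upper.max())) if len(upper) else None,
            hist_edges=edges,
            hist_counts=counts,
            fitted=False,
        )
    return fit


def select_high_correlation(
    population: Dataset, f: ForestScores, t: ThresholdStats
) -> Dataset:
    """Queries whose best score strictly exceeds the effective threshold."""
    cut = t.effective
    keep = {
        q for q, s in zip(f.query_ids, f.best_score) if s > cut
    }
    out = population.subset(keep)
    out.log(f"select_high_correlation threshold={cut}")
    return out


def plot_forest(f: ForestScores, t: ThresholdStats, path) -> None:
    """Bar plot of best scores per candidate with the threshold line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, len(f.query_ids) * 0.12), 4))
    ax.bar(range(len(f.query_ids)), f.best_score, width=0.8, color="#2a6f4e")
    ax.axhline(t.effective, color="crimson", ls="--", label=f"threshold {t.effective:.0f}")
    ax.set_xlabel("candidate")
    ax.set_ylabel("best local-alignment score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_bimodal(fit: BimodalFit, t: ThresholdStats, path) -> None:
    """Histogram of best scores split into lower/upper zones."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    centers = 0.5 * (fit.hist_edges[:-1] + fit.hist_edges[1:])
    colors = ["#2a6f4e" if c <= t.effective else "#1f4e9c" for c in centers]
    ax.bar(centers, fit.hist_counts, width=np.diff(fit.hist_edges), color=colors)
    ax.axvline(t.effective, color="crimson", ls="--")
    ax.set_xlabel("best score")
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
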