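# Methods

This note records the models implemented, the defaults chosen, and the
numerical decisions a user should know before trusting or tuning a run.

## Sequence model and identifiers

Protein sequences are uppercase strings over the 20 standard amino acids
plus the ambiguity codes `B Z X U O`; anything else is a fatal input
error (silent coercion hides upstream corruption). Accessions are the
FASTA header token before the first whitespace or `|`; a trailing `*`
(stop codon artifact) is stripped. GO terms must match `GO:\d{7}` and
Pfam accessions `PF\d{5}`; malformed terms in annotation tables are
dropped and counted, never guessed at.

## Staged filtering

A filter stage is a labelled set of rules (`has_any`, `has_all`,
`lacks_all`, `text_contains_any` over GO/Pfam/keyword/name fields) with
an AND/OR connective. Stages apply sequentially, so survivor sets are
nested and per-stage counts are non-increasing; the run validates both
invariants. The shipped `configs/carotenoid_stages.yaml` encodes the
carotenoid screen's structure (chloroplast localization → pathway GO
terms → pathway Pfam domains) with identifiers quoted in the study text;
exact published per-stage lists live in supplementary material, so a
stage file reproducing a specific published trajectory must be supplied
by the user.

The redundancy screen removes records with an identical key (default:
exact sequence identity; accession or either-of also available). First
occurrence wins, and every removed record is reported with its retained
representative, because "which copy survived" matters when accessions
carry species provenance.

## Local alignment

Scores come from the Gotoh affine-gap Smith–Waterman recurrence: a gap
of length *k* costs `open + (k−1)·extend`, defaults BLOSUM62 / 11 / 1
(the field-standard protein defaults). The DP fill is numba-compiled;
the score-only population kernel keeps two rolling rows per gap state so
the all-candidates × all-references "forest" matrix is linear in memory.
The implementation is validated against an exhaustive
alignment-enumeration oracle on short sequences and cross-checked
against Biopython's `PairwiseAligner` on hundreds of random pairs.

## Forest analysis

For each candidate, the best score against the whole reference set is
retained along with the argmax reference. The selection threshold is

```
ScoreThreshold = ScoreMean + 0.5 · (ScoreMax − ScoreMean)
```

over the per-candidate best scores, with selection on a strict `>`.
A fixed override (conventionally 200 for this protein-family size and
scoring scheme) replaces the formula when given; the formula adapts to
the population but is deliberately aggressive on small heterogeneous
populations — with few families, weaker true families can fall below
halfway-to-max, which is why the fixed cutoff exists. The best-score
distribution is summarized as a two-zone ("bimodal") description:
sample mean/SD of the sub-threshold undergrowth as a Gaussian null, and
a count/range census of the sparse upper zone. No EM mixture fitting is
attempted — with typical upper-zone counts of tens, moments of the
thresholded split are more honest than a fitted mixture.

## Multiple alignment and distances

Progressive alignment: 3-mer count distances → UPGMA (average-linkage
`scipy` hierarchy) guide tree → profile–profile global Needleman–Wunsch
on column frequency vectors under the same substitution matrix. This is
a deliberately standard progressive scheme; for publication-grade trees
an external aligner's output can be supplied (`phylo build --aligned`).

Distances are p-distance or Poisson-corrected `−ln(1−p)`, with three
gap-deletion policies: `complete` (drop any column with a gap/ambiguity),
`partial` (drop columns below a coverage fraction, default 0.8), and
`pairwise` (per-pair valid columns). **`pairwise` is the pipeline
default**: the population entering the tree stage spans many unrelated
families, and a global MSA of unrelated families leaves almost no
gap-free columns — complete deletion then produces degenerate distances.
Saturated pairs (p → 1 under Poisson) are capped at 10.0 and flagged;
zero-overlap pairs under pairwise deletion get the cap too.

## Trees, supports, clusters

Neighbor joining follows Saitou–Nei with the standard Q-criterion; ties
break lexicographically on the minimum leaf label beneath each node, so
topologies are deterministic. Negative branch lengths are clamped to
zero and noted. The root is a display trifurcation, not a clade. NJ is
validated by exact recovery (Robinson–Foulds 0) of hundreds of random
additive matrices.

Bootstrap supports are nonparametric column resamples; a clade's support
is the fraction of replicate trees containing the same bipartition
(canonicalized by an anchor taxon). Supports are reported in [0, 1];
Newick inputs with percentage supports are normalized and flagged.

Cluster extraction: for every reference-species leaf, the smallest clade
containing it, ≥1 target-species leaf and no second reference leaf is a
candidate cluster, emitted iff its support ≥ `min_support` (default 0.5;
unannotated clades count as fully supported). The accepted clade is then
widened through successive non-root ancestors while each keeps a single
reference leaf and clears the support floor, so `((ref,t1),t2)` and
`(ref,(t1,t2))` both yield the one-to-many call `{t1, t2}`; the reported
support is the minimum along the accepted path. Because every accepted
clade holds exactly one reference leaf, no target can be claimed twice.

`min_support` presets: 0.5 is the default; 0.75 mirrors the common
">75%" significance convention; an exploratory 0.11 admits the
permissive low-support band some studies inspect manually. Choose
explicitly; the default is the compromise.

## Evidence combination and error

The default policy, `intersection_then_rescue`, calls **ortholog** iff
phylogenetic and functional-screen evidence agree, demotes forest-only
candidates to **needs_verification** (with their best reference and
score attached), and reports unmatched references as **not_found**.
Plain `intersection`, `union`, and score-`weighted` policies are also
available. The error statistic against an independent call set is
`extras / total` over all called rows (unverified rows included),
rounded half-up to one decimal — e.g. 4/72 → 5.6%. Half-up (via
`decimal`) rather than banker's rounding, to match how such percentages
are conventionally printed.

## Synthetic generator

Each family is an ancestral random sequence (length uniform in
[150, 250]); each species copy mutates it independently — per-site
substitution at the configured rate (uniform over the 19 alternatives),
geometric-length indels at a separate rate. Decoys are
residue-frequency-matched shuffles of the family pool, so they match
composition but not order; annotation noise flips term presence
symmetrically. Generation is byte-identical under a fixed seed
(`numpy.random.default_rng` throughout). Scope: the generator plants
clean one-to-one and one-to-many families for validation; it does not
model domain shuffling, fragmentary sequences, or rate heterogeneity
across sites, so recovery statistics on it are upper bounds for real
proteomes.

Measured behavior: planted-pair recovery F1 is 1.0 across 20 seeds at
5% substitution divergence (5 families + 5 decoys per species) and the
median degrades monotonically through 0.2 / 0.4 / 0.6 divergence —
the pipeline's working range matches the intra-genus divergence it was
designed for.

## Not implemented

- A score "mix factor" for blending forest and support evidence into a
  single scalar: left out because the combination policies make the
  evidence channels explicit instead of collapsing them.
- EM mixture fitting of the score distribution (see above).
- Tree-reconciliation (species-tree-aware) ortholog calling; extraction
  is deliberately tree-agnostic so externally built trees drop in.
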