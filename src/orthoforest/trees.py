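"""Distance-based phylogenetics and ortholog-cluster extraction.

The bundled estimator is neighbor joining (Saitou–Nei) on p- or
Poisson-corrected distances computed from an alignment after gap-column
deletion, with clade support from a column (nonparametric) bootstrap.
Externally computed support-annotated Newick trees are accepted as drop-in
input everywhere a tree is consumed — ortholog calling is tree-agnostic.

Ortholog clusters are read off the tree: for each reference-species leaf,
the smallest clade that contains it, at least one target-species leaf and
no second reference-species leaf is a putative ortholog group (one-to-many
allowed), emitted when its support clears a configurable floor.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .msa import MSA, GAP

MISSING = {GAP, "X", ".", "?"}
#: distances are capped here when the Poisson correction diverges (p → 1)
DISTANCE_CEILING = 10.0


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances over accessions, with provenance flags."""

    ids: list[str]
    values: np.ndarray
    deletion_mode: str = "complete"
    correction: str = "poisson"
    n_columns_used: int = 0
    capped_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values
        assert v.shape == (len(self.ids), len(self.ids))
        assert np.allclose(v, v.T), "distance matrix must be symmetric"
        assert np.allclose(np.diag(v), 0.0)
        assert (v >= 0).all() and np.isfinite(v).all()


@dataclass
class OrthologCluster:
    """One reference leaf with its co-claded target-species leaves."""

    reference_member: str
    ortholog_members: list[str]
    support: float
    clade_size: int

    def __post_init__(self) -> None:
        assert self.ortholog_members
        assert 0.0 <= self.support <= 1.0


@dataclass
class PhyloTree:
    """A (possibly support-annotated) tree plus run flags."""

    tree: TreeNode
    notes: list[str] = field(default_factory=list)

    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]


def _column_mask(rows: list[str], deletion: str, coverage: float) -> np.ndarray:
    arr = np.array([list(r) for r in rows])
    missing = np.isin(arr, list(MISSING))
    if deletion == "complete":
        return ~missing.any(axis=0)
    if deletion == "partial":
        return (1.0 - missing.mean(axis=0)) >= coverage
    if deletion == "pairwise":
        return np.ones(arr.shape[1], dtype=bool)
    raise ValueError(f"unknown deletion mode {deletion!r}")


def distance_matrix(
    msa: MSA,
    deletion: str = "complete",
    coverage: float = 0.8,
    correction: str = "poisson",
) -> DistanceMatrix:
    """Pairwise distances from an alignment.

    Columns are first pruned: *complete* deletion drops any column holding a
    gap or missing residue in any row; *partial* keeps columns whose
    non-missing coverage is at least ``coverage``; *pairwise* keeps all
    columns and lets each pair use its own valid set. For each pair, the
    p-distance is mismatches over pairwise-valid columns; the Poisson
    correction is d = −ln(1 − p), capped at :data:`DISTANCE_CEILING` (and
    flagged) when it diverges. Pairs sharing no valid column get the
    ceiling distance outright.
    """
    if len(msa.rows) < 2:
        raise ValueError("need at least 2 sequences")
    if correction not in ("p-distance", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    mask = _column_mask(msa.rows, deletion, coverage)
    if not mask.any():
        raise ValueError("no alignment columns remain after deletion")
    arr = np.array([list(r) for r in msa.rows])[:, mask]
    missing = np.isin(arr, list(MISSING))
    n = len(msa.ids)
    d = np.zeros((n, n))
    capped: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            valid = ~(missing[i] | missing[j])
            nv = int(valid.sum())
            if nv == 0:
                dist = DISTANCE_CEILING
                capped.append((msa.ids[i], msa.ids[j]))
            else:
                p = float((arr[i, valid] != arr[j, valid]).sum()) / nv
                if correction == "p-distance":
                    dist = p
                elif p >= 1.0:
                    dist = DISTANCE_CEILING
                    capped.append((msa.ids[i], msa.ids[j]))
                else:
                    dist = min(-np.log(1.0 - p), DISTANCE_CEILING)
            d[i, j] = d[j, i] = max(dist, 0.0)
    return DistanceMatrix(
        ids=list(msa.ids),
        values=d,
        deletion_mode=f"partial({coverage})" if deletion == "partial" else deletion,
        correction=correction,
        n_columns_used=int(mask.sum()),
        capped_pairs=capped,
    )


def _clamp(x: float, notes: list[str], context: str) -> float:
    if x < 0:
        notes.append(f"negative branch length clamped to 0 at {context}")
        return 0.0
    return x


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Canonical neighbor joining (Saitou–Nei Q-criterion).

    Deterministic: Q-ties are broken by the lexicographically smallest
    (minimum-leaf-name) node pair. Negative branch lengths are clamped to
    zero and noted. Two taxa give a single edge split evenly; the final
    three-node join yields the standard unrooted (trifurcating) tree.
    """
    if not np.allclose(dm.values, dm.values.T):
        raise ValueError("distance matrix must be symmetric")
    notes: list[str] = []
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=name) for name in dm.ids]
    labels = list(dm.ids)  # min leaf name per active node, for tie-breaks
    D = dm.values.astype(float).copy()
    if n == 2:
        root = TreeNode()
        for node in nodes:
            node.length = D[0, 1] / 2.0
            root.append(node)
        return PhyloTree(tree=root, notes=notes)
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                i, j = active[ai], active[bi]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = (q, tuple(sorted((labels[i], labels[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        nodes[i].length = _clamp(li, notes, f"join({labels[i]},{labels[j]})")
        nodes[j].length = _clamp(lj, notes, f"join({labels[i]},{labels[j]})")
        parent.append(nodes[i])
        parent.append(nodes[j])
        # new distances replace slot i; slot j is retired
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - dij)
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        active.remove(j)
    # final three-way join
    i, j, k = active
    root = TreeNode()
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = _clamp(ln, notes, "final join")
        root.append(nodes[idx])
    return PhyloTree(tree=root, notes=notes)


def _bipartitions(tree: TreeNode, anchor: str) -> set[frozenset[str]]:
    """Non-trivial bipartitions, canonicalized as the side without ``anchor``."""
    all_leaves = frozenset(t.name for t in tree.tips())
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue  # trivial split
        if anchor in side:
            side = all_leaves - side
        out.add(side)
    return out


def bootstrap_supports(
    msa: MSA,
    reps: int = 100,
    seed: int = 0,
    deletion: str = "complete",
    coverage: float = 0.8,
    correction: str = "poisson",
) -> PhyloTree:
    """NJ tree with column-bootstrap clade supports (normalized 0–1).

    Alignment columns are resampled with replacement per replicate, the
    tree rebuilt, and each internal bipartition of the point-estimate tree
    annotated with the fraction of replicates in which it recurs.
    Bit-reproducible for a fixed seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    point_dm = distance_matrix(msa, deletion, coverage, correction)
    point = nj_tree(point_dm)
    anchor = min(msa.ids)
    counts: dict[frozenset[str], int] = {
        bp: 0 for bp in _bipartitions(point.tree, anchor)
    }
    ncol = msa.n_cols
    arr = np.array([list(r) for r in msa.rows])
    done = 0
    for _ in range(reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = ["".join(row) for row in arr[:, cols]]
        rep_msa = MSA(ids=list(msa.ids), species=list(msa.species), rows=rep_rows)
        try:
            rep_tree = nj_tree(distance_matrix(rep_msa, deletion, coverage, correction))
        except ValueError:
            continue  # replicate lost all columns; skip
        rep_bps = _bipartitions(rep_tree.tree, anchor)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
        done += 1
    all_leaves = frozenset(msa.ids)
    for node in point.tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(all_leaves - side) < 2:
            node.support = 1.0  # trivial split: present in every tree
            continue
        if anchor in side:
            side = all_leaves - side
        node.support = counts.get(side, 0) / done if done else 0.0
    point.notes.append(f"bootstrap reps={reps} seed={seed} done={done}")
    return point


_NUM_RE = re.compile(r"^\d+(\.\d+)?([eE][+-]?\d+)?$")


def read_newick(text_or_path: str) -> PhyloTree:
    """Parse a Newick tree; numeric internal labels become supports.

    Support values greater than 1 are interpreted as percentages, divided
    by 100 and flagged in the notes.
    """
    text = text_or_path
    if "(" not in text:  # looks like a path
        with open(text_or_path) as fh:
            text = fh.read()
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # registry sniffer is chatty
            tree = TreeNode.read(
                _io.StringIO(text), format="newick", convert_underscores=False
            )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    notes: list[str] = []
    tree.assign_supports()
    for node in tree.non_tips(include_self=True):
        sup = getattr(node, "support", None)
        if sup is not None and sup > 1.0:
            notes.append(f"support {sup:g} read as percentage")
            node.support = sup / 100.0
    return PhyloTree(tree=tree, notes=notes)


def write_newick(pt: PhyloTree, path: str | None = None) -> str:
    """Serialize with supports as internal-node labels."""
    tree = pt.tree.copy()
    for node in tree.non_tips(include_self=False):
        if getattr(node, "support", None) is not None:
            node.name = None  # the writer emits the support as the label
    out = _io.StringIO()
    tree.write(out)
    text = out.getvalue().strip()
    # the writer quotes labels containing '_'; ours are plain identifiers
    text = re.sub(r"'([^'\s,():;]+)'", r"\1", text)
    if path:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def leaf_species(label: str, known_tags: set[str]) -> tuple[str, str] | None:
    """(accession, species) from a ``ACC_TAG`` or ``TAG_ACC`` leaf label."""
    if "_" in label:
        head, _, tail = label.rpartition("_")
        if tail in known_tags:
            return head, tail
        head2, _, tail2 = label.partition("_")
        if head2 in known_tags:
            return tail2, head2
    return None


def extract_ortholog_clusters(
    pt: PhyloTree,
    ref_species: str,
    target_species: str,
    min_support: float = 0.5,
) -> tuple[list[OrthologCluster], list[str]]:
    """Read ortholog groups off a support-annotated tree.

    For every reference-species leaf, the smallest clade containing it, at
    least one target-species leaf and no other reference-species leaf is a
    candidate cluster; it is emitted when the clade's support meets
    ``min_support`` (unannotated clades are treated as fully supported).
    The clade is then widened through successive non-root ancestors as long
    as each still holds a single reference leaf and clears the support
    floor, so caterpillar shapes like ``((ref,t1),t2)`` yield the same
    one-to-many call as ``(ref,(t1,t2))``; the reported support is the
    minimum along the accepted path.  The root is never used for widening
    because its trifurcation is an artefact of display, not a clade.
    Returns (clusters, no-call reference accessions). A target leaf can
    never be claimed by two reference leaves because every accepted clade
    holds exactly one reference leaf, so two such clades cannot nest.
    """
    tags = {ref_species, target_species}
    leaves = list(pt.tree.tips())
    parsed: dict[int, tuple[str, str]] = {}
    found_tags = set()
    for leaf in leaves:
        got = leaf_species(leaf.name, tags)
        if got:
            parsed[id(leaf)] = got
            found_tags.add(got[1])
    for tag in (ref_species, target_species):
        if tag not in found_tags:
            raise ValueError(f"unknown species tag {tag!r}: no matching leaves")
    clusters: list[OrthologCluster] = []
    no_calls: list[str] = []
    for leaf in leaves:
        got = parsed.get(id(leaf))
        if not got or got[1] != ref_species:
            continue
        acc = got[0]

        def census(node):
            tips = list(node.tips())
            refs = [
                parsed[id(t)][0]
                for t in tips
                if id(t) in parsed and parsed[id(t)][1] == ref_species
            ]
            targets = [
                parsed[id(t)][0]
                for t in tips
                if id(t) in parsed and parsed[id(t)][1] == target_species
            ]
            support = getattr(node, "support", None)
            return refs, targets, (1.0 if support is None else float(support)), len(tips)

        node = leaf.parent
        emitted = None
        while node is not None:
            ref_here, targets, support, size = census(node)
            if len(ref_here) > 1:
                break  # clade now holds another reference leaf: stop
            if targets:
                if support >= min_support:
                    emitted = (sorted(targets), support, size)
                # smallest qualifying clade decides, pass or fail
                break
            node = node.parent
        if emitted is not None:
            # widen through non-root ancestors that keep a single reference
            # leaf and clear the support floor
            members, path_support, size = emitted
            node = node.parent
            while node is not None and node.parent is not None:
                ref_here, targets, support, wide_size = census(node)
                if len(ref_here) > 1 or support < min_support:
                    break
                members = sorted(targets)
                path_support = min(path_support, support)
                size = wide_size
                node = node.parent
            clusters.append(
                OrthologCluster(
                    reference_member=acc,
                    ortholog_members=members,
                    support=path_support,
                    clade_size=size,
                )
            )
        else:
            no_calls.append(acc)
    return clusters, no_calls
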