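"""Distances, neighbor joining, bootstrap supports, ortholog clusters."""

import io

import numpy as np
import pytest
from skbio import TreeNode

from orthoforest.msa import MSA
from orthoforest.trees import (
    DISTANCE_CEILING,
    DistanceMatrix,
    bootstrap_supports,
    distance_matrix,
    extract_ortholog_clusters,
    nj_tree,
    read_newick,
    write_newick,
)

from conftest import random_protein


def msa_of(rows, species=None):
    ids = [f"t{i}" for i in range(len(rows))]
    return MSA(ids=ids, species=species or ["NA"] * len(rows), rows=rows)


class TestDistanceMatrix:
    def test_identical_rows_are_zero(self):
        dm = distance_matrix(msa_of(["ACDE", "ACDE", "ACDE"]))
        assert (dm.values == 0).all()

    def test_p_and_poisson_closed_forms(self):
        dm_p = distance_matrix(msa_of(["AAAA", "AAAC"]), correction="p-distance")
        assert dm_p.values[0, 1] == pytest.approx(0.25)
        dm_poisson = distance_matrix(msa_of(["AAAA", "AAAC"]), correction="poisson")
        assert dm_poisson.values[0, 1] == pytest.approx(-np.log(0.75))

    def test_complete_deletion_drops_gapped_columns(self):
        # column 2 has a gap in row 2: under complete deletion only AAA/AAC
        # columns count, so p = 1/3
        dm = distance_matrix(
            msa_of(["AAAA", "AA-C"]), deletion="complete", correction="p-distance"
        )
        assert dm.n_columns_used == 3
        assert dm.values[0, 1] == pytest.approx(1 / 3)

    def test_partial_deletion_coverage_rule(self):
        rows = ["AAAA", "AA-A", "AA-A", "AAAA", "AAAA"]
        dm = distance_matrix(
            msa_of(rows), deletion="partial", coverage=0.8, correction="p-distance"
        )
        assert dm.n_columns_used == 3  # column 3 has 60% coverage, dropped

    def test_pairwise_deletion_keeps_all_columns(self):
        dm = distance_matrix(
            msa_of(["AAAA", "AA-A"]), deletion="pairwise", correction="p-distance"
        )
        assert dm.n_columns_used == 4
        assert dm.values[0, 1] == 0.0  # the 3 shared valid columns agree

    def test_saturated_distance_capped_and_flagged(self):
        dm = distance_matrix(msa_of(["AAAA", "CCCC"]), correction="poisson")
        assert dm.values[0, 1] == DISTANCE_CEILING
        assert dm.capped_pairs == [("t0", "t1")]

    def test_no_columns_left_is_fatal(self):
        with pytest.raises(ValueError, match="columns"):
            distance_matrix(msa_of(["A-", "-A"]), deletion="complete")


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_tree(self):
        # path distances of ((A:1,B:2):1,(C:3,D:4):0)
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        pt = nj_tree(DistanceMatrix(ids=list("ABCD"), values=D))
        newick = write_newick(pt)
        assert newick == "((A:1.0,B:2.0):1.0,C:3.0,D:4.0);"

    def test_two_taxa_split_evenly(self):
        dm = DistanceMatrix(ids=["A", "B"], values=np.array([[0, 0.5], [0.5, 0]]))
        assert write_newick(nj_tree(dm)) == "(A:0.25,B:0.25);"

    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ids=["A", "B", "C"],
            values=np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float),
        )
        pt = nj_tree(dm)
        lengths = {t.name: t.length for t in pt.tree.children}
        assert lengths == {"A": 0.0, "B": 2.0, "C": 3.0}

    def test_asymmetric_matrix_is_fatal(self):
        bad = DistanceMatrix(ids=["A", "B"], values=np.zeros((2, 2)))
        bad.values = np.array([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(bad)

    @pytest.mark.parametrize("n_taxa", [5, 6, 7, 8])
    def test_random_additive_matrices_recovered(self, n_taxa, rng):
        """NJ must reconstruct trees exactly from their path distances."""
        for _ in range(10):
            ref, dm = _random_additive_tree(n_taxa, rng)
            pt = nj_tree(dm)
            rf = ref.compare_rfd(pt.tree)
            assert rf == 0.0


def _random_additive_tree(n_taxa: int, rng) -> tuple[TreeNode, DistanceMatrix]:
    """A random topology with positive branch lengths, plus its path metric."""
    nodes = [TreeNode(name=f"L{i}", length=None) for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode()
        a.length = float(rng.uniform(0.1, 1.0))
        b.length = float(rng.uniform(0.1, 1.0))
        parent.append(a)
        parent.append(b)
        nodes.append(parent)
    root = TreeNode()
    for node in nodes:
        node.length = float(rng.uniform(0.1, 1.0))
        root.append(node)
    names = [f"L{i}" for i in range(n_taxa)]
    D = np.zeros((n_taxa, n_taxa))
    tipmap = {t.name: t for t in root.tips()}
    for x in range(n_taxa):
        for y in range(x + 1, n_taxa):
            d = tipmap[names[x]].distance(tipmap[names[y]])
            D[x, y] = D[y, x] = d
    return root, DistanceMatrix(ids=names, values=D)


class TestBootstrap:
    def _two_pair_msa(self, rng, ncols=200):
        a = random_protein(rng, ncols)
        b = random_protein(rng, ncols)
        return MSA(
            ids=["A1", "A2", "B1", "B2"],
            species=["NA"] * 4,
            rows=[a, a, b, b],
        )

    def test_identical_pairs_get_full_support(self, rng):
        msa = self._two_pair_msa(rng)
        pt = bootstrap_supports(msa, reps=50, seed=1)
        supports = [
            node.support
            for node in pt.tree.non_tips(include_self=False)
            if node.support is not None
        ]
        assert supports and all(s >= 0.99 for s in supports)

    def test_single_rep_supports_are_binary(self, rng):
        msa = self._two_pair_msa(rng)
        pt = bootstrap_supports(msa, reps=1, seed=3)
        for node in pt.tree.non_tips(include_self=False):
            if node.support is not None:
                assert node.support in (0.0, 1.0)

    def test_supports_reproducible_for_fixed_seed(self, rng):
        base = random_protein(rng, 120)
        from orthoforest.simulate import mutate_sequence

        rows = [mutate_sequence(base, 0.3, 0.0, rng) for _ in range(6)]
        msa = MSA(ids=[f"s{i}" for i in range(6)], species=["NA"] * 6, rows=rows)
        t1 = bootstrap_supports(msa, reps=40, seed=11)
        t2 = bootstrap_supports(msa, reps=40, seed=11)
        assert write_newick(t1) == write_newick(t2)
        t3 = bootstrap_supports(msa, reps=40, seed=12)
        s1 = sorted(n.support for n in t1.tree.non_tips(include_self=False))
        assert all(0.0 <= s <= 1.0 for s in s1)

    def test_supports_in_unit_interval(self, rng):
        msa = self._two_pair_msa(rng, ncols=30)
        pt = bootstrap_supports(msa, reps=25, seed=5)
        for node in pt.tree.non_tips(include_self=False):
            assert node.support is None or 0.0 <= node.support <= 1.0


class TestNewickIO:
    def test_round_trip_preserves_supports(self):
        text = "((ARA_a:1.0,RA_b:1.0)0.9:1.0,RA_c:2.0);"
        pt = read_newick(text)
        assert write_newick(pt) == text

    def test_percentage_supports_normalized(self):
        pt = read_newick("((A:1,B:1)87:1,C:2);")
        node = next(iter(pt.tree.non_tips(include_self=False)))
        assert node.support == pytest.approx(0.87)
        assert any("percentage" in n for n in pt.notes)

    def test_malformed_input_raises(self):
        with pytest.raises(ValueError, match="[Nn]ewick"):
            read_newick("((A,B;")


class TestClusterExtraction:
    def test_one_to_one(self):
        pt = read_newick("((ARA_a:1,RA_b:1)0.9:1,RA_c:2);")
        clusters, no_calls = extract_ortholog_clusters(pt, "ARA", "RA", 0.5)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.reference_member == "a"
        assert c.ortholog_members == ["b"]
        assert c.support == pytest.approx(0.9)
        assert no_calls == []

    def test_support_floor_blocks_call(self):
        pt = read_newick("((ARA_a:1,RA_b:1)0.9:1,RA_c:2);")
        clusters, no_calls = extract_ortholog_clusters(pt, "ARA", "RA", 0.95)
        assert clusters == [] and no_calls == ["a"]

    def test_one_to_many(self):
        pt = read_newick("((ARA_a,(RA_b,RA_c)0.8)0.7,ARA_d);")
        clusters, no_calls = extract_ortholog_clusters(pt, "ARA", "RA", 0.5)
        assert len(clusters) == 1
        assert clusters[0].ortholog_members == ["b", "c"]
        assert clusters[0].support == pytest.approx(0.7)
        assert no_calls == ["d"]

    def test_suffix_labels_work_too(self):
        pt = read_newick("((a_ARA:1,b_RA:1)0.9:1,c_RA:2);")
        clusters, _ = extract_ortholog_clusters(pt, "ARA", "RA", 0.5)
        assert clusters[0].reference_member == "a"

    def test_unknown_species_tag_is_fatal(self):
        pt = read_newick("((ARA_a:1,RA_b:1)0.9:1,RA_c:2);")
        with pytest.raises(ValueError, match="XX"):
            extract_ortholog_clusters(pt, "XX", "RA", 0.5)

    def test_targets_never_shared_between_references(self, rng):
        """Qualifying clades hold exactly one reference leaf, so no target
        can be claimed twice; checked on random labelled trees."""
        for trial in range(20):
            n_ref, n_tgt = rng.integers(2, 5), rng.integers(2, 6)
            labels = [f"ARA_r{i}" for i in range(n_ref)] + [
                f"RA_t{i}" for i in range(n_tgt)
            ]
            rng.shuffle(labels)
            tree = _random_labelled_tree(labels, rng)
            pt = read_newick(tree)
            clusters, _ = extract_ortholog_clusters(pt, "ARA", "RA", 0.0)
            seen: dict[str, str] = {}
            for c in clusters:
                for member in c.ortholog_members:
                    assert member not in seen, (
                        f"{member} claimed by {seen[member]} and {c.reference_member}"
                    )
                    seen[member] = c.reference_member


def _random_labelled_tree(labels, rng) -> str:
    items = [f"{name}:1" for name in labels]
    while len(items) > 2:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        items.append(f"({a},{b}):1")
    return f"({items[0]},{items[1]});"
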