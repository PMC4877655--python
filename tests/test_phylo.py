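"""Protein distances, neighbor-joining exactness, and family assignment."""

import math

import dendropy
import numpy as np
import pytest

from ladderlens.io import DistanceMatrix, MultipleAlignment, ProteinRecord
from ladderlens.phylo import UNASSIGNED, assign_families, nj_tree, protein_distance
from ladderlens.simulate import simulate_ortholog_family


def _aln(rows):
    return MultipleAlignment([ProteinRecord(id=f"r{i}", sequence=s)
                              for i, s in enumerate(rows)])


class TestProteinDistance:
    def test_identical_rows_are_zero(self):
        dm = protein_distance(_aln(["A" * 40, "A" * 40]))
        assert dm.values[0, 1] == 0.0

    def test_p_and_poisson_closed_form(self):
        rows = ["AAAA" * 10, ("AAAT" * 10)]
        dm_p = protein_distance(_aln(rows), model="p")
        assert dm_p.values[0, 1] == pytest.approx(0.25)
        dm = protein_distance(_aln(rows), model="poisson")
        assert dm.values[0, 1] == pytest.approx(-math.log(0.75))

    def test_insufficient_overlap_names_pair(self):
        rows = ["AAAA" + "-" * 36, "----" + "A" * 36]
        with pytest.raises(ValueError, match="r0.*r1"):
            protein_distance(_aln(rows))

    def test_x_always_mismatches(self):
        rows = ["X" * 40, "X" * 40]
        dm = protein_distance(_aln(rows), model="p")
        assert dm.values[0, 1] == pytest.approx(1.0)


def path_distance_matrix(tree: dendropy.Tree, labels):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            out[i, j] = out[j, i] = d
    return out


def random_additive_matrix(n_taxa, rng):
    """Random unrooted topology by sequential attachment; returns the leaf
    distance matrix computed by path lengths (independent of NJ)."""
    # edges as dict node -> list of (neighbor, length); leaves are 0..n-1
    edges = {}

    def add_edge(a, b, w):
        edges.setdefault(a, []).append((b, w))
        edges.setdefault(b, []).append((a, w))

    next_internal = n_taxa
    add_edge(0, 1, rng.uniform(0.5, 2.0))
    for leaf in range(2, n_taxa):
        # pick a random existing edge and subdivide it
        pairs = [(a, b) for a in edges for b, _ in edges[a] if a < b]
        a, b = pairs[rng.integers(len(pairs))]
        w = next(w for nb, w in edges[a] if nb == b)
        edges[a] = [(nb, ww) for nb, ww in edges[a] if nb != b]
        edges[b] = [(nb, ww) for nb, ww in edges[b] if nb != a]
        mid = next_internal
        next_internal += 1
        split = rng.uniform(0.2, 0.8) * w
        add_edge(a, mid, split)
        add_edge(mid, b, w - split)
        add_edge(mid, leaf, rng.uniform(0.5, 2.0))
    # BFS distances between leaves
    import collections

    n = n_taxa
    out = np.zeros((n, n))
    for src in range(n):
        dist = {src: 0.0}
        q = collections.deque([src])
        while q:
            u = q.popleft()
            for v, w in edges[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    q.append(v)
        for dst in range(n):
            out[src, dst] = dist[dst]
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(labels=["a", "b", "c"],
                           values=np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = nj_tree(d)
        lengths = {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) -> additive distances
        labels = list("abcd")
        vals = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0]], float)
        tree = nj_tree(DistanceMatrix(labels=labels, values=vals))
        got = path_distance_matrix(tree, labels)
        np.testing.assert_allclose(got, vals, atol=1e-9)

    def test_random_additive_recovery_eight_taxa(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            labels = [f"t{i}" for i in range(8)]
            vals = random_additive_matrix(8, rng)
            tree = nj_tree(DistanceMatrix(labels=labels, values=vals))
            got = path_distance_matrix(tree, labels)
            np.testing.assert_allclose(got, vals, atol=1e-8)

    def test_requires_three_labels(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(labels=["a", "b"], values=np.zeros((2, 2))))


def _synthetic_families(rng, n_families=4, n_queries=3, seq_len=120):
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    records = []
    refs = {}
    truth = {}
    for f in range(n_families):
        fam = f"F{f + 1}"
        root = ProteinRecord(id=f"{fam}_root",
                             sequence="".join(rng.choice(alphabet, seq_len)))
        rates = np.full(seq_len, 1.0)
        aln, _ = simulate_ortholog_family(root, n_queries + 1, rates, 0.1,
                                          seed=int(rng.integers(2**31)))
        for k, rec in enumerate(aln.records):
            records.append(rec)
            if k == 1:
                refs[rec.id] = fam
            truth[rec.id] = fam
    return MultipleAlignment(records), refs, truth


class TestFamilyAssignment:
    def test_clean_clades_assign_queries(self, rng):
        aln, refs, truth = _synthetic_families(rng)
        tree = nj_tree(protein_distance(aln))
        assigned = assign_families(tree, refs)
        correct = sum(1 for rec_id, fam in assigned.items()
                      if truth[rec_id] == fam)
        assert correct / len(assigned) >= 0.95

    def test_references_map_to_own_family(self, rng):
        aln, refs, _ = _synthetic_families(rng)
        tree = nj_tree(protein_distance(aln))
        assigned = assign_families(tree, refs)
        for ref, fam in refs.items():
            assert assigned[ref] == fam

    def test_missing_reference_is_error(self, rng):
        aln, refs, _ = _synthetic_families(rng)
        tree = nj_tree(protein_distance(aln))
        refs["ghost"] = "F9"
        with pytest.raises(ValueError, match="ghost"):
            assign_families(tree, refs)

    def test_needs_two_families(self, rng):
        aln, refs, _ = _synthetic_families(rng)
        tree = nj_tree(protein_distance(aln))
        one = {k: "F1" for k in refs}
        with pytest.raises(ValueError):
            assign_families(tree, one)

    def test_invariant_to_leaf_input_order(self, rng):
        aln, refs, _ = _synthetic_families(rng)
        reversed_aln = MultipleAlignment(list(reversed(aln.records)))
        t1 = nj_tree(protein_distance(aln))
        t2 = nj_tree(protein_distance(reversed_aln))
        assert assign_families(t1, refs) == assign_families(t2, refs)

    def test_query_between_clades_unassigned(self):
        # qm hangs on the internal path between the F1 and F3 clades, so its
        # smallest reference-containing clade mixes families
        newick = ("(((ra:0.1,qa:0.1):1.0,(rb:0.1,qb:0.1):1.0,qm:0.05):2.0,"
                  "(rc:0.1,qc:0.1):2.0);")
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assigned = assign_families(tree, {"ra": "F1", "rb": "F3", "rc": "F5"})
        assert assigned["qa"] == "F1"
        assert assigned["qb"] == "F3"
        assert assigned["qc"] == "F5"
        assert assigned["qm"] == UNASSIGNED
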