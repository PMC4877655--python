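"""Distance-based family clustering: Poisson-corrected protein distances,
neighbor-joining, and reference-anchored clade labeling.

This is a deliberately coarse stand-in for full maximum-likelihood tree
inference: the receptor families form deep, well-separated clades, so
Saitou–Nei neighbor-joining on corrected pairwise distances recovers the
family structure that downstream labeling needs.
"""

from __future__ import annotations

import math
from typing import Literal

import dendropy
import numpy as np

from .io import GAP, DistanceMatrix, MultipleAlignment

FAMILY_LABELS = ("F1", "F3", "F4", "F5", "F7", "F11", "F13", "F15")
UNASSIGNED = "UNASSIGNED"


def protein_distance(alignment: MultipleAlignment,
                     model: Literal["p", "poisson"] = "poisson",
                     min_overlap: int = 30,
                     max_distance: float = 10.0) -> DistanceMatrix:
    """Pairwise distances over shared non-gap columns.

    p-distance is the mismatch fraction ('X' always mismatches); the Poisson
    correction is -ln(1 - p), capped at ``max_distance`` near saturation.
    Pairs overlapping in fewer than ``min_overlap`` columns are an error.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    rows = alignment.records
    n = len(rows)
    seqs = [np.frombuffer(r.sequence.encode(), dtype="S1") for r in rows]
    gap = GAP.encode()
    unknown = b"X"
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (seqs[i] != gap) & (seqs[j] != gap)
            overlap = int(both.sum())
            if overlap < min_overlap:
                raise ValueError(
                    f"pair ({rows[i].id!r}, {rows[j].id!r}): only {overlap} shared "
                    f"non-gap columns (< {min_overlap})"
                )
            match = (seqs[i] == seqs[j]) & both & (seqs[i] != unknown)
            p = 1.0 - int(match.sum()) / overlap
            if model == "p":
                d = p
            else:
                d = -math.log1p(-p) if p < 1.0 - math.exp(-max_distance) else max_distance
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=[r.id for r in rows], values=values)


# ---------------------------------------------------------------------------
# Neighbor-joining
# ---------------------------------------------------------------------------

def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor-joining tree.

    Exact on additive matrices.  Q-matrix ties are broken by lexicographic
    order of each cluster's smallest leaf label, so the result is
    deterministic.  Negative branch lengths are clamped to zero with the
    deficit moved to the sister branch.  The returned tree is unrooted
    (degree-3 seed node).
    """
    labels = list(d.labels)
    if len(labels) < 3:
        raise ValueError("neighbor-joining needs at least 3 labels")
    tns = dendropy.TaxonNamespace(labels)
    nodes: dict[int, dendropy.Node] = {}
    rep: dict[int, str] = {}
    dist: dict[tuple[int, int], float] = {}
    for i, lab in enumerate(labels):
        node = dendropy.Node()
        node.taxon = tns.get_taxon(lab)
        nodes[i] = node
        rep[i] = lab
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            dist[(i, j)] = float(d.values[i, j])
    next_id = len(labels)

    def D(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    active = set(nodes)
    while len(active) > 3:
        n = len(active)
        r = {i: sum(D(i, k) for k in active if k != i) for i in active}
        best = None
        best_q = math.inf
        for i in active:
            for j in active:
                if i >= j:
                    continue
                q = (n - 2) * D(i, j) - r[i] - r[j]
                key = tuple(sorted((rep[i], rep[j])))
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12 and
                                          (best is None or key < best[2])):
                    best_q = q
                    best = (i, j, key)
        i, j, _ = best
        dij = D(i, j)
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        u = next_id
        next_id += 1
        nodes[u] = parent
        rep[u] = min(rep[i], rep[j])
        for k in active:
            if k in (i, j):
                continue
            duk = max(0.0, (D(i, k) + D(j, k) - dij) / 2.0)
            dist[(min(u, k), max(u, k))] = duk
        active.discard(i)
        active.discard(j)
        active.add(u)

    a, b, c = sorted(active, key=lambda k: rep[k])
    la = max(0.0, (D(a, b) + D(a, c) - D(b, c)) / 2.0)
    lb = max(0.0, (D(a, b) + D(b, c) - D(a, c)) / 2.0)
    lc = max(0.0, (D(a, c) + D(b, c) - D(a, b)) / 2.0)
    root = dendropy.Node()
    for node_id, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[node_id])
        nodes[node_id].edge.length = length
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Reference-anchored family assignment
# ---------------------------------------------------------------------------

def assign_families(tree: dendropy.Tree,
                    references: dict[str, str]) -> dict[str, str]:
    """Label each leaf with the family of the smallest midpoint-rooted clade
    containing it and references of exactly one family.

    Leaves whose smallest reference-containing clade mixes families are
    UNASSIGNED.  Reference leaves always map to their own family.
    """
    if len(set(references.values())) < 2:
        raise ValueError("need references from at least 2 families")
    work = tree.clone(depth=1)
    leaf_labels = {leaf.taxon.label for leaf in work.leaf_node_iter()}
    for ref in references:
        if ref not in leaf_labels:
            raise ValueError(f"reference leaf {ref!r} missing from tree")
    work.reroot_at_midpoint(update_bipartitions=False)

    fam_below: dict[dendropy.Node, frozenset[str]] = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            fam = references.get(node.taxon.label)
            fam_below[node] = frozenset([fam]) if fam else frozenset()
        else:
            fams: set[str] = set()
            for child in node.child_nodes():
                fams |= fam_below[child]
            fam_below[node] = frozenset(fams)

    out: dict[str, str] = {}
    for leaf in work.leaf_node_iter():
        label = leaf.taxon.label
        if label in references:
            out[label] = references[label]
            continue
        node = leaf
        assigned = UNASSIGNED
        while node is not None:
            fams = fam_below[node]
            if fams:
                assigned = next(iter(fams)) if len(fams) == 1 else UNASSIGNED
                break
            node = node.parent_node
        out[label] = assigned
    return out
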