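"""Tree plumbing shared by the distance, likelihood and simulation modules.

Trees cross module boundaries as dendropy ``Tree`` objects (or newick
strings); the likelihood engine flattens them into postorder index arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


def from_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    return tree


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def floor_negative_lengths(tree: dendropy.Tree, floor: float = 0.0) -> int:
    """Clamp negative branch lengths at ``floor``; returns how many."""
    n = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < floor:
            edge.length = floor
            n += 1
    return n


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def has_split(tree: dendropy.Tree, taxa_subset: set[str]) -> bool:
    """True if the unrooted tree contains the bipartition subset | rest."""
    labels = set(leaf_labels(tree))
    if not taxa_subset <= labels:
        return False
    other = labels - taxa_subset
    if not other or not taxa_subset:
        return True
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below == taxa_subset or below == other:
            return True
    return False


def robinson_foulds(newick_a: str, newick_b: str) -> int:
    ns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(
        data=newick_a, schema="newick", taxon_namespace=ns, preserve_underscores=True
    )
    tb = dendropy.Tree.get(
        data=newick_b, schema="newick", taxon_namespace=ns, preserve_underscores=True
    )
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)


@dataclass
class TreeArrays:
    """Flattened rooted view of a (possibly unrooted) tree.

    ``postorder`` lists node ids children-first with the root last; leaves
    carry ``leaf_taxon`` labels; ``edge_length[i]`` is the branch above
    node i (0 for the root).  ``node_refs`` maps array ids back to the
    dendropy nodes so optimized lengths can be written back.
    """

    n_nodes: int
    postorder: np.ndarray
    children: list[list[int]]
    parent: np.ndarray
    edge_length: np.ndarray
    leaf_taxon: dict[int, str]
    node_refs: list
    tree: dendropy.Tree

    @property
    def root(self) -> int:
        return int(self.postorder[-1])

    def write_back(self) -> dendropy.Tree:
        for i, node in enumerate(self.node_refs):
            if node is not None and node.parent_node is not None:
                node.edge.length = float(self.edge_length[i])
        return self.tree


def to_arrays(tree: dendropy.Tree) -> TreeArrays:
    tree = tree.clone(depth=1)
    # suppress unifurcations at the seed node so the root has >=2 children
    tree.suppress_unifurcations()
    nodes = list(tree.postorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    children: list[list[int]] = [[] for _ in range(n)]
    parent = np.full(n, -1, dtype=int)
    edge_length = np.zeros(n)
    leaf_taxon: dict[int, str] = {}
    for i, node in enumerate(nodes):
        if node.parent_node is not None:
            parent[i] = index[id(node.parent_node)]
            edge_length[i] = node.edge.length or 0.0
        for ch in node.child_nodes():
            children[i].append(index[id(ch)])
        if node.is_leaf():
            leaf_taxon[i] = node.taxon.label
    return TreeArrays(
        n_nodes=n,
        postorder=np.arange(n),
        children=children,
        parent=parent,
        edge_length=edge_length,
        leaf_taxon=leaf_taxon,
        node_refs=nodes,
        tree=tree,
    )


def ols_branch_lengths(tree: dendropy.Tree, dist: np.ndarray, taxa: list[str]) -> dendropy.Tree:
    """Fit branch lengths to a distance matrix by non-negative least squares.

    The design matrix has one row per taxon pair and one column per edge,
    with a 1 wherever the edge lies on the path between the pair.
    """
    from scipy.optimize import nnls

    arr = to_arrays(tree)
    leaf_ids = {t: i for i, t in arr.leaf_taxon.items()}
    # edges = all non-root nodes
    edge_nodes = [i for i in range(arr.n_nodes) if arr.parent[i] >= 0]
    col = {e: j for j, e in enumerate(edge_nodes)}
    pairs = [(a, b) for ai, a in enumerate(taxa) for b in taxa[ai + 1 :]]
    A = np.zeros((len(pairs), len(edge_nodes)))
    d = np.zeros(len(pairs))
    tindex = {t: i for i, t in enumerate(taxa)}

    def path_to_root(i):
        out = []
        while arr.parent[i] >= 0:
            out.append(i)
            i = arr.parent[i]
        return out

    for r, (a, b) in enumerate(pairs):
        pa = path_to_root(leaf_ids[a])
        pb = path_to_root(leaf_ids[b])
        sym = set(pa).symmetric_difference(pb)
        for e in sym:
            A[r, col[e]] = 1.0
        d[r] = dist[tindex[a], tindex[b]]
    x, _ = nnls(A, d)
    for e, j in col.items():
        arr.edge_length[e] = x[j]
    return arr.write_back()
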