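"""Array-based view of rooted phylogenies.

Dendropy ``Tree`` objects are the user-facing representation (Newick/Nexus
I/O, tree manipulation); the numerical core works on a flat postorder
encoding that the likelihood kernels can consume.  Tip order is canonical
(sorted labels) unless an explicit order is supplied, so that character
matrices line up across every tree of a tree set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import InputError


@dataclass
class TreeArrays:
    """Postorder encoding of a rooted tree.

    Nodes are numbered 0..n_nodes-1 in postorder, so every child index is
    smaller than its parent's and the root is ``n_nodes - 1``.
    ``edge_len[i]`` is the length of the branch above node *i* (0 for the
    root).  ``tip_node[j]`` is the node index of the *j*-th taxon in
    ``taxon_labels``.
    """

    taxon_labels: list[str]
    parent: np.ndarray
    child_list: np.ndarray
    child_start: np.ndarray
    child_count: np.ndarray
    edge_len: np.ndarray
    tip_node: np.ndarray
    _clusters: dict[frozenset[int], int] | None = field(default=None, repr=False)

    @property
    def n_tips(self) -> int:
        return len(self.taxon_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @classmethod
    def from_tree(cls, tree: dendropy.Tree, taxon_order: list[str] | None = None) -> "TreeArrays":
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        edge_len = np.zeros(n, dtype=np.float64)
        child_count = np.zeros(n, dtype=np.int64)
        kids: list[list[int]] = [[] for _ in range(n)]
        labels: dict[str, int] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise InputError("tree has a branch without a length")
                edge_len[i] = float(nd.edge.length)
                kids[parent[i]].append(i)
            if nd.is_leaf():
                if nd.taxon is None or nd.taxon.label is None:
                    raise InputError("tree has an unlabeled tip")
                if nd.taxon.label in labels:
                    raise InputError(f"duplicate tip label {nd.taxon.label!r}")
                labels[nd.taxon.label] = i
        if taxon_order is None:
            taxon_order = sorted(labels)
        elif set(taxon_order) != set(labels):
            raise InputError("taxon_order does not match the tree's tip labels")
        child_start = np.zeros(n, dtype=np.int64)
        flat: list[int] = []
        for i in range(n):
            child_start[i] = len(flat)
            child_count[i] = len(kids[i])
            flat.extend(kids[i])
        tip_node = np.array([labels[t] for t in taxon_order], dtype=np.int64)
        return cls(
            taxon_labels=list(taxon_order),
            parent=parent,
            child_list=np.array(flat, dtype=np.int64),
            child_start=child_start,
            child_count=child_count,
            edge_len=edge_len,
            tip_node=tip_node,
        )

    # -- derived structure -------------------------------------------------

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node (preorder accumulation)."""
        depth = np.zeros(self.n_nodes)
        for i in range(self.n_nodes - 2, -1, -1):  # reverse postorder skips root
            depth[i] = depth[self.parent[i]] + self.edge_len[i]
        return depth

    def tip_depths(self) -> np.ndarray:
        return self.node_depths()[self.tip_node]

    def clusters(self) -> dict[frozenset[int], int]:
        """Map each clade (frozenset of taxon indices) to its node index."""
        if self._clusters is None:
            tipsets: list[frozenset[int]] = [frozenset()] * self.n_nodes
            node_of_tip = {int(nd): j for j, nd in enumerate(self.tip_node)}
            out: dict[frozenset[int], int] = {}
            for i in range(self.n_nodes):
                if self.child_count[i] == 0:
                    tipsets[i] = frozenset({node_of_tip[i]})
                else:
                    acc: set[int] = set()
                    for ci in range(self.child_start[i], self.child_start[i] + self.child_count[i]):
                        acc |= tipsets[self.child_list[ci]]
                    tipsets[i] = frozenset(acc)
                out[tipsets[i]] = i
            self._clusters = out
        return self._clusters

    def patristic_matrix(self) -> np.ndarray:
        """Pairwise path-length distances between tips, in taxon order."""
        depth = self.node_depths()
        tip_of_node = {int(nd): j for j, nd in enumerate(self.tip_node)}
        under: list[list[int]] = [[] for _ in range(self.n_nodes)]
        n = self.n_tips
        mrca_depth = np.zeros((n, n))
        for i in range(self.n_nodes):
            if self.child_count[i] == 0:
                under[i] = [tip_of_node[i]]
                continue
            groups = [
                under[self.child_list[ci]]
                for ci in range(self.child_start[i], self.child_start[i] + self.child_count[i])
            ]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    mrca_depth[np.ix_(groups[a], groups[b])] = depth[i]
                    mrca_depth[np.ix_(groups[b], groups[a])] = depth[i]
            under[i] = [t for g in groups for t in g]
        td = depth[self.tip_node]
        d = td[:, None] + td[None, :] - 2.0 * mrca_depth
        np.fill_diagonal(d, 0.0)
        return d


def read_tree_set(path: str, schema: str | None = None) -> dendropy.TreeList:
    """Read a multi-tree Newick or Nexus file as a rooted tree set."""
    if schema is None:
        schema = "nexus" if str(path).lower().endswith((".nex", ".nexus")) else "newick"
    trees = dendropy.TreeList.get(path=str(path), schema=schema, rooting="default-rooted")
    if len(trees) == 0:
        raise InputError(f"no trees found in {path}")
    return trees


def write_tree_set(trees: dendropy.TreeList, path: str, schema: str = "newick") -> None:
    trees.write(path=str(path), schema=schema, suppress_rooting=(schema == "newick"))


def common_taxon_order(trees) -> list[str]:
    """Sorted shared tip-label order; raises if the trees disagree."""
    tipsets = [frozenset(leaf.taxon.label for leaf in t.leaf_node_iter()) for t in trees]
    if any(s != tipsets[0] for s in tipsets[1:]):
        raise InputError("trees in the set do not share a common tip set")
    return sorted(tipsets[0])
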