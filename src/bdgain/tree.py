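"""Rooted species tree with per-branch parameter slots.

A light array-based representation: nodes are indexed in post-order (root
last), each non-root node identifies the branch to its parent.  Newick
parsing and writing delegate to dendropy; branch lengths present in the
input are parsed but ignored under the unit-branch-time normalization used
for fitting (the per-branch duration is a model parameter, not data).
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np

__all__ = ["SpeciesTree", "TreeError"]


class TreeError(ValueError):
    pass


class SpeciesTree:
    """Rooted binary species tree.

    Attributes
    ----------
    n_nodes : int
        Total node count |V|; nodes are indexed 0..n_nodes-1 in post-order,
        with the root at index n_nodes - 1.
    parent : ndarray of int
        Parent index per node (-1 for the root).
    children : list[tuple[int, ...]]
        Child indices per node (empty for leaves).
    labels : list[str]
        Node labels; leaves keep their taxon names, unlabeled internal nodes
        get post-order names ``N1, N2, ...``.
    leaf_names : list[str]
        Taxon names in post-order leaf order.
    """

    def __init__(self, parent: np.ndarray, children: list[tuple[int, ...]],
                 labels: list[str]):
        self.parent = np.asarray(parent, dtype=int)
        self.children = children
        self.labels = list(labels)
        self.n_nodes = len(labels)
        self.root = self.n_nodes - 1
        self.leaves = [i for i in range(self.n_nodes) if not children[i]]
        self.leaf_names = [labels[i] for i in self.leaves]
        self.leaf_index = {name: i for name, i in zip(self.leaf_names, self.leaves)}
        if len(self.leaf_index) != len(self.leaves):
            raise TreeError("leaf labels must be unique")
        # Branches are identified by their child node: every node but the root.
        self.branch_nodes = [i for i in range(self.n_nodes) if i != self.root]

    # ------------------------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def n_branches(self) -> int:
        """|B| = |V| − 1."""
        return self.n_nodes - 1

    def branch_labels(self) -> list[str]:
        """Branch names (child-node labels) in post-order."""
        return [self.labels[i] for i in self.branch_nodes]

    def internal_nodes(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.children[i]]

    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        try:
            dtree = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"could not parse Newick string: {exc}") from exc
        dtree.is_rooted = True
        nodes = list(dtree.postorder_node_iter())
        for nd in nodes:
            kids = nd.child_nodes()
            if kids and len(kids) != 2:
                raise TreeError(
                    "tree must be rooted and strictly binary; node with "
                    f"{len(kids)} children found (unrooted/multifurcating input?)"
                )
        if any(nd.edge.length is not None for nd in nodes if nd.parent_node):
            warnings.warn(
                "branch lengths in the Newick input are ignored; branch "
                "durations are normalized to 1 and rates are free parameters",
                stacklevel=2,
            )
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=int)
        children: list[tuple[int, ...]] = [() for _ in nodes]
        labels: list[str] = []
        n_internal = 0
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
            children[i] = tuple(index[id(c)] for c in nd.child_nodes())
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise TreeError("every leaf must carry a taxon name")
                labels.append(nd.taxon.label.replace(" ", "_"))
            else:
                n_internal += 1
                lbl = nd.label or f"N{n_internal}"
                labels.append(lbl)
        return cls(parent, children, labels)

    def to_newick(self) -> str:
        def rec(i: int) -> str:
            if not self.children[i]:
                return self.labels[i]
            inner = ",".join(rec(c) for c in self.children[i])
            lbl = self.labels[i] if i != self.root else ""
            return f"({inner}){lbl}"

        return rec(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SpeciesTree({self.n_leaves} leaves, {self.n_branches} branches)"
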