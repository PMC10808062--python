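"""Rooted phylogeny with branch lengths and named clades.

Thin array-based facade over dendropy: parsing, rerooting and subtree
extraction delegate to dendropy; likelihood code consumes the flat arrays
(``postorder``, ``parent``, ``lengths``) directly.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import dendropy
import numpy as np

__all__ = ["Phylogeny"]


class Phylogeny:
    """A rooted tree with non-negative branch lengths and named clades.

    Nodes are indexed ``0 .. n_nodes-1`` with tips first (``0 .. n_tips-1``);
    ``postorder`` visits children before parents and ends at the root.
    A named clade is a connected subtree, stored as its MRCA node index.
    """

    def __init__(self, dtree: dendropy.Tree, clades: Mapping[str, Iterable[str]] | None = None):
        dtree.is_rooted = True
        self._dtree = dtree

        tips = [leaf for leaf in dtree.leaf_node_iter()]
        names = [leaf.taxon.label if leaf.taxon else None for leaf in tips]
        if any(n is None for n in names):
            raise ValueError("every tip must be named")
        if len(set(names)) != len(names):
            raise ValueError("tip names must be unique")

        self.n_tips = len(tips)
        index: dict[int, int] = {}
        for i, leaf in enumerate(tips):
            index[id(leaf)] = i
        next_id = self.n_tips
        post: list[int] = []
        for node in dtree.postorder_node_iter():
            if node.is_leaf():
                post.append(index[id(node)])
            else:
                index[id(node)] = next_id
                post.append(next_id)
                next_id += 1
        self.n_nodes = next_id
        self.postorder = np.asarray(post, dtype=np.int64)
        self.root = self.postorder[-1]

        self.parent = np.full(self.n_nodes, -1, dtype=np.int64)
        self.lengths = np.zeros(self.n_nodes, dtype=float)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for node in dtree.preorder_node_iter():
            i = index[id(node)]
            if node.parent_node is not None:
                p = index[id(node.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                bl = node.edge.length
                if bl is None:
                    bl = 0.0
                if bl < 0:
                    raise ValueError(f"negative branch length on node {i}")
                self.lengths[i] = float(bl)

        self.tip_names: list[str] = names
        self.tip_index: dict[str, int] = {n: i for i, n in enumerate(names)}

        self.clades: dict[str, int] = {}
        # internal node labels register as clades
        for node in dtree.preorder_internal_node_iter():
            if node.label:
                self.clades[node.label] = index[id(node)]
        if clades:
            for name, tip_names in clades.items():
                self.clades[name] = self._mrca_of(set(tip_names))

    # ------------------------------------------------------------------ #

    def _mrca_of(self, tip_names: set[str]) -> int:
        unknown = tip_names - set(self.tip_names)
        if unknown:
            raise ValueError(f"unknown tips in clade definition: {sorted(unknown)}")
        mrca = self._dtree.mrca(taxon_labels=sorted(tip_names))
        node_tips = {l.taxon.label for l in mrca.leaf_iter()}
        if node_tips != tip_names:
            raise ValueError(
                "clade is not a connected subtree: MRCA spans "
                f"{sorted(node_tips - tip_names)} beyond the given tips"
            )
        # map back through postorder identity
        next_id = self.n_tips
        for node in self._dtree.postorder_node_iter():
            if node.is_leaf():
                if node is mrca:
                    return self.tip_index[node.taxon.label]
            else:
                if node is mrca:
                    return next_id
                next_id += 1
        raise AssertionError("MRCA not found")  # pragma: no cover

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def from_newick(cls, source: str, clades: Mapping[str, Iterable[str]] | None = None) -> "Phylogeny":
        """Parse a Newick string or file path (auto-detected)."""
        text = source
        if "\n" not in source and not source.lstrip().startswith("("):
            with open(source) as fh:
                text = fh.read()
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", rooting="force-rooted",
                suppress_internal_node_taxa=True,
            )
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValueError(f"tip names must be unique: {exc}") from exc
        return cls(dtree, clades=clades)

    def to_newick(self) -> str:
        """Serialize to Newick; named clades become internal node labels."""
        index_to_name = {v: k for k, v in self.clades.items()}
        next_id = self.n_tips
        for node in self._dtree.postorder_node_iter():
            if not node.is_leaf():
                if next_id in index_to_name:
                    node.label = index_to_name[next_id]
                next_id += 1
        return self._dtree.as_string(schema="newick", suppress_rooting=True).strip()

    # ------------------------------------------------------------------ #
    # clade machinery

    def clade_node(self, clade: str | None) -> int:
        if clade is None:
            return self.root
        try:
            return self.clades[clade]
        except KeyError:
            raise KeyError(f"unknown clade {clade!r}; known: {sorted(self.clades)}") from None

    def subtree_nodes(self, node: int) -> np.ndarray:
        """All node indices in the subtree rooted at ``node`` (postorder)."""
        out: list[int] = []
        stack = [node]
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(self.children[cur])
        return np.asarray(sorted(out), dtype=np.int64)

    def clade_tips(self, clade: str | None) -> list[str]:
        node = self.clade_node(clade)
        nodes = self.subtree_nodes(node)
        return [self.tip_names[i] for i in nodes if i < self.n_tips]

    def clade_branches(self, clade: str | None, include_stem: bool = True) -> np.ndarray:
        """Node indices whose parent branch belongs to the clade's subtree.

        With ``include_stem`` the branch leading into the clade MRCA is
        included; for ``clade=None`` every branch in the tree is returned.
        """
        node = self.clade_node(clade)
        nodes = set(self.subtree_nodes(node).tolist())
        if not include_stem or node == self.root:
            nodes.discard(node)
            if node == self.root:
                nodes.discard(self.root)
        branches = [i for i in nodes if self.parent[i] >= 0]
        return np.asarray(sorted(branches), dtype=np.int64)

    def subtree(self, clade: str) -> "Phylogeny":
        """Extract the named clade as a standalone rooted tree."""
        tips = self.clade_tips(clade)
        sub = self._dtree.extract_tree_with_taxa_labels(tips)
        sub.is_rooted = True
        return Phylogeny(sub)

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips}, clades={sorted(self.clades)})"
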