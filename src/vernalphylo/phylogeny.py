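"""Rooted, branch-lengthed phylogeny over the observed species pool.

A light wrapper around a dendropy tree that pins down everything the
diversity metrics need: unique tip labels, branch lengths everywhere
(except optionally the root edge), a patristic (cophenetic) distance
matrix, and a fast edge/bitmask representation used by Faith's PD under
thousands of null-model evaluations.
"""

from __future__ import annotations

import dendropy
import numpy as np
from skbio import DistanceMatrix

__all__ = ["Phylogeny"]


class Phylogeny:
    """Rooted tree with branch lengths, tips labelled by species name."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dups}")
        self.tip_labels = sorted(labels)
        self._tip_index = {l: i for i, l in enumerate(self.tip_labels)}
        self.n_polytomies = sum(
            1 for nd in tree.preorder_internal_node_iter() if len(nd.child_nodes()) > 2
        )
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue  # the root edge may legitimately be length-free
            if edge.length is None:
                raise ValueError(
                    f"missing branch length above node {edge.head_node!r}"
                )
            if edge.length < 0:
                raise ValueError("negative branch length")
        self._edges = None
        self._coph = None

    # -- construction -------------------------------------------------
    @classmethod
    def from_newick(cls, source: str) -> "Phylogeny":
        """Parse a newick string or file path into a rooted phylogeny."""
        try:
            tree = dendropy.Tree.get(
                data=source, schema="newick", suppress_internal_node_taxa=True
            )
        except (dendropy.utility.error.DataParseError, ValueError) as exc:
            raise ValueError(f"could not parse newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def retain(self, labels) -> "Phylogeny":
        """Subtree induced by ``labels`` (e.g. natives only), lengths preserved."""
        keep = sorted(set(labels))
        unknown = sorted(set(keep) - set(self.tip_labels))
        if unknown:
            raise KeyError(f"species not on the tree: {unknown}")
        sub = self.tree.extract_tree_with_taxa_labels(keep)
        return Phylogeny(sub)

    # -- basic facts ---------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def total_length(self) -> float:
        """Sum of all branch lengths (root edge excluded if length-free)."""
        return float(
            sum(
                e.length
                for e in self.tree.preorder_edge_iter()
                if e.length is not None
            )
        )

    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path lengths in tip-label (sorted) order."""
        depths = np.empty(self.n_tips)
        for leaf in self.tree.leaf_node_iter():
            d, nd = 0.0, leaf
            while nd.parent_node is not None:
                d += nd.edge.length or 0.0
                nd = nd.parent_node
            depths[self._tip_index[leaf.taxon.label]] = d
        return depths

    # -- derived structures --------------------------------------------
    def cophenetic(self) -> DistanceMatrix:
        """Patristic distance between every pair of tips."""
        if self._coph is None:
            n = self.n_tips
            mat = np.zeros((n, n))
            pdm = self.tree.phylogenetic_distance_matrix()
            for t1 in pdm.taxon_iter():
                for t2 in pdm.taxon_iter():
                    i, j = self._tip_index[t1.label], self._tip_index[t2.label]
                    if i < j:
                        mat[i, j] = mat[j, i] = pdm.patristic_distance(t1, t2)
            self._coph = DistanceMatrix(mat, ids=self.tip_labels)
        return self._coph

    def edge_table(self) -> list:
        """(branch length, bitmask of descendant tips) for every non-root edge.

        The bitmask sets bit ``i`` when sorted tip ``i`` descends through
        the edge; Faith's PD over a species set then reduces to summing
        lengths of edges whose mask intersects the set's mask.
        """
        if self._edges is None:
            edges = []
            masks: dict = {}
            for nd in self.tree.postorder_node_iter():
                if nd.is_leaf():
                    masks[nd] = 1 << self._tip_index[nd.taxon.label]
                else:
                    m = 0
                    for ch in nd.child_nodes():
                        m |= masks[ch]
                    masks[nd] = m
                if nd is not self.tree.seed_node and nd.edge.length is not None:
                    edges.append((float(nd.edge.length), masks[nd]))
            self._edges = edges
        return self._edges

    def mask_of(self, community) -> int:
        """Bitmask of a species set; unknown species raise with their names."""
        mask = 0
        unknown = []
        for sp in community:
            idx = self._tip_index.get(sp)
            if idx is None:
                unknown.append(sp)
            else:
                mask |= 1 << idx
        if unknown:
            raise KeyError(f"species not on the tree: {sorted(unknown)}")
        return mask
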