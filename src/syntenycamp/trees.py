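"""Rooted species/cluster trees with leaf-set addressing.

Internal nodes (equivalently, the edges above them) are addressed by the
frozenset of descendant leaf labels — a representation that is stable
across traversal order, serialization, and child swaps, and is the
identifier used throughout the gain/loss/duplication machinery.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping

import dendropy

Clade = frozenset


class SpeciesTree:
    """A rooted tree wrapping :class:`dendropy.Tree`.

    Leaf labels must be unique.  ``ages`` optionally annotates nodes
    (addressed by leaf set) with ages in million years; no age inference
    is ever performed.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        ages: Mapping[frozenset[str], float] | None = None,
    ) -> None:
        self._tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
        self._leafset: dict[int, frozenset[str]] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                self._leafset[id(node)] = frozenset([node.taxon.label])
            else:
                s: set[str] = set()
                for ch in node.child_nodes():
                    s |= self._leafset[id(ch)]
                self._leafset[id(node)] = frozenset(s)
        self._by_clade: dict[frozenset[str], dendropy.Node] = {
            self._leafset[id(n)]: n for n in tree.preorder_node_iter()
        }
        self.ages: dict[frozenset[str], float] = dict(ages or {})

    # -- construction -------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, ages: Mapping[frozenset[str], float] | None = None) -> "SpeciesTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        return cls(tree, ages=ages)

    # -- basic queries -------------------------------------------------
    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self) -> frozenset[str]:
        return self._leafset[id(self._tree.seed_node)]

    @property
    def leaves(self) -> frozenset[str]:
        return self.root

    def clades(self) -> Iterator[frozenset[str]]:
        """All clades (one per node), root first."""
        for node in self._tree.preorder_node_iter():
            yield self._leafset[id(node)]

    def has_clade(self, clade: Iterable[str]) -> bool:
        return frozenset(clade) in self._by_clade

    def node(self, clade: Iterable[str]) -> dendropy.Node:
        key = frozenset(clade)
        try:
            return self._by_clade[key]
        except KeyError:
            raise KeyError(f"no node with leaf set {sorted(key)}") from None

    def children(self, clade: Iterable[str]) -> list[frozenset[str]]:
        return [self._leafset[id(ch)] for ch in self.node(clade).child_nodes()]

    def parent(self, clade: Iterable[str]) -> frozenset[str] | None:
        p = self.node(clade).parent_node
        return None if p is None else self._leafset[id(p)]

    def is_leaf(self, clade: Iterable[str]) -> bool:
        return len(frozenset(clade)) == 1

    def is_binary(self) -> bool:
        return all(
            len(n.child_nodes()) == 2
            for n in self._tree.preorder_internal_node_iter()
        )

    def edge_length(self, clade: Iterable[str]) -> float:
        """Length of the edge above the node; 1.0 where unspecified."""
        ln = self.node(clade).edge.length
        return 1.0 if ln is None else float(ln)

    def mrca(self, labels: Iterable[str]) -> frozenset[str]:
        """Leaf set of the most recent common ancestor of ``labels``."""
        want = frozenset(labels)
        missing = want - self.leaves
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        best = self.root
        for clade in self.clades():
            if want <= clade and len(clade) < len(best):
                best = clade
        return best

    def path_to_root(self, clade: Iterable[str]) -> list[frozenset[str]]:
        """Clades from ``clade`` (inclusive) up to the root (inclusive)."""
        out = [frozenset(clade)]
        while (p := self.parent(out[-1])) is not None:
            out.append(p)
        return out

    def path_length(self, ancestor: Iterable[str], descendant: Iterable[str]) -> float:
        """Sum of edge lengths strictly below ``ancestor`` down to ``descendant``."""
        anc, desc = frozenset(ancestor), frozenset(descendant)
        total = 0.0
        cur = desc
        while cur != anc:
            total += self.edge_length(cur)
            p = self.parent(cur)
            if p is None:
                raise ValueError(f"{sorted(anc)} is not an ancestor of {sorted(desc)}")
            cur = p
        return total

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def __repr__(self) -> str:
        return f"SpeciesTree({len(self.leaves)} leaves)"
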