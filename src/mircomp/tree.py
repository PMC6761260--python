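"""Rooted species tree with branch lengths.

A thin wrapper around :mod:`dendropy` that enforces the invariants the
pipeline relies on: the tree is rooted and strictly bifurcating, tip names
are unique, and every non-root branch carries a non-negative length
(branch lengths are required downstream by the phylogenetically
independent contrasts).

Branches are identified by the node below them.  A tip branch is named by
the tip; an internal branch is named by the sorted, ``|``-joined tip set of
its clade, which is stable across parses of the same topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy


class TreeError(ValueError):
    """Raised for trees violating the pipeline's structural requirements."""


@dataclass
class SpeciesTree:
    newick_text: str
    _tree: dendropy.Tree = field(repr=False)
    tip_names: list[str] = field(default_factory=list)

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
        tree.is_rooted = True
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(tips)) != len(tips):
            dup = sorted({t for t in tips if tips.count(t) > 1})
            raise TreeError(f"duplicate tip name(s): {', '.join(dup)}")
        for node in tree.preorder_node_iter():
            children = node.child_nodes()
            if children and len(children) != 2:
                where = "root" if node.parent_node is None else "internal node"
                raise TreeError(
                    f"{where} has {len(children)} children; tree must be "
                    "rooted and strictly bifurcating"
                )
            if node.parent_node is not None:
                if node.edge.length is None:
                    raise TreeError(
                        "missing branch length (lengths are required for "
                        "independent contrasts)"
                    )
                if node.edge.length < 0:
                    raise TreeError(f"negative branch length {node.edge.length}")
        obj = cls(newick_text=text.strip(), _tree=tree, tip_names=tips)
        return obj

    # -- identification ------------------------------------------------

    def node_id(self, node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        return "|".join(sorted(l.taxon.label for l in node.leaf_iter()))

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    def postorder(self):
        return self._tree.postorder_node_iter()

    def mrca(self, tip_names) -> dendropy.Node:
        taxa = [self._tree.taxon_namespace.get_taxon(t) for t in tip_names]
        if any(t is None for t in taxa):
            missing = [n for n, t in zip(tip_names, taxa) if t is None]
            raise TreeError(f"species not on tree: {', '.join(missing)}")
        if len(taxa) == 1:
            return self._tree.find_node_for_taxon(taxa[0])
        return self._tree.mrca(taxa=taxa)

    def branch_ids(self) -> list[str]:
        """All branch ids (one per node, including the root branch)."""
        return [self.node_id(n) for n in self.postorder()]

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()
        return s

    def __len__(self) -> int:
        return len(self.tip_names)


def read_newick(path) -> SpeciesTree:
    """Read a single rooted, fully bifurcating newick tree from *path*."""
    with open(path) as fh:
        text = fh.read()
    return SpeciesTree.from_newick(text)


def write_newick(tree: SpeciesTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
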