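"""Branching topology of the sampled tree.

The physical tree is described as a rooted topology whose tips are the
sampled branches (B1..B7 by default).  Somatic mutations that arise in an
apical meristem are propagated into every branch that later develops from
it, so the set of branches carrying a meristematic mutation is expected to
be the complete tip set of one node of this topology (a clade).
"""

from __future__ import annotations

import io
from typing import Iterable

from skbio import TreeNode

#: Default layout: the trunk splits into three secondary stems, two of
#: which branch further.  Used by the synthetic-data generator.
DEFAULT_NEWICK = "((B1,(B2,B3)),B4,(B5,(B6,B7)));"


class TopologyError(ValueError):
    pass


class TreeTopology:
    """Rooted branching structure over named branch tips.

    Internal nodes without a label in the source Newick are assigned
    deterministic names ``N1, N2, ...`` in preorder so that every node can
    be referenced (e.g. as the origin of a simulated mutation).
    """

    def __init__(self, root: TreeNode):
        self.root = root
        counter = 0
        seen_tips: set[str] = set()
        for node in root.preorder():
            if node.is_tip():
                if node.name is None:
                    raise TopologyError("unnamed tip in topology")
                if node.name in seen_tips:
                    raise TopologyError(f"duplicate tip label {node.name!r}")
                seen_tips.add(node.name)
            elif node.name is None:
                counter += 1
                node.name = f"N{counter}"
        names = [n.name for n in root.preorder()]
        if len(names) != len(set(names)):
            raise TopologyError("duplicate node labels in topology")
        self._nodes = {n.name: n for n in root.preorder()}
        self.tips: tuple[str, ...] = tuple(t.name for t in root.tips())
        if not self.tips:
            raise TopologyError("topology has no tips")

    @classmethod
    def from_newick(cls, newick: str) -> "TreeTopology":
        try:
            root = TreeNode.read(io.StringIO(newick), convert_underscores=False)
        except Exception as exc:  # skbio raises several parse error types
            raise TopologyError(f"malformed Newick: {exc}") from exc
        return cls(root)

    @classmethod
    def default(cls) -> "TreeTopology":
        return cls.from_newick(DEFAULT_NEWICK)

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self._nodes)

    def node(self, name: str) -> TreeNode:
        try:
            return self._nodes[name]
        except KeyError:
            raise TopologyError(f"unknown node {name!r}") from None

    def subtree_tips(self, name: str) -> frozenset[str]:
        """Tip labels descending from (and including) the named node."""
        node = self.node(name)
        if node.is_tip():
            return frozenset([node.name])
        return frozenset(t.name for t in node.tips())

    def clade_sets(self) -> frozenset[frozenset[str]]:
        """The complete tip set of every node (incl. singleton tips)."""
        return frozenset(self.subtree_tips(n) for n in self._nodes)

    def is_clade(self, branch_set: Iterable[str]) -> bool:
        bs = frozenset(branch_set)
        unknown = bs - set(self.tips)
        if unknown:
            raise TopologyError(f"unknown branch labels {sorted(unknown)}")
        return bs in self.clade_sets()

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.root.write(buf)
        return buf.getvalue().strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"TreeTopology(tips={list(self.tips)})"
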