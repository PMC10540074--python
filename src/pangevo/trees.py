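"""Lightweight rooted-tree structure shared by the parsimony and simulation code.

The tree is deliberately minimal: named nodes with parent/child links and
optional branch lengths.  Branch lengths are ignored by Wagner parsimony but
drive the gene-content and sequence simulators.  Newick I/O lives in
:mod:`pangevo.io_formats` (via dendropy); this module only defines the
in-memory structure so the dynamic programming can walk it directly.
"""

from __future__ import annotations

from typing import Iterator, Optional


class TreeNode:
    """A node of a rooted tree.

    Parameters
    ----------
    name : str
        Node label.  Leaf labels must be unique within a tree; internal
        labels are auto-assigned deterministically when absent.
    length : float or None
        Length of the branch leading to this node (None at the root).
    """

    __slots__ = ("name", "length", "parent", "children")

    def __init__(self, name: str = "", length: Optional[float] = None):
        self.name = name
        self.length = length
        self.parent: Optional[TreeNode] = None
        self.children: list[TreeNode] = []

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal/{len(self.children)}"
        return f"TreeNode({self.name!r}, {kind})"


class RootedTree:
    """A rooted tree with unique leaf labels and deterministically named
    internal nodes.

    Attributes
    ----------
    root : TreeNode
    root_multifurcation : bool
        True when the root has more than two children (e.g. an unrooted
        newick accepted as-is); flagged so reports can note it.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._autoname_internals()
        self._validate()
        self.root_multifurcation = len(root.children) > 2

    # -- traversals ---------------------------------------------------------

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            # reversed keeps left-to-right newick order in the traversal
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out = list(self.preorder())
        return iter(reversed(out))

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves]

    def nodes(self) -> list[TreeNode]:
        return list(self.preorder())

    def find(self, name: str) -> TreeNode:
        for node in self.preorder():
            if node.name == name:
                return node
        raise KeyError(f"no node named {name!r} in tree")

    # -- construction helpers ----------------------------------------------

    def _autoname_internals(self) -> None:
        used = {n.name for n in self._raw_preorder() if n.name}
        idx = 0
        for node in self._raw_preorder():
            if not node.is_leaf and not node.name:
                while f"N{idx}" in used:
                    idx += 1
                node.name = f"N{idx}"
                used.add(node.name)
                idx += 1

    def _raw_preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def _validate(self) -> None:
        leaf_names = [n.name for n in self._raw_preorder() if n.is_leaf]
        seen: set[str] = set()
        dup = sorted({x for x in leaf_names if x in seen or seen.add(x)})
        if dup:
            raise ValueError(f"duplicate leaf labels: {dup}")
        if any(not name for name in leaf_names):
            raise ValueError("every leaf must carry a label")

    # -- serialization ------------------------------------------------------

    def to_newick(self, comments: Optional[dict[str, str]] = None) -> str:
        """Render as a newick string.

        Parameters
        ----------
        comments : dict, optional
            Map node name -> bracketed comment text appended after the label
            (used to annotate gain/loss counts onto the species tree).
        """

        def render(node: TreeNode) -> str:
            label = node.name
            if comments and node.name in comments:
                label += f"[{comments[node.name]}]"
            blen = "" if node.length is None else f":{node.length:.6f}"
            if node.is_leaf:
                return f"{label}{blen}"
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){label}{blen}"

        return render(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"RootedTree({len(self.leaves)} leaves)"
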