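"""Rooted phylogenies with branch lengths.

Newick parsing and serialization are delegated to dendropy; on top of the
parsed topology we keep a small mutable node structure (parent pointers,
children lists, branch lengths) that the ancestral-reconstruction code can
traverse, prune and re-root cheaply.

Internal nodes that arrive unlabeled are named deterministically in postorder
("n1".."nk") so that output tables join with trees across runs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import dendropy

from .io import FormatError


class Node:
    __slots__ = ("label", "length", "parent", "children")

    def __init__(
        self,
        label: str | None = None,
        length: float | None = None,
        parent: "Node | None" = None,
    ) -> None:
        self.label = label
        self.length = length
        self.parent = parent
        self.children: list[Node] = []

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} bl={self.length}>"


class PhyloTree:
    """A rooted tree with non-negative branch lengths and unique tip labels."""

    def __init__(self, root: Node) -> None:
        self.root = root
        self._validate()

    # -- construction / validation ------------------------------------------

    def _validate(self) -> None:
        labels = [n.label for n in self.tips()]
        if len(labels) != len(set(labels)):
            seen: set[str] = set()
            for lab in labels:
                if lab in seen:
                    raise FormatError(f"duplicate tip label {lab!r}")
                seen.add(lab)
        for node in self.preorder():
            if node is self.root:
                continue
            if node.length is None:
                raise FormatError(
                    f"missing branch length above node {node.label!r} "
                    "(pass default_length to accept)"
                )
            if node.length < 0:
                raise FormatError(f"negative branch length above {node.label!r}")
        self.assign_internal_labels()

    def assign_internal_labels(self) -> None:
        """Name unlabeled internal nodes n1..nk in postorder, skipping taken names."""
        taken = {n.label for n in self.preorder() if n.label}
        counter = 1
        for node in self.postorder():
            if node.is_tip or node.label:
                continue
            while f"n{counter}" in taken:
                counter += 1
            node.label = f"n{counter}"
            taken.add(node.label)
            counter += 1

    # -- traversal ------------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def find(self, label: str) -> Node:
        for node in self.preorder():
            if node.label == label:
                return node
        raise KeyError(f"no node labeled {label!r}")

    def mrca(self, labels: list[str]) -> Node:
        paths = []
        for lab in labels:
            node = self.find(lab)
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(list(reversed(path)))
        mrca = self.root
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                mrca = level[0]
            else:
                break
        return mrca

    def depths(self) -> dict[str, float]:
        """Root-to-node path length for every node, keyed by label."""
        out: dict[str, float] = {}
        for node in self.preorder():
            if node is self.root:
                out[node.label] = 0.0
            else:
                out[node.label] = out[node.parent.label] + node.length
        return out

    def is_binary(self) -> bool:
        return all(
            len(n.children) == 2 for n in self.internal_nodes() if n is not self.root
        ) and len(self.root.children) in (2,)

    # -- editing ---------------------------------------------------------------

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root))

    def prune_to(self, keep: set[str]) -> "PhyloTree":
        """Return a copy restricted to the given tip labels.

        Unifurcations created by pruning are suppressed, merging branch
        lengths; a unifurcating root is collapsed onto its child (the child's
        stem length is dropped, as the root carries no branch).
        """
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        tree = self.copy()

        def rec(node: Node) -> Node | None:
            if node.is_tip:
                return node if node.label in keep else None
            kept = [rec(c) for c in node.children]
            kept = [c for c in kept if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                child = kept[0]
                if node.length is not None and child.length is not None:
                    child.length += node.length
                else:
                    child.length = node.length if child.length is None else child.length
                return child
            node.children = []
            for c in kept:
                node.add_child(c)
            return node

        new_root = rec(tree.root)
        if new_root is None:
            raise FormatError("pruning removed every tip")
        new_root.parent = None
        if new_root is not tree.root:
            new_root.length = None
        return PhyloTree(new_root)

    def resolve_polytomies(self) -> "PhyloTree":
        """Binary resolution of polytomies with zero-length branches.

        Children are combined left-to-right in input order, so the resolution
        is deterministic for a given Newick string.
        """
        tree = self.copy()
        for node in list(tree.postorder()):
            while len(node.children) > 2:
                a = node.children.pop(0)
                b = node.children.pop(0)
                joint = Node(label=None, length=0.0)
                joint.add_child(a)
                joint.add_child(b)
                joint.parent = node
                node.children.insert(0, joint)
        tree.assign_internal_labels()
        return tree

    # -- newick -----------------------------------------------------------------

    def to_newick(self, *, include_internal_labels: bool = True) -> str:
        def rec(node: Node) -> str:
            if node.is_tip:
                core = node.label or ""
            else:
                inner = ",".join(rec(c) for c in node.children)
                label = node.label if include_internal_labels else ""
                core = f"({inner}){label or ''}"
            if node.parent is not None and node.length is not None:
                core += f":{node.length:.12g}"
            return core

        return rec(self.root) + ";"


def _from_dendropy(dtree: dendropy.Tree, default_length: float | None) -> PhyloTree:
    def convert(dnode: dendropy.Node) -> Node:
        label = None
        if dnode.taxon is not None and dnode.taxon.label:
            label = dnode.taxon.label.replace(" ", "_")
        elif dnode.label:
            label = dnode.label.replace(" ", "_")
        length = dnode.edge.length
        node = Node(label=label, length=length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    root.length = None  # root edge length ignored
    if default_length is not None:
        stack = [root]
        while stack:
            node = stack.pop()
            if node is not root and node.length is None:
                node.length = default_length
            stack.extend(node.children)
    return PhyloTree(root)


def parse_newick(text: str, *, default_length: float | None = None) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Quoted labels are supported, [] comments stripped, the root edge length
    ignored, polytomies tolerated. Missing branch lengths raise unless
    ``default_length`` is given.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise FormatError(f"Newick parse error: {exc}") from exc
    return _from_dendropy(dtree, default_length)


def read_newick(path: str | Path, *, default_length: float | None = None) -> PhyloTree:
    return parse_newick(Path(path).read_text(), default_length=default_length)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def bipartitions(tree: PhyloTree) -> set[frozenset[str]]:
    """Non-trivial tip bipartitions (one side each), for topology comparison."""
    all_tips = frozenset(tree.tip_labels)
    out: set[frozenset[str]] = set()
    clade: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_tip:
            clade[id(node)] = frozenset([node.label])
        else:
            merged = frozenset().union(*(clade[id(c)] for c in node.children))
            clade[id(node)] = merged
            if node is not tree.root and 1 < len(merged) < len(all_tips):
                out.add(merged)
    return out
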