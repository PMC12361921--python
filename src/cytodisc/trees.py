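"""Phylogenetic tree container used throughout the pipeline.

Trees are stored rooted for traversal convenience but all split logic is
unrooted: the root is an arbitrary internal node (degree 3 after
:meth:`Tree.unroot` for a binary unrooted tree) and every comparison goes
through leaf-set bipartitions.  Each non-root node owns the edge to its
parent; branch lengths and the dual support values (nonparametric bootstrap
percentage and aBayes posterior) live on that edge.

Newick serialization is delegated to dendropy; supports are written as
internal-node labels ``"bs/abayes"`` (the canonical form) and read back from
either that form or ``[&bs=..,ab=..]`` comments.
"""

from __future__ import annotations

import io
import itertools
import re
from typing import Callable, Iterable, Iterator, Optional

import dendropy


class TreeError(ValueError):
    """Malformed tree or invalid tree operation."""


class NewickParseError(TreeError):
    """Unparseable newick; carries an approximate character offset."""

    def __init__(self, message: str, offset: Optional[int] = None):
        if offset is not None:
            message = f"{message} (near character {offset})"
        super().__init__(message)
        self.offset = offset


class Node:
    __slots__ = ("label", "length", "bs", "abayes", "children", "parent")

    def __init__(self, label: Optional[str] = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.bs: Optional[float] = None
        self.abayes: Optional[float] = None
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, len={self.length:.4g})"


class Tree:
    """Unrooted phylogeny stored with an arbitrary internal root."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        try:
            dt = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
                extract_comment_metadata=False,
            )
        except Exception as exc:  # dendropy raises several error types
            offset = _error_offset(exc)
            raise NewickParseError(f"cannot parse newick: {exc}", offset) from exc
        return cls(_from_dendropy(dt.seed_node))

    @classmethod
    def read(cls, path) -> "Tree":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_newick(fh.read())

    def to_newick(self, supports: bool = True, lengths: bool = True) -> str:
        return _to_newick(self.root, supports=supports, lengths=lengths) + ";"

    def write(self, path, supports: bool = True) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_newick(supports=supports) + "\n")

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(supports=False),
            schema="newick",
            taxon_namespace=taxon_namespace,
            preserve_underscores=True,
        )

    # ----------------------------------------------------------- traversal

    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf():
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf()]

    def leaf_labels(self) -> frozenset:
        return frozenset(n.label for n in self.leaves())

    def find_leaf(self, label: str) -> Node:
        for n in self.postorder():
            if n.is_leaf() and n.label == label:
                return n
        raise KeyError(f"leaf {label!r} not in tree")

    def internal_edges(self) -> list[Node]:
        """Non-root internal nodes, i.e. owners of internal edges."""
        return [
            n
            for n in self.postorder()
            if n is not self.root and not n.is_leaf()
        ]

    def n_edges(self) -> int:
        return sum(1 for n in self.postorder() if n is not self.root)

    # ------------------------------------------------------------- editing

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            c = Node(node.label, node.length)
            c.bs, c.abayes = node.bs, node.abayes
            for child in node.children:
                c.add_child(clone(child))
            return c

        return Tree(clone(self.root))

    def validate(self) -> None:
        labels = [n.label for n in self.leaves()]
        if len(labels) != len(set(labels)):
            raise TreeError("duplicate leaf labels")
        for n in self.postorder():
            if n is not self.root and n.length < 0:
                raise TreeError(f"negative branch length on edge above {n!r}")

    def is_binary_unrooted(self) -> bool:
        if len(self.root.children) != 3:
            return False
        return all(
            len(n.children) in (0, 2)
            for n in self.postorder()
            if n is not self.root
        )

    def unroot(self) -> "Tree":
        """Collapse a degree-2 root so the root has >=3 children."""
        while len(self.root.children) == 2:
            a, b = self.root.children
            keep, merge = (a, b) if not a.is_leaf() else (b, a)
            if keep.is_leaf():
                break  # two-leaf tree; nothing to collapse
            keep.parent = None
            merge.length += keep.length
            keep.length = 0.0
            keep.bs = keep.abayes = None
            keep.add_child(merge)
            self.root = keep
        return self

    def suppress_unifurcations(self) -> "Tree":
        changed = True
        while changed:
            changed = False
            for node in list(self.postorder()):
                if node.is_leaf() or len(node.children) != 1:
                    continue
                child = node.children[0]
                if node.parent is None:
                    child.parent = None
                    child.length = 0.0
                    self.root = child
                else:
                    parent = node.parent
                    idx = parent.children.index(node)
                    child.length += node.length
                    child.parent = parent
                    parent.children[idx] = child
                changed = True
        return self

    def prune_leaf(self, label: str) -> "Tree":
        leaf = self.find_leaf(label)
        parent = leaf.parent
        if parent is None:
            raise TreeError("cannot prune the only node")
        parent.remove_child(leaf)
        self.suppress_unifurcations()
        self.unroot()
        return self

    def restrict(self, taxa: Iterable[str]) -> "Tree":
        keep = set(taxa)
        tree = self.copy()
        for label in sorted(tree.leaf_labels() - keep):
            tree.prune_leaf(label)
        return tree

    def attach_at_edge(
        self,
        edge_child: Node,
        label: str,
        pendant_length: float,
        position: float = 0.5,
    ) -> Node:
        """Insert a new leaf on the edge above ``edge_child``.

        The edge is split at ``position`` (fraction measured from the
        parent); the new leaf hangs from the inserted node with
        ``pendant_length``.  Returns the new leaf node.
        """
        parent = edge_child.parent
        if parent is None:
            raise TreeError("cannot attach on the root (no edge)")
        mid = Node(None, edge_child.length * position)
        idx = parent.children.index(edge_child)
        parent.children[idx] = mid
        mid.parent = parent
        edge_child.length *= 1.0 - position
        mid.add_child(edge_child)
        leaf = Node(label, pendant_length)
        mid.add_child(leaf)
        return leaf

    # ------------------------------------------------------------- splits

    def bipartitions(self, nontrivial_only: bool = True) -> dict:
        """Map canonical split -> owning node.

        A split is represented as a frozenset of frozensets (the two sides).
        Trivial splits (one side a single leaf) are skipped by default.
        """
        universe = self.leaf_labels()
        below: dict[int, frozenset] = {}
        result: dict = {}
        for node in self.postorder():
            if node.is_leaf():
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children)
                )
            if node is self.root:
                continue
            side = below[id(node)]
            other = universe - side
            if nontrivial_only and (len(side) < 2 or len(other) < 2):
                continue
            result[frozenset([side, other])] = node
        return result

    def split_set(self) -> frozenset:
        return frozenset(self.bipartitions().keys())

    def clades(self) -> dict:
        """Map node -> frozenset of leaf labels below it (rooted view)."""
        below: dict[int, frozenset] = {}
        out: dict[Node, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf():
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children)
                )
            out[node] = below[id(node)]
        return out

    def edge_distance(self, node_a: Node, node_b: Node) -> int:
        """Topological distance between the edges owned by two nodes.

        Edges are contracted to midpoints: edges sharing an endpoint are at
        distance 1; an edge is at distance 0 only from itself.
        """
        if node_a is node_b:
            return 0
        ends_a = [node_a] + ([node_a.parent] if node_a.parent else [])
        ends_b = [node_b] + ([node_b.parent] if node_b.parent else [])
        best = min(
            _node_distance(u, v) for u in ends_a for v in ends_b
        )
        return best + 1


def _node_distance(u: Node, v: Node) -> int:
    """Number of edges on the path between two nodes of one tree."""

    def chain(n: Node) -> list[Node]:
        out = [n]
        while n.parent is not None:
            n = n.parent
            out.append(n)
        return out

    ca, cb = chain(u), chain(v)
    index_a = {id(n): i for i, n in enumerate(ca)}
    for j, n in enumerate(cb):
        if id(n) in index_a:
            return index_a[id(n)] + j
    raise TreeError("nodes not in the same tree")


# -------------------------------------------------------------- internals

_SUPPORT_LABEL = re.compile(r"^\s*([0-9.eE+-]+)\s*/\s*([0-9.eE+-]+)\s*$")
_COMMENT_META = re.compile(r"bs\s*=\s*([0-9.eE+-]+)|ab\s*=\s*([0-9.eE+-]+)")


def _error_offset(exc: Exception) -> Optional[int]:
    for attr in ("column", "col", "pos"):
        val = getattr(exc, attr, None)
        if isinstance(val, int):
            return val
    m = re.search(r"column (\d+)", str(exc))
    return int(m.group(1)) if m else None


def _from_dendropy(dnode) -> Node:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.is_leaf() and dnode.label:
        label = dnode.label
    node = Node(label, dnode.edge.length or 0.0)
    if not dnode.is_leaf():
        _parse_supports(dnode, node)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def _parse_supports(dnode, node: Node) -> None:
    raw = dnode.label
    if raw:
        m = _SUPPORT_LABEL.match(raw)
        if m:
            node.bs = float(m.group(1))
            node.abayes = float(m.group(2))
            return
        try:
            node.bs = float(raw)
            return
        except ValueError:
            pass
    comments = list(getattr(dnode, "comments", []) or [])
    comments += list(getattr(dnode.edge, "comments", []) or [])
    for comment in comments:
        for m in _COMMENT_META.finditer(comment):
            if m.group(1) is not None:
                node.bs = float(m.group(1))
            if m.group(2) is not None:
                node.abayes = float(m.group(2))


def _format_support(node: Node) -> str:
    if node.bs is None and node.abayes is None:
        return ""
    bs = "" if node.bs is None else f"{node.bs:g}"
    ab = "" if node.abayes is None else f"{node.abayes:g}"
    return f"{bs}/{ab}"


def _to_newick(node: Node, supports: bool, lengths: bool) -> str:
    if node.is_leaf():
        body = _quote_label(node.label or "")
    else:
        inner = ",".join(
            _to_newick(c, supports=supports, lengths=lengths)
            for c in node.children
        )
        label = _format_support(node) if supports else ""
        body = f"({inner}){label}"
    if lengths and node.parent is not None:
        body += f":{node.length:.10g}"
    return body


def _quote_label(label: str) -> str:
    if re.search(r"[\s(),:;\[\]']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ----------------------------------------------------------- constructors


def star_tree(labels: Iterable[str], length: float = 1.0) -> Tree:
    root = Node()
    for lab in labels:
        root.add_child(Node(lab, length))
    return Tree(root)


def random_binary_tree(labels: list[str], rng, min_len=0.05, max_len=0.5) -> Tree:
    """Random unrooted binary topology by sequential leaf addition."""
    if len(labels) < 3:
        raise TreeError("need >= 3 labels")

    def rlen() -> float:
        return float(min_len + (max_len - min_len) * rng.random())

    root = Node()
    for lab in labels[:3]:
        root.add_child(Node(lab, rlen()))
    tree = Tree(root)
    for lab in labels[3:]:
        edges = [n for n in tree.postorder() if n is not tree.root]
        target = edges[int(rng.integers(len(edges)))]
        tree.attach_at_edge(target, lab, rlen(), position=0.5)
    return tree


def rf_distance(a: Tree, b: Tree) -> int:
    """Robinson-Foulds distance via symmetric split-set difference."""
    sa, sb = a.split_set(), b.split_set()
    return len(sa ^ sb)
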