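"""Phylogenetic trees: a small node-based structure with Newick round-trip.

Unrooted trees are represented with a trifurcating root by convention.
Support values live on internal nodes (fraction in [0, 1]) and are written
as internal node labels in Newick. Canonical output orders every node's
children by their lexicographically smallest descendant leaf label, so two
topologically identical trees serialize to the same string.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .errors import ParseError


@dataclass
class TreeNode:
    name: str | None = None
    length: float | None = None  # branch length to the parent, subs/site
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def traverse_preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def traverse_postorder(self) -> Iterator["TreeNode"]:
        out: list[TreeNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        yield from reversed(out)

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.traverse_preorder() if n.is_leaf]


class PhyloTree:
    """A rooted representation of a (possibly unrooted) tree.

    Leaf labels must be unique and non-empty; branch lengths, when present,
    are finite and nonnegative.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        names = root.leaf_names()
        if any(not n for n in names):
            raise ValueError("every leaf needs a label")
        if len(set(names)) != len(names):
            raise ValueError("leaf labels must be unique")
        for node in root.traverse_preorder():
            if node.length is not None and not (node.length >= 0.0):
                raise ValueError(f"negative or non-finite branch length {node.length}")

    # -- queries ----------------------------------------------------------

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.traverse_preorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def find_leaf(self, name: str) -> TreeNode:
        for n in self.leaves:
            if n.name == name:
                return n
        raise KeyError(name)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalized as the side NOT containing
        the lexicographically smallest leaf label."""
        all_leaves = frozenset(self.leaf_names)
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()
        for node in self.root.traverse_postorder():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            if anchor in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                splits.add(side)
        return splits

    def clades(self) -> dict[frozenset[str], TreeNode]:
        """Map from descendant-leaf set to node, for every non-root node."""
        out = {}
        for node in self.root.traverse_postorder():
            if node is self.root:
                continue
            out[frozenset(node.leaf_names())] = node
        return out

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        up_a = self._ancestor_chain(self.find_leaf(a))
        up_b = self._ancestor_chain(self.find_leaf(b))
        seen = {id(n): d for n, d in up_a}
        for n, d in up_b:
            if id(n) in seen:
                return seen[id(n)] + d
        raise ValueError("leaves are not connected")

    @staticmethod
    def _ancestor_chain(node: TreeNode) -> list[tuple[TreeNode, float]]:
        chain, dist = [], 0.0
        while node is not None:
            chain.append((node, dist))
            dist += node.length or 0.0
            node = node.parent
        return chain

    # -- serialization ----------------------------------------------------

    def to_newick(self) -> str:
        return format_newick(self)

    def copy(self) -> "PhyloTree":
        return read_newick(self.to_newick())

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.to_newick()})"


# ---------------------------------------------------------------------------
# Newick writing (canonical form)
# ---------------------------------------------------------------------------

def _fmt_length(x: float) -> str:
    s = f"{x:.6g}"  # 6 significant digits
    if "." not in s and "e" not in s and "E" not in s:
        s += ".0"
    return s


def _min_leaf(node: TreeNode) -> str:
    return min(node.leaf_names())


def _write_node(node: TreeNode, is_root: bool) -> str:
    if node.is_leaf:
        body = node.name
    else:
        kids = sorted(node.children, key=_min_leaf)
        body = "(" + ",".join(_write_node(k, False) for k in kids) + ")"
        if node.support is not None and not is_root:
            body += f"{node.support:g}"
        elif node.name and not is_root:
            body += node.name
    if not is_root and node.length is not None:
        body += f":{_fmt_length(node.length)}"
    return body


def format_newick(tree: PhyloTree) -> str:
    return _write_node(tree.root, True) + ";"


# ---------------------------------------------------------------------------
# Newick reading (recursive descent with character offsets)
# ---------------------------------------------------------------------------

_LABEL_END = set("(),:;")


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> ParseError:
        return ParseError(f"newick: {msg}", position=self.pos)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def take(self) -> str:
        ch = self.peek()
        self.pos += 1
        return ch

    def skip_ws(self):
        while self.peek() in " \t\n\r":
            self.pos += 1

    def parse(self) -> TreeNode:
        self.skip_ws()
        node = self.parse_node(is_root=True)
        self.skip_ws()
        if self.peek() != ";":
            raise self.error("expected ';'")
        self.take()
        return node

    def parse_node(self, is_root: bool = False) -> TreeNode:
        self.skip_ws()
        node = TreeNode()
        if self.peek() == "(":
            self.take()
            while True:
                node.add_child(self.parse_node())
                self.skip_ws()
                ch = self.peek()
                if ch == ",":
                    self.take()
                    continue
                if ch == ")":
                    self.take()
                    break
                raise self.error("expected ',' or ')'")
            label = self.parse_label()
            if label:
                # internal labels are support values when numeric in [0,1]
                try:
                    val = float(label)
                except ValueError:
                    node.name = label
                else:
                    if 0.0 <= val <= 1.0:
                        node.support = val
                    else:
                        node.name = label
        else:
            name = self.parse_label()
            if not name:
                raise self.error("expected a leaf label or '('")
            node.name = name
        if self.peek() == ":":
            self.take()
            node.length = self.parse_number()
        return node

    def parse_label(self) -> str:
        start = self.pos
        while self.peek() and self.peek() not in _LABEL_END:
            self.pos += 1
        return self.text[start:self.pos].strip()

    def parse_number(self) -> float:
        start = self.pos
        while self.peek() and self.peek() not in _LABEL_END:
            self.pos += 1
        token = self.text[start:self.pos].strip()
        try:
            return float(token)
        except ValueError:
            self.pos = start
            raise self.error(f"bad branch length {token!r}")


def read_newick(text: str) -> PhyloTree:
    """Parse one Newick tree. Raises ParseError with a character offset."""
    parser = _Parser(text)
    root = parser.parse()
    return PhyloTree(root)
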