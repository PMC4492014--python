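"""Rooted phylogenetic trees and Newick serialization.

A tree is a mutable graph of :class:`TreeNode` objects.  Each node carries a
name (required and unique for tips, optional for internal nodes), the length
of the branch connecting it to its parent (``0.0`` when absent in the input;
the root's own length is parseable but ignored by all downstream metrics),
and an ordered list of children.  Multifurcations are permitted anywhere.

Newick conventions: quoted labels (``'...'`` with ``''`` escaping an embedded
quote) are supported; underscores in unquoted labels are preserved literally
(the behaviour of most modern tools, and required for replicate-tip names of
the form ``otu__sample__k`` to round-trip); bracketed comments are skipped.
An unrooted Newick file (trifurcating top-level node) is accepted and its top
node is treated as the root — rooting changes both UniFrac metrics, so callers
must ensure the file is rooted as intended.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Iterator


class NewickError(ValueError):
    """Malformed Newick text; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at character {offset})"
        super().__init__(message)
        self.offset = offset


class TreeValidationError(ValueError):
    """Structurally valid Newick that violates a tree invariant."""


class TreeNode:
    """A node in a rooted tree; the root is the node with ``parent is None``."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0,
                 children: list["TreeNode"] | None = None):
        self.name = name
        self.length = float(length)
        self.parent: TreeNode | None = None
        self.children: list[TreeNode] = []
        for child in children or []:
            self.add_child(child)

    # -- structure -------------------------------------------------------

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def add_child(self, node: "TreeNode") -> None:
        node.parent = self
        self.children.append(node)

    def remove_child(self, node: "TreeNode") -> None:
        self.children.remove(node)
        node.parent = None

    # -- traversal -------------------------------------------------------

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["TreeNode"]:
        # iterative two-stack postorder; children left-to-right before parent
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> Iterator["TreeNode"]:
        """Tips in left-to-right (preorder) order."""
        return (n for n in self.preorder() if n.is_tip)

    def tip_names(self) -> list[str]:
        return [t.name for t in self.tips()]

    def find(self, name: str) -> "TreeNode":
        for node in self.preorder():
            if node.name == name:
                return node
        raise KeyError(name)

    # -- derived quantities ----------------------------------------------

    def depths(self) -> dict["TreeNode", float]:
        """Path length from ``self`` to every descendant (self at depth 0).

        ``self``'s own branch length is excluded, so calling this on the root
        yields root-to-node distances with the (ignored) root length omitted.
        """
        out: dict[TreeNode, float] = {self: 0.0}
        for node in self.preorder():
            if node is self:
                continue
            out[node] = out[node.parent] + node.length
        return out

    def bipartitions(self) -> Counter:
        """Multiset of (descendant-tip-name frozenset, branch length) pairs.

        One entry per non-root branch; used to compare topologies without
        caring about child order or internal labels.
        """
        below: dict[TreeNode, frozenset] = {}
        parts: Counter = Counter()
        for node in self.postorder():
            if node.is_tip:
                below[node] = frozenset([node.name])
            else:
                below[node] = frozenset().union(*(below[c] for c in node.children))
            if not node.is_root:
                parts[(below[node], round(node.length, 12))] += 1
        return parts

    def copy(self) -> "TreeNode":
        mapping: dict[TreeNode, TreeNode] = {}
        for node in self.preorder():
            clone = TreeNode(node.name, node.length)
            mapping[node] = clone
            if node is not self:
                mapping[node.parent].add_child(clone)
        return mapping[self]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<TreeNode {self.name!r} {kind} length={self.length}>"


def validate_tree(root: TreeNode) -> None:
    """Raise :class:`TreeValidationError` on any invariant violation."""
    seen: set[str] = set()
    for node in root.preorder():
        if node.length < 0:
            raise TreeValidationError(
                f"negative branch length {node.length} on node {node.name!r}")
        for child in node.children:
            if child.parent is not node:
                raise TreeValidationError("inconsistent parent pointer")
        if node.is_tip and node is not root:
            if not node.name:
                raise TreeValidationError("tip without a name")
            if node.name in seen:
                raise TreeValidationError(f"duplicate tip name: {node.name!r}")
            seen.add(node.name)


_NUMBER = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")
_UNQUOTED_STOP = set("(),:;[]'") | set(" \t\r\n")


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, message: str) -> NewickError:
        return NewickError(message, self.pos)

    def skip(self) -> None:
        text = self.text
        while self.pos < len(text):
            ch = text[self.pos]
            if ch in " \t\r\n":
                self.pos += 1
            elif ch == "[":  # comment
                end = text.find("]", self.pos)
                if end < 0:
                    raise self.error("unterminated comment")
                self.pos = end + 1
            else:
                return

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def parse(self) -> TreeNode:
        self.skip()
        root = self.clade()
        self.skip()
        if self.peek() != ";":
            raise self.error("expected ';' terminating the tree")
        self.pos += 1
        self.skip()
        if self.pos != len(self.text):
            raise self.error("trailing content after ';'")
        return root

    def clade(self) -> TreeNode:
        self.skip()
        node = TreeNode()
        if self.peek() == "(":
            self.pos += 1
            while True:
                node.add_child(self.clade())
                self.skip()
                ch = self.peek()
                if ch == ",":
                    self.pos += 1
                elif ch == ")":
                    self.pos += 1
                    break
                else:
                    raise self.error("expected ',' or ')'")
        node.name = self.label()
        self.skip()
        if self.peek() == ":":
            self.pos += 1
            self.skip()
            match = _NUMBER.match(self.text, self.pos)
            if not match:
                raise self.error("expected a branch length after ':'")
            node.length = float(match.group())
            self.pos = match.end()
        return node

    def label(self) -> str | None:
        self.skip()
        text = self.text
        if self.peek() == "'":
            self.pos += 1
            chars: list[str] = []
            while True:
                if self.pos >= len(text):
                    raise self.error("unterminated quoted label")
                ch = text[self.pos]
                if ch == "'":
                    if self.pos + 1 < len(text) and text[self.pos + 1] == "'":
                        chars.append("'")
                        self.pos += 2
                    else:
                        self.pos += 1
                        return "".join(chars)
                else:
                    chars.append(ch)
                    self.pos += 1
        start = self.pos
        while self.pos < len(text) and text[self.pos] not in _UNQUOTED_STOP:
            self.pos += 1
        return text[start:self.pos] or None


def parse_newick(text: str) -> TreeNode:
    """Parse a single Newick statement into a validated tree.

    Raises :class:`NewickError` (with character offset) on malformed input and
    :class:`TreeValidationError` on duplicate/empty tip names or negative
    branch lengths.
    """
    root = _Parser(text).parse()
    validate_tree(root)
    return root


_NEEDS_QUOTING = re.compile(r"[\s(),:;\[\]']")


def _format_label(name: str | None) -> str:
    if name is None:
        return ""
    if name == "" or _NEEDS_QUOTING.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(root: TreeNode) -> str:
    """Serialize a tree; ``parse_newick(write_newick(t))`` is isomorphic to ``t``.

    Branch lengths are written with ``repr`` (shortest exact round-trip form),
    so lengths survive to full float precision.
    """
    rendered: dict[TreeNode, str] = {}
    for node in root.postorder():
        if node.is_tip:
            body = _format_label(node.name)
        else:
            inner = ",".join(rendered.pop(c) for c in node.children)
            body = f"({inner}){_format_label(node.name)}"
        if node.parent is not None:
            body += f":{node.length!r}"
        elif node.length:
            body += f":{node.length!r}"
        rendered[node] = body
    return rendered[root] + ";"
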