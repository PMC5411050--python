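"""Rooted phylogenetic trees in Newick format.

Parsing, validation, depth/path queries and serialization. Trees are kept
rooted exactly as written: a basal trifurcation becomes a root with three
children and is never re-rooted. Node ids are assigned depth-first in
pre-order so that every downstream tie-break is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional


class NewickError(ValueError):
    """Malformed Newick input; ``offset`` is the character position."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


@dataclass(eq=False)
class TreeNode:
    """One node of a rooted tree.

    ``branch_length`` is the length of the edge to the parent in tree
    units; the root carries none. ``support`` holds a bootstrap score when
    the Newick internal label was numeric. ``depth`` counts edges from the
    root (root depth 0).
    """

    id: int = -1
    name: str = ""
    branch_length: Optional[float] = None
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = field(default=None, repr=False)
    depth: int = 0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def ancestors(self) -> Iterator["TreeNode"]:
        """Yield parent, grandparent, ... up to and including the root."""
        node = self.parent
        while node is not None:
            yield node
            node = node.parent

    def ancestor_at_depth(self, level: int) -> "TreeNode":
        if not 0 <= level <= self.depth:
            raise ValueError(
                f"level {level} out of range for node at depth {self.depth}"
            )
        node: TreeNode = self
        while node.depth > level:
            assert node.parent is not None
            node = node.parent
        return node


@dataclass
class PhyloTree:
    """A rooted tree plus the derived indices the layout pipeline needs."""

    root: TreeNode
    leaves: list[TreeNode] = field(default_factory=list)
    max_depth: int = 0
    total_length: float = 0.0

    def __post_init__(self) -> None:
        if not self.leaves:
            self._reindex()

    def _reindex(self) -> None:
        """Assign ids/depths depth-first and rebuild the leaf list."""
        self.leaves = []
        self.total_length = 0.0
        self.max_depth = 0
        next_id = 0
        stack = [(self.root, None, 0)]
        while stack:
            node, parent, depth = stack.pop()
            node.id = next_id
            next_id += 1
            node.parent = parent
            node.depth = depth
            if parent is not None:
                self.total_length += node.branch_length or 0.0
            if node.is_leaf:
                self.leaves.append(node)
                self.max_depth = max(self.max_depth, depth)
            for child in reversed(node.children):
                stack.append((child, node, depth + 1))

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def nodes(self) -> Iterator[TreeNode]:
        """All nodes in pre-order (id order)."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def node_by_id(self, node_id: int) -> TreeNode:
        for node in self.nodes():
            if node.id == node_id:
                return node
        raise KeyError(f"no node with id {node_id}")


_TOKEN_CHARS_END = set("(),:;[]'")


def _parse_label(text: str, i: int) -> tuple[str, bool, int]:
    """Read a (possibly quoted) label starting at ``i``.

    Returns (label, was_quoted, next_index).
    """
    if i < len(text) and text[i] == "'":
        j = i + 1
        out = []
        while j < len(text):
            if text[j] == "'":
                if j + 1 < len(text) and text[j + 1] == "'":  # escaped quote
                    out.append("'")
                    j += 2
                    continue
                return "".join(out), True, j + 1
            out.append(text[j])
            j += 1
        raise NewickError("unterminated quoted label", i)
    j = i
    while j < len(text) and text[j] not in _TOKEN_CHARS_END and not text[j].isspace():
        j += 1
    return text[i:j], False, j


def _parse_number(text: str, i: int, what: str) -> tuple[float, int]:
    j = i
    while j < len(text) and (text[j] not in _TOKEN_CHARS_END) and not text[j].isspace():
        j += 1
    token = text[i:j]
    try:
        return float(token), j
    except ValueError:
        raise NewickError(f"invalid {what} {token!r}", i) from None


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def parse_newick(text: str, default_branch_length: float = 1.0) -> PhyloTree:
    """Parse one Newick statement into a :class:`PhyloTree`.

    Missing branch lengths are replaced by ``default_branch_length``
    (1.0 by default, so a length-free cladogram still lays out). Internal
    labels that parse as numbers are stored as bootstrap ``support``
    following the dominant Newick dialect; quoted labels are always names.
    A negative branch length, unbalanced parentheses, empty input or a
    second tree raise :class:`NewickError` naming the character offset.
    """
    if text is None or not text.strip():
        raise NewickError("empty Newick input", 0)

    i = 0
    n = len(text)
    while i < n and text[i].isspace():
        i += 1

    root = TreeNode()
    cur = root
    depth_guard = 0  # open parens
    seen_semicolon_at = -1

    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c == "(":
            child = TreeNode(parent=cur)
            cur.children.append(child)
            cur = child
            depth_guard += 1
            i += 1
        elif c == ",":
            if cur.parent is None:
                raise NewickError("comma outside parentheses", i)
            sibling = TreeNode(parent=cur.parent)
            cur.parent.children.append(sibling)
            cur = sibling
            i += 1
        elif c == ")":
            if cur.parent is None or depth_guard == 0:
                raise NewickError("unbalanced parentheses: unexpected ')'", i)
            cur = cur.parent
            depth_guard -= 1
            i += 1
        elif c == ":":
            i += 1
            value, i = _parse_number(text, i, "branch length")
            if value < 0:
                raise NewickError(f"negative branch length {value}", i - 1)
            cur.branch_length = value
        elif c == ";":
            seen_semicolon_at = i
            i += 1
            break
        elif c == "[":  # Newick comment, skipped
            j = text.find("]", i)
            if j < 0:
                raise NewickError("unterminated comment", i)
            i = j + 1
        else:
            label, quoted, i = _parse_label(text, i)
            if not label:
                raise NewickError(f"unexpected character {c!r}", i)
            if cur.children and not quoted and _is_number(label):
                cur.support = float(label)
            else:
                cur.name = label

    if depth_guard != 0:
        raise NewickError("unbalanced parentheses: unclosed '('", n - 1)
    if seen_semicolon_at < 0:
        raise NewickError("missing ';' terminator", n - 1)
    rest = text[i:].strip()
    if rest:
        raise NewickError("trailing content after ';' (multiple trees?)", i)

    root.branch_length = None  # a root edge length has no meaning here

    for node in _preorder(root):
        if node is not root and node.branch_length is None:
            node.branch_length = default_branch_length

    return PhyloTree(root=root)


def _preorder(root: TreeNode) -> Iterator[TreeNode]:
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(node.children))


def _format_length(x: float) -> str:
    return f"{x:.6g}"


def _node_suffix(node: TreeNode, is_root: bool) -> str:
    parts = []
    if node.is_leaf:
        parts.append(_quote_if_needed(node.name))
    else:
        if node.name:
            parts.append(_quote_if_needed(node.name))
        elif node.support is not None:
            s = node.support
            parts.append(f"{int(s)}" if float(s).is_integer() else f"{s:g}")
    if not is_root and node.branch_length is not None:
        parts.append(f":{_format_length(node.branch_length)}")
    return "".join(parts)


def _quote_if_needed(name: str) -> str:
    if name and (set(name) & _TOKEN_CHARS_END or any(ch.isspace() for ch in name)):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: PhyloTree) -> str:
    """Serialize to Newick; lengths at 6 significant digits.

    ``parse_newick(write_newick(t))`` reproduces topology, names, supports
    and branch lengths. Unnamed internal nodes emit no label unless a
    support value is present. Iterative, so arbitrarily deep (pectinate)
    trees serialize without recursion limits.
    """
    out: list[str] = []
    # frames: ("enter", node), ("exit", node), ("comma", None)
    stack: list[tuple[str, Optional[TreeNode]]] = [("enter", tree.root)]
    while stack:
        kind, node = stack.pop()
        if kind == "comma":
            out.append(",")
        elif kind == "enter":
            assert node is not None
            if node.is_leaf:
                out.append(_node_suffix(node, node is tree.root))
            else:
                out.append("(")
                stack.append(("exit", node))
                for k, child in enumerate(reversed(node.children)):
                    stack.append(("enter", child))
                    if k < len(node.children) - 1:
                        stack.append(("comma", None))
        else:  # exit
            assert node is not None
            out.append(")")
            out.append(_node_suffix(node, node is tree.root))
    out.append(";")
    return "".join(out)


def mrca_depth(tree: PhyloTree, u: TreeNode, v: TreeNode) -> int:
    """Depth of the most recent common ancestor of two distinct nodes.

    0 means the pair is related only at the root.
    """
    if u is v:
        raise ValueError("mrca_depth requires two distinct nodes")
    ancestors_u = {id(a) for a in u.ancestors()}
    ancestors_u.add(id(u))
    node: Optional[TreeNode] = v
    while node is not None:
        if id(node) in ancestors_u:
            return node.depth
        node = node.parent
    raise ValueError("nodes do not share a root: not in the same tree")


def path_length_to_ancestor(leaf: TreeNode, level: int) -> float:
    """Cumulative branch length from ``leaf`` up to its depth-``level``
    ancestor, exclusive of that ancestor's own edge.

    0 at ``level == depth(leaf)``; non-increasing as ``level`` grows.
    """
    if not 0 <= level <= leaf.depth:
        raise ValueError(
            f"level {level} out of range 0..{leaf.depth} for this leaf"
        )
    total = 0.0
    node = leaf
    while node.depth > level:
        total += node.branch_length or 0.0
        assert node.parent is not None
        node = node.parent
    return total
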