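"""Phylogenetic trees: Newick I/O, MRCA queries, outgroup rooting.

Trees are stored as parent/child linked :class:`TreeNode` objects under a
single top node.  A tree whose top node has exactly two children is treated
as rooted; a basal multifurcation marks an unrooted tree (the usual Newick
convention).  Branch lengths are substitutions/site, ``>= 0``; absent
lengths default to ``0.0`` so topology-only reference trees parse cleanly.

Coordinates of the Newick dialect: quoted labels (``'...'``) and internal
node names are accepted; bracketed comments are stripped before parsing.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterator


class NewickError(ValueError):
    """Raised on malformed Newick input; message names the position/token."""


class TreeError(ValueError):
    """Raised on invalid tree operations (e.g. MRCA on an unrooted tree)."""


_counter = itertools.count()


@dataclass(eq=False)
class TreeNode:
    name: str | None = None
    length: float = 0.0
    parent: "TreeNode | None" = None
    children: list["TreeNode"] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._uid = next(_counter)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

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
        return reversed(out)

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.traverse_preorder() if n.is_leaf]

    def leaf_names(self) -> set[str]:
        return {n.name for n in self.leaves() if n.name is not None}


class PhyloTree:
    """A tree over taxon-labelled leaves.

    Parameters
    ----------
    root:
        Top node of the parent/child structure.
    rooted:
        If ``None``, inferred: a top node with exactly two children (or a
        single leaf/unary chain) means rooted, three or more means unrooted.
    """

    def __init__(self, root: TreeNode, rooted: bool | None = None):
        self.root = root
        if rooted is None:
            rooted = len(root.children) <= 2
        self.rooted = rooted
        self._index: dict[str, TreeNode] = {}
        seen: set[str] = set()
        for node in root.traverse_preorder():
            if node.is_leaf:
                if node.name is None or node.name == "":
                    raise TreeError("tree contains an unlabelled leaf")
                if node.name in seen:
                    raise TreeError(f"duplicate leaf label {node.name!r}")
                seen.add(node.name)
            if node.name:
                self._index.setdefault(node.name, node)

    # -- basic queries ---------------------------------------------------

    def nodes(self) -> list[TreeNode]:
        return list(self.root.traverse_preorder())

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_names(self) -> set[str]:
        return self.root.leaf_names()

    def find(self, name: str) -> TreeNode:
        try:
            return self._index[name]
        except KeyError:
            raise TreeError(f"no node named {name!r} in tree") from None

    def leaves_under(self, name: str) -> set[str]:
        """Leaf labels of the subtree rooted at the named node."""
        return self.find(name).leaf_names()

    def mrca(self, taxa: set[str] | frozenset[str]) -> TreeNode:
        """Most recent common ancestor of the given leaf labels.

        Requires a rooted tree; a singleton query returns the leaf itself.
        """
        if not self.rooted:
            raise TreeError("MRCA requires a rooted tree; root it first "
                            "(e.g. with root_with_outgroup)")
        if not taxa:
            raise TreeError("MRCA query set is empty")
        leaf_by_name = {n.name: n for n in self.leaves()}
        unknown = set(taxa) - leaf_by_name.keys()
        if unknown:
            raise TreeError(f"unknown taxa in MRCA query: {sorted(unknown)}")
        paths = []
        for t in sorted(taxa):
            node: TreeNode | None = leaf_by_name[t]
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(list(reversed(path)))
        mrca = paths[0][0]
        for depth in range(min(len(p) for p in paths)):
            first = paths[0][depth]
            if all(p[depth] is first for p in paths):
                mrca = first
            else:
                break
        return mrca

    # -- bipartitions ----------------------------------------------------

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each encoded as the side not containing an
        arbitrary fixed reference leaf (canonical for unrooted comparison)."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        splits: set[frozenset[str]] = set()
        for node in self.root.traverse_preorder():
            if node is self.root:
                continue
            side = frozenset(node.leaf_names())
            if ref in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(side)
        return splits

    def robinson_foulds(self, other: "PhyloTree") -> int:
        if self.leaf_names() != other.leaf_names():
            raise TreeError("RF distance requires identical leaf sets")
        a, b = self.bipartitions(), other.bipartitions()
        return len(a ^ b)

    # -- output ----------------------------------------------------------

    def write(self, lengths: bool = True, support: bool = False) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                core = _quote_label(node.name or "")
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = _quote_label(node.name) if node.name else ""
                core = f"({inner}){label}"
            if lengths and node.parent is not None:
                core += f":{node.length:.10g}"
            return core

        return fmt(self.root) + ";"

    def copy(self) -> "PhyloTree":
        return parse_newick(self.write(), rooted=self.rooted)


_NEEDS_QUOTE = re.compile(r"[\s(),:;\[\]']")


def _quote_label(name: str) -> str:
    if name and _NEEDS_QUOTE.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


# -- parsing -------------------------------------------------------------

_COMMENT = re.compile(r"\[[^\]]*\]")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    """Yield (kind, value, pos) tokens; kind in {punct, label}."""
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in "(),:;":
            tokens.append(("punct", ch, i))
            i += 1
        elif ch == "'":
            j = i + 1
            buf = []
            while True:
                if j >= n:
                    raise NewickError(f"unterminated quoted label at position {i}")
                if text[j] == "'":
                    if j + 1 < n and text[j + 1] == "'":
                        buf.append("'")
                        j += 2
                        continue
                    break
                buf.append(text[j])
                j += 1
            tokens.append(("label", "".join(buf), i))
            i = j + 1
        else:
            j = i
            while j < n and text[j] not in "(),:;'[] \t\n\r":
                j += 1
            tokens.append(("label", text[i:j], i))
            i = j
    return tokens


def parse_newick(text: str, rooted: bool | None = None) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Bracketed comments are stripped; quoted labels honoured; missing branch
    lengths default to 0.  Raises :class:`NewickError` naming the offending
    position for unbalanced parentheses, trailing garbage or empty input,
    and :class:`TreeError` for duplicate leaf labels.
    """
    text = _COMMENT.sub("", text).strip()
    if not text:
        raise NewickError("empty Newick string")
    if not text.endswith(";"):
        raise NewickError("Newick string must be terminated by ';'")
    tokens = _tokenize(text)
    pos = 0

    def peek() -> tuple[str, str, int] | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> tuple[str, str, int]:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise NewickError("unexpected end of input")
        pos += 1
        return tok

    def parse_clade() -> TreeNode:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise NewickError("unexpected end of input")
        node = TreeNode()
        if tok[0] == "punct" and tok[1] == "(":
            take()
            while True:
                node.add_child(parse_clade())
                sep = take()
                if sep[0] != "punct" or sep[1] not in ",)":
                    raise NewickError(
                        f"expected ',' or ')' at position {sep[2]}, got {sep[1]!r}")
                if sep[1] == ")":
                    break
        tok = peek()
        if tok is not None and tok[0] == "label":
            node.name = take()[1]
        tok = peek()
        if tok is not None and tok == ("punct", ":", tok[2]):
            take()
            num = take()
            if num[0] != "label":
                raise NewickError(f"expected branch length at position {num[2]}")
            try:
                node.length = float(num[1])
            except ValueError:
                raise NewickError(
                    f"invalid branch length {num[1]!r} at position {num[2]}") from None
        if node.is_leaf and not node.name:
            raise NewickError("unlabelled leaf in Newick string")
        return node

    root = parse_clade()
    tok = take()
    if tok != ("punct", ";", tok[2]):
        raise NewickError(f"unbalanced parentheses: expected ';' at position {tok[2]}")
    if pos != len(tokens):
        raise NewickError(f"trailing content after ';' at position {tokens[pos][2]}")
    return PhyloTree(root, rooted=rooted)


def read_newick(path: str) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: PhyloTree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(tree.write() + "\n")


# -- rooting -------------------------------------------------------------

def root_with_outgroup(tree: PhyloTree, outgroup: set[str]) -> PhyloTree:
    """Root an unrooted tree on the edge separating ``outgroup`` from the rest.

    The outgroup must form a clan (one side of some edge); otherwise a
    :class:`TreeError` is raised rather than silently forcing a root.  A
    single-leaf outgroup roots at the midpoint of its pendant edge.
    """
    outgroup = set(outgroup)
    all_leaves = tree.leaf_names()
    if not outgroup or not outgroup < all_leaves:
        raise TreeError("outgroup must be a non-empty proper subset of the leaves")

    work = tree.copy()
    # Find the edge (child side) whose leaf set equals the outgroup or its
    # complement; rerooting happens on that edge.
    target: TreeNode | None = None
    for node in work.root.traverse_preorder():
        if node is work.root:
            continue
        side = node.leaf_names()
        if side == outgroup:
            target = node
            break
        if side == all_leaves - outgroup:
            target = node
            break
    if target is None:
        raise TreeError(
            f"outgroup {sorted(outgroup)} does not form a clan in the tree")

    # Invert the path from target's parent up to the old top node.
    edge_len = target.length
    new_root = TreeNode(name=None)
    old_parent = target.parent
    assert old_parent is not None
    old_parent.children.remove(target)

    new_root.add_child(target)
    target.length = edge_len / 2.0

    # Reverse parent pointers along the chain old_parent -> ... -> old root.
    chain: list[TreeNode] = []
    node: TreeNode | None = old_parent
    while node is not None:
        chain.append(node)
        node = node.parent
    prev = new_root
    prev_len = edge_len / 2.0
    for node in chain:
        parent = node.parent
        if parent is not None:
            parent.children.remove(node)
        node.parent = None
        this_len = node.length
        prev.add_child(node)
        node.length = prev_len
        prev_len = this_len
        prev = node
    # The old top node may now be a unary internal node; splice it out.
    _suppress_unary(new_root)
    return PhyloTree(new_root, rooted=True)


def _suppress_unary(root: TreeNode) -> None:
    for node in list(root.traverse_postorder()):
        if node is root or node.is_leaf:
            continue
        if len(node.children) == 1:
            child = node.children[0]
            parent = node.parent
            assert parent is not None
            child.length += node.length
            idx = parent.children.index(node)
            parent.children[idx] = child
            child.parent = parent
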