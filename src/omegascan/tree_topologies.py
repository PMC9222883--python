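"""Newick trees, foreground-branch labelling, and exhaustive enumeration of
single-foreground topologies.

Branch and branch-site tests mark exactly one branch of the phylogeny as
*foreground* with the ``#1`` tag of the codeml Newick dialect, e.g.
``((A,B) #1,C);``.  This module parses and writes that dialect, checks
tree/alignment consistency, and enumerates every possible foreground branch
— one labelled copy of the tree per branch — in a deterministic depth-first
order.  Rooted bifurcating input is treated as unrooted for branch counting
(the two root-adjacent edges are one branch), matching codeml, so a fully
resolved tree with n leaves yields 2n-3 labelled topologies.

Branch identifiers are stable strings built from the sorted leaf set under
the branch (e.g. ``"A|B"``), so they survive serialization and parallel
execution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "TreeNode",
    "PhyloTree",
    "LabelledTopology",
    "parse_newick",
    "enumerate_foreground_topologies",
    "write_labelled_newick",
    "check_tree_alignment_consistency",
]


@dataclass
class TreeNode:
    name: Optional[str] = None
    length: Optional[float] = None
    label: Optional[int] = None  # codeml branch mark: 1 for "#1"
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self


class PhyloTree:
    """A rooted tree structure interpreted, where it matters, as unrooted."""

    def __init__(self, root: TreeNode):
        self.root = root
        names = root.leaf_names()
        if any(n is None for n in names):
            raise ValueError("all leaves must be named")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf names: {dupes}")
        if not names:
            raise ValueError("empty tree")

    @property
    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def copy(self) -> "PhyloTree":
        return parse_newick(self.to_newick())

    def nodes(self) -> list[TreeNode]:
        return list(self.root.preorder())

    def branch_nodes(self) -> list[TreeNode]:
        """Nodes subtending a distinct branch, in depth-first (preorder)
        enumeration order, under the unrooted interpretation.

        Every non-root node defines the branch to its parent.  When the root
        is a bifurcation, its two child edges are the same unrooted branch;
        the second child's edge is dropped as the duplicate.
        """
        nodes = [n for n in self.root.preorder() if n is not self.root]
        if len(self.root.children) == 2 and self.n_leaves >= 3:
            dup = self.root.children[1]
            nodes = [n for n in nodes if n is not dup]
        return nodes

    def branch_ids(self) -> list[str]:
        return [branch_id(n) for n in self.branch_nodes()]

    def clear_labels(self) -> None:
        for node in self.root.preorder():
            node.label = None

    def to_newick(self, include_lengths: bool = True) -> str:
        return _serialize(self.root, include_lengths) + ";"


def branch_id(node: TreeNode) -> str:
    """Stable branch identifier: sorted leaf names under the branch."""
    return "|".join(sorted(node.leaf_names()))


# ---------------------------------------------------------------------------
# Newick parsing (codeml dialect: optional "#<k>" branch marks)
# ---------------------------------------------------------------------------

_TOKEN = re.compile(
    r"\s*(?:(?P<punct>[(),;])"
    r"|(?P<quoted>'[^']*')"
    r"|(?P<word>[^\s(),;:#]+)"
    r"|(?P<colon>:)"
    r"|(?P<hash>#\s*\d+))"
)


class _Tokenizer:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def next(self) -> Optional[str]:
        if self.pos >= len(self.text):
            return None
        m = _TOKEN.match(self.text, self.pos)
        if m is None:
            raise ValueError(
                f"unexpected character at position {self.pos}: {self.text[self.pos:self.pos+10]!r}"
            )
        self.pos = m.end()
        return m.group().strip()

    def peek(self) -> Optional[str]:
        saved = self.pos
        tok = self.next()
        self.pos = saved
        return tok


def _is_punct(token: str) -> bool:
    return token in {"(", ")", ",", ";", ":"} or token.startswith("#")


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string, honouring codeml ``#1``-style branch marks.

    Marks may follow a leaf name, a closing parenthesis, or a branch length,
    with or without intervening whitespace.  Branch lengths and internal node
    names are optional.  ``serialize(parse(x))`` preserves topology, lengths
    and marks.
    """
    text = text.strip()
    if not text:
        raise ValueError("empty Newick string")
    tok = _Tokenizer(text)
    root = _parse_clade(tok)
    tail = tok.next()
    if tail != ";":
        raise ValueError(f"expected ';' at end of Newick string, got {tail!r}")
    return PhyloTree(root)


def _parse_clade(tok: _Tokenizer) -> TreeNode:
    node = TreeNode()
    nxt = tok.peek()
    if nxt == "(":
        tok.next()
        while True:
            node.children.append(_parse_clade(tok))
            node.children[-1].parent = node
            sep = tok.next()
            if sep == ",":
                continue
            if sep == ")":
                break
            raise ValueError(f"unbalanced parentheses: got {sep!r}")
        nxt = tok.peek()
        if nxt is not None and not _is_punct(nxt):
            node.name = _unquote(tok.next())
    elif nxt is None or _is_punct(nxt) or nxt == "(":
        raise ValueError(f"expected a clade, got {nxt!r}")
    else:
        node.name = _unquote(tok.next())
    # optional "#k" then ":length" in either order (codeml writes "name #1:t")
    for _ in range(2):
        nxt = tok.peek()
        if nxt is not None and nxt.startswith("#"):
            tok.next()
            node.label = int(nxt[1:].strip())
        elif nxt == ":":
            tok.next()
            length = tok.next()
            try:
                node.length = float(length)
            except (TypeError, ValueError):
                raise ValueError(f"invalid branch length {length!r}") from None
    return node


def _unquote(word: str) -> str:
    if word.startswith("'") and word.endswith("'"):
        return word[1:-1]
    return word


def _serialize(node: TreeNode, include_lengths: bool) -> str:
    if node.is_leaf:
        out = node.name or ""
    else:
        inner = ",".join(_serialize(c, include_lengths) for c in node.children)
        out = f"({inner})" + (node.name or "")
    if node.label is not None:
        out += f" #{node.label}"
    if include_lengths and node.length is not None:
        out += f":{node.length:g}"
    return out


# ---------------------------------------------------------------------------
# Foreground enumeration
# ---------------------------------------------------------------------------


@dataclass
class LabelledTopology:
    """One copy of the base tree with a single branch marked ``#1``."""

    tree: PhyloTree
    foreground_branch: str
    index: int

    def newick(self, include_lengths: bool = True) -> str:
        return self.tree.to_newick(include_lengths)


def enumerate_foreground_topologies(tree: PhyloTree) -> list[LabelledTopology]:
    """One labelled topology per branch of the (unrooted) tree.

    Any pre-existing marks are cleared.  Order is deterministic: depth-first
    over the input tree with children in input order.  A fully resolved
    unrooted tree with n leaves yields exactly 2n-3 topologies; polytomies
    yield one per actual edge.
    """
    if tree.n_leaves < 3:
        raise ValueError(f"need at least 3 leaves to enumerate branches, got {tree.n_leaves}")
    ids = tree.branch_ids()
    topologies: list[LabelledTopology] = []
    for index, target in enumerate(ids):
        labelled = tree.copy()
        labelled.clear_labels()
        for node in labelled.branch_nodes():
            if branch_id(node) == target:
                node.label = 1
                break
        else:  # pragma: no cover - ids come from an identical copy
            raise RuntimeError(f"branch {target} not found in copied tree")
        topologies.append(
            LabelledTopology(tree=labelled, foreground_branch=target, index=index)
        )
    return topologies


def write_labelled_newick(topology: LabelledTopology) -> str:
    """Serialize a labelled topology; exactly one branch carries ``#1``."""
    text = topology.newick()
    if text.count("#") != 1:
        raise ValueError(f"expected exactly one '#1' mark, got: {text}")
    return text


def check_tree_alignment_consistency(tree: PhyloTree, taxa: list[str]) -> None:
    """Raise unless the tree's leaf set equals the alignment's taxon set."""
    tree_set = set(tree.leaf_names)
    aln_set = set(taxa)
    if tree_set != aln_set:
        only_tree = sorted(tree_set - aln_set)
        only_aln = sorted(aln_set - tree_set)
        raise ValueError(
            "tree and alignment name sets differ: "
            f"only in tree {only_tree}, only in alignment {only_aln}"
        )
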