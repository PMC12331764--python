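"""Constituency trees in bracket notation, tree positions, and node tags.

A constituency (phrase-structure) tree analyses a sentence as nested,
labeled phrases: words combine into noun phrases (NP), verb phrases (VP),
prepositional phrases (PP), and so on, up to a sentence node S.  Trees are
exchanged as Penn-Treebank-style bracket strings, e.g.::

    (S (NP (PRP I)) (VP (VBP like) (NP (NNS apples))))

Every node is addressed by its *tree position*: the sequence of child
indices from a virtual super-root, so the sentence node is ``(0,)``, its
first child ``(0, 0)``, and so forth.  The string encoding of a position
("00", "011", ...) appended to the node's label yields a tag such as
``NP/00`` that is unique within the sentence even when the bare label
repeats.  Tags are the currency of the whole alignment pipeline: each word
row in the alignment table carries the tags of every node dominating it.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from typing import Iterator, Sequence

__all__ = [
    "SyntaxTree",
    "NodeTag",
    "TreePosition",
    "ParseError",
    "PositionError",
    "parse_bracket",
    "to_bracket",
    "read_trees",
    "leaf_positions",
    "prefix_paths",
    "node_tag",
    "node_at",
    "encode_position",
    "decode_position",
]

#: A tree position is a tuple of child indices measured from the virtual
#: super-root; the sentence node is ``(0,)``.
TreePosition = tuple[int, ...]

#: Labels treated as an outer wrapper that the virtual root absorbs.
ROOT_LABELS = frozenset({"ROOT", "TOP", ""})


class ParseError(ValueError):
    """Malformed bracket input; carries the character offset of the fault."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class PositionError(IndexError):
    """A tree position that does not address a node of the given tree."""


@dataclass(frozen=True)
class SyntaxTree:
    """A node of a constituency tree.

    Internal nodes carry a phrase or part-of-speech label and an ordered
    tuple of children.  A terminal (the word itself) is a childless node
    whose ``label`` is the token, so a preterminal like ``(DT The)`` is an
    internal node with one terminal child.
    """

    label: str
    children: tuple["SyntaxTree", ...] = ()

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("every node needs a non-empty label/token")

    @property
    def is_terminal(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        """Token sequence, left to right."""
        if self.is_terminal:
            return [self.label]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def __iter__(self) -> Iterator["SyntaxTree"]:
        return iter(self.children)


@dataclass(frozen=True)
class NodeTag:
    """A node's label plus its encoded position: the unique identifier.

    ``encoding`` selects how the position renders: ``"concat"`` joins the
    child indices without separator ("NP/00", matching the conventional
    table layout, valid only while every arity is below 10) and
    ``"dotted"`` joins with dots ("NP/0.0"), unambiguous for any arity.
    """

    label: str
    position: TreePosition
    encoding: str = field(default="concat", compare=False)

    @property
    def id(self) -> str:
        return f"{self.label}/{encode_position(self.position, self.encoding)}"

    @property
    def depth(self) -> int:
        return len(self.position)

    def __str__(self) -> str:
        return self.id


def encode_position(position: Sequence[int], encoding: str = "concat") -> str:
    """Render a position as a string ("0110" or "0.1.1.0").

    The concatenated form is ambiguous once a node has ten or more
    children, so it refuses indices above 9; switch to ``dotted`` there.
    """
    if encoding == "concat":
        if any(i > 9 for i in position):
            raise PositionError(
                f"child index >= 10 in {tuple(position)} cannot be encoded "
                "unambiguously in concatenated mode; use encoding='dotted'"
            )
        return "".join(str(i) for i in position)
    if encoding == "dotted":
        return ".".join(str(i) for i in position)
    raise ValueError(f"unknown position encoding {encoding!r}")


def decode_position(text: str, encoding: str = "concat") -> TreePosition:
    """Inverse of :func:`encode_position`."""
    if not text:
        raise ValueError("empty position string")
    if encoding == "concat":
        if not text.isdigit():
            raise ValueError(f"bad concatenated position {text!r}")
        return tuple(int(ch) for ch in text)
    if encoding == "dotted":
        return tuple(int(part) for part in text.split("."))
    raise ValueError(f"unknown position encoding {encoding!r}")


# ---------------------------------------------------------------------------
# bracket notation


def _tokenize(text: str) -> Iterator[tuple[str, int]]:
    """Yield (token, offset) where token is '(' , ')' or a symbol run."""
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in "()":
            yield ch, i
            i += 1
        else:
            start = i
            while i < n and not text[i].isspace() and text[i] not in "()":
                i += 1
            yield text[start:i], start


def parse_bracket(text: str) -> SyntaxTree:
    """Parse one bracket-notation tree from a string.

    The input may carry an explicit outer wrapper — ``(ROOT (S ...))``,
    ``(TOP ...)`` or an unlabeled outer pair ``((S ...))`` — which is
    absorbed: positions are always measured from a virtual super-root, so
    the sentence node sits at position ``(0,)`` either way.  Arbitrary
    whitespace (including newlines) is tolerated.
    """
    text = unicodedata.normalize("NFC", text)
    tokens = list(_tokenize(text))
    if not tokens:
        raise ParseError("empty input", 0)
    tree, pos = _parse_node(tokens, 0, text)
    if pos != len(tokens):
        raise ParseError("unexpected trailing material", tokens[pos][1])
    # absorb a single outer wrapper with exactly one child
    if (
        tree.label.upper() in ROOT_LABELS or tree.label == _UNLABELED
    ) and len(tree.children) == 1 and not tree.children[0].is_terminal:
        return tree.children[0]
    if tree.label == _UNLABELED:
        raise ParseError("unlabeled node with multiple children", tokens[0][1])
    return tree


_UNLABELED = "\x00"  # sentinel for an outer pair with no label


def _parse_node(tokens: list[tuple[str, int]], pos: int, text: str) -> tuple[SyntaxTree, int]:
    tok, off = tokens[pos]
    if tok != "(":
        raise ParseError(f"expected '(' but found {tok!r}", off)
    pos += 1
    if pos >= len(tokens):
        raise ParseError("unbalanced parentheses: unexpected end of input", len(text))
    tok, off = tokens[pos]
    if tok == ")":
        raise ParseError("empty node '()'", off)
    if tok == "(":
        label = _UNLABELED  # unlabeled outer pair, e.g. "((S ...))"
    else:
        label = tok
        pos += 1
    children: list[SyntaxTree] = []
    terminal: str | None = None
    while True:
        if pos >= len(tokens):
            raise ParseError("unbalanced parentheses: unexpected end of input", len(text))
        tok, off = tokens[pos]
        if tok == ")":
            pos += 1
            break
        if tok == "(":
            child, pos = _parse_node(tokens, pos, text)
            children.append(child)
        else:
            terminal = tok
            children.append(SyntaxTree(terminal))
            pos += 1
    if not children:
        raise ParseError(f"node {label!r} has no children", off)
    return SyntaxTree(label, tuple(children)), pos


def to_bracket(tree: SyntaxTree) -> str:
    """Canonical single-space bracket serialization (round-trip stable)."""
    if tree.is_terminal:
        return tree.label
    inner = " ".join(to_bracket(c) for c in tree.children)
    return f"({tree.label} {inner})"


def read_trees(path) -> list[SyntaxTree]:
    """Read a UTF-8 file of bracket trees, one per line or blank-separated.

    A tree may span several lines; records are cut at balanced
    parenthesis depth.
    """
    with open(path, encoding="utf-8") as fh:
        content = fh.read()
    trees: list[SyntaxTree] = []
    depth = 0
    buf: list[str] = []
    for ch in content:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        buf.append(ch)
        if depth == 0 and ch == ")":
            chunk = "".join(buf).strip()
            if chunk:
                trees.append(parse_bracket(chunk))
            buf = []
    rest = "".join(buf).strip()
    if rest:
        raise ParseError("unbalanced parentheses at end of file", len(content))
    return trees


# ---------------------------------------------------------------------------
# navigation


def node_at(tree: SyntaxTree, position: Sequence[int]) -> SyntaxTree:
    """Return the node addressed by ``position`` (virtual-root based).

    The first index steps from the virtual super-root onto the sentence
    node, so ``(0,)`` is the tree itself.
    """
    position = tuple(position)
    if not position:
        raise PositionError("empty position (the virtual root has no tag)")
    if position[0] != 0:
        raise PositionError(
            f"position {position} must start at 0 (single sentence under the virtual root)"
        )
    node = tree
    for depth, index in enumerate(position[1:], start=1):
        if index >= len(node.children):
            raise PositionError(
                f"index {index} at depth {depth} out of range for node "
                f"{node.label!r} with {len(node.children)} children"
            )
        node = node.children[index]
    return node


def leaf_positions(tree: SyntaxTree) -> list[TreePosition]:
    """Positions of all terminals, left to right (depth-first order)."""
    out: list[TreePosition] = []

    def walk(node: SyntaxTree, prefix: TreePosition) -> None:
        if node.is_terminal:
            out.append(prefix)
            return
        for i, child in enumerate(node.children):
            walk(child, prefix + (i,))

    walk(tree, (0,))
    return out


def prefix_paths(position: Sequence[int]) -> list[TreePosition]:
    """All non-empty prefixes of a position, shortest first.

    A word at position ``(0, 0, 1)`` is dominated by the nodes at ``(0,)``,
    ``(0, 0)`` and ``(0, 0, 1)``; slicing the position incrementally
    enumerates exactly that root path.
    """
    position = tuple(position)
    if not position:
        raise ValueError("empty position has no prefixes")
    return [position[: i + 1] for i in range(len(position))]


def node_tag(tree: SyntaxTree, position: Sequence[int], encoding: str = "concat") -> NodeTag:
    """Tag (label + unique position id) for the node at ``position``.

    For a terminal the "label" is the word token itself, so the deepest
    tag on a word's root path reads like ``product/0111110``.
    """
    node = node_at(tree, position)
    return NodeTag(node.label, tuple(position), encoding)
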