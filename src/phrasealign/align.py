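"""Word-to-structure alignment: the wide table of node tags per word.

This is the core of the pipeline.  Given a constituency tree and the word
timestamps, every timestamped word is tagged with the unique identifiers
of *all* the syntactic nodes that dominate it — one column per nesting
depth — so the hierarchical (bidimensional) structure is projected onto
the time axis without being flattened.  The result is a wide table: one
row per word with onset, offset, token, then the tags ``S/0``, ``NP/00``,
... down to the word's own ``token/position`` tag.

Tokenization mismatches are reconciled first: a parser may split a
contracted form into several leaves (``hadn't`` -> ``had`` + ``n't``)
while the annotation carries a single interval for the surface word.
Split leaves are merged back onto the one timestamped row, keeping the
first leaf's root path; the sub-lexical category of the later parts (the
negation's tag) is dropped, which is harmless above the preterminal level
because the single word interval already covers both parts' duration.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .timestamps import WordTier
from .tree import (
    NodeTag,
    SyntaxTree,
    TreePosition,
    decode_position,
    leaf_positions,
    node_tag,
    prefix_paths,
)

__all__ = [
    "TokenMap",
    "AlignmentTable",
    "AlignmentRow",
    "AlignmentError",
    "map_tokens",
    "align",
    "align_corpus",
    "normalize_token",
]

log = logging.getLogger(__name__)

#: Apostrophe look-alikes unified before comparing tokens.
_APOSTROPHES = str.maketrans({"’": "'", "ʼ": "'", "`": "'", "´": "'"})

_PUNCT_CATEGORIES = ("P", "S")  # unicode punctuation and symbols


class AlignmentError(ValueError):
    """Parser tokens and timestamped tokens cannot be reconciled."""


def normalize_token(token: str, lowercase: bool = False) -> str:
    """Normalization applied to both token streams before matching.

    Unicode NFC, apostrophe variants unified; case-sensitive unless
    ``lowercase`` is set.
    """
    token = unicodedata.normalize("NFC", token).translate(_APOSTROPHES)
    return token.lower() if lowercase else token


def _is_punctuation(token: str) -> bool:
    return all(unicodedata.category(ch)[0] in _PUNCT_CATEGORIES for ch in token)


@dataclass(frozen=True)
class TokenMap:
    """How timestamped words map onto parser leaves.

    ``pairs[k] = (tier_index, (leaf_index, ...))``: the k-th timestamped
    word covers those (consecutive) tree leaves.  ``dropped_leaves`` are
    leaves with no timestamped counterpart (punctuation, typically).
    """

    pairs: tuple[tuple[int, tuple[int, ...]], ...]
    dropped_leaves: tuple[int, ...] = ()

    @property
    def is_identity(self) -> bool:
        return not self.dropped_leaves and all(
            len(leaves) == 1 and leaves[0] == i for i, (_, leaves) in enumerate(self.pairs)
        )

    @property
    def n_merged(self) -> int:
        return sum(1 for _, leaves in self.pairs if len(leaves) > 1)


def map_tokens(
    tree_leaves: Sequence[str],
    tier: WordTier | Sequence[str],
    contractions: Mapping[str, Sequence[str]] | None = None,
    *,
    lowercase: bool = False,
    drop_punctuation: bool = True,
) -> TokenMap:
    """Greedy left-to-right reconciliation of the two token streams.

    Each timestamped token consumes the fewest leading parser leaves whose
    normalized concatenation equals it; an exact one-to-one match is the
    common fast path.  ``contractions`` maps a surface form to its split
    parts (``{"hadn't": ["had", "n't"]}``) and takes precedence over the
    concatenation rule.  Punctuation leaves with no timestamped
    counterpart are dropped with a warning.  Any residue raises
    :class:`AlignmentError` showing both windows, so the mismatch can be
    inspected by eye.
    """
    tier_tokens = tier.tokens if isinstance(tier, WordTier) else list(tier)
    if not tree_leaves or not tier_tokens:
        raise AlignmentError("cannot align empty token sequences")

    norm = lambda t: normalize_token(t, lowercase)
    lexicon = {norm(k): [norm(p) for p in v] for k, v in (contractions or {}).items()}

    pairs: list[tuple[int, tuple[int, ...]]] = []
    dropped: list[int] = []
    j = 0  # cursor into tree_leaves
    n_leaves = len(tree_leaves)
    for i, raw in enumerate(tier_tokens):
        target = norm(raw)
        # skip leading punctuation leaves that cannot begin this word
        while (
            drop_punctuation
            and j < n_leaves
            and _is_punctuation(norm(tree_leaves[j]))
            and not target.startswith(norm(tree_leaves[j]))
        ):
            log.warning("dropping punctuation leaf %r (no timestamp)", tree_leaves[j])
            dropped.append(j)
            j += 1
        if j >= n_leaves:
            raise AlignmentError(
                f"timestamped word {raw!r} (index {i}) has no parser leaves left"
            )
        parts = lexicon.get(target)
        if parts is not None:
            window = [norm(t) for t in tree_leaves[j : j + len(parts)]]
            if window != parts:
                raise AlignmentError(
                    f"contraction {raw!r} expects parts {parts} but parser "
                    f"leaves are {tree_leaves[j:j + len(parts)]} (leaf index {j})"
                )
            span = tuple(range(j, j + len(parts)))
            j += len(parts)
        else:
            span_list: list[int] = []
            concat = ""
            k = j
            while k < n_leaves and len(concat) < len(target):
                concat += norm(tree_leaves[k])
                span_list.append(k)
                k += 1
            if concat != target:
                raise AlignmentError(
                    f"token mismatch at timestamped word {raw!r} (index {i}): "
                    f"parser leaves {list(tree_leaves[j:k + 2])} do not "
                    f"concatenate to it (leaf index {j}); provide a "
                    "contraction lexicon entry or fix the inputs"
                )
            span = tuple(span_list)
            j = k
        pairs.append((i, span))
    while drop_punctuation and j < n_leaves and _is_punctuation(norm(tree_leaves[j])):
        log.warning("dropping trailing punctuation leaf %r", tree_leaves[j])
        dropped.append(j)
        j += 1
    if j != n_leaves:
        raise AlignmentError(
            f"{n_leaves - j} parser leaves left over after the last "
            f"timestamped word: {list(tree_leaves[j:])}"
        )
    return TokenMap(tuple(pairs), tuple(dropped))


@dataclass(frozen=True)
class AlignmentRow:
    """One word of the alignment table with its full root path of tags."""

    onset: float
    offset: float
    token: str
    tags: tuple[NodeTag, ...]  # depth 1 (sentence tag) .. the word's own tag

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def leaf_tag(self) -> NodeTag:
        return self.tags[-1]

    @property
    def preterminal_tag(self) -> NodeTag:
        return self.tags[-2]


@dataclass(frozen=True)
class AlignmentTable:
    """The wide word-by-depth table of node tags (the pipeline's output).

    Column ``d`` (zero-based) holds, for each word, the tag of the node at
    nesting depth ``d + 1`` on that word's root path — empty beyond the
    word's own depth.  Filled cells therefore form a contiguous prefix of
    each row, and the number of filled cells equals the length of the
    word's tree position.
    """

    rows: tuple[AlignmentRow, ...]
    encoding: str = field(default="concat", compare=False)
    sentence_index: tuple[int, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment table needs at least one row")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def depth(self) -> int:
        """Number of tag columns = deepest word's tree-position length."""
        return max(len(r.tags) for r in self.rows)

    def tags(self) -> list[NodeTag]:
        """Distinct tags in first-appearance (reading) order."""
        seen: dict[NodeTag, None] = {}
        for row in self.rows:
            for tag in row.tags:
                seen.setdefault(tag, None)
        return list(seen)

    def rows_for(self, tag: "NodeTag | str") -> list[int]:
        """Indices of the rows whose root path carries ``tag``."""
        wanted = tag.id if isinstance(tag, NodeTag) else str(tag)
        hits = [i for i, row in enumerate(self.rows) if any(t.id == wanted for t in row.tags)]
        if not hits:
            raise KeyError(f"tag {wanted!r} does not occur in the table")
        return hits

    def to_frame(self, precision: int | None = 3) -> pd.DataFrame:
        """Render as a DataFrame: onset, offset, words, 0..D-1."""
        depth = self.depth
        data: dict[str, list] = {
            "onset": [round(r.onset, precision) if precision else r.onset for r in self.rows],
            "offset": [round(r.offset, precision) if precision else r.offset for r in self.rows],
            "words": [r.token for r in self.rows],
        }
        if self.sentence_index:
            data["sentence"] = list(self.sentence_index)
        for d in range(depth):
            data[str(d)] = [r.tags[d].id if d < len(r.tags) else "" for r in self.rows]
        return pd.DataFrame(data)

    def write_csv(self, path, *, sep: str | None = None, precision: int = 3) -> None:
        path = Path(path)
        if sep is None:
            sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        self.to_frame(precision).to_csv(path, sep=sep, index=False, float_format=f"%.{precision}f")

    @classmethod
    def read_csv(cls, path, *, sep: str | None = None, encoding: str = "concat") -> "AlignmentTable":
        """Re-load a table written by :meth:`write_csv`."""
        path = Path(path)
        if sep is None:
            sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        return cls.from_frame(frame, encoding=encoding)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, *, encoding: str = "concat") -> "AlignmentTable":
        """Rebuild a table from its wide DataFrame form (string cells)."""
        depth_cols = [c for c in frame.columns if c.isdigit()]
        depth_cols.sort(key=int)
        rows = []
        sentences = []
        for _, rec in frame.iterrows():
            tags = []
            for col in depth_cols:
                cell = rec[col]
                if not cell:
                    break
                label, _, pos = cell.rpartition("/")
                tags.append(NodeTag(label, decode_position(pos, encoding), encoding))
            rows.append(
                AlignmentRow(float(rec["onset"]), float(rec["offset"]), rec["words"], tuple(tags))
            )
            if "sentence" in frame.columns:
                sentences.append(int(rec["sentence"]))
        return cls(tuple(rows), encoding=encoding, sentence_index=tuple(sentences))


def align(
    tree: SyntaxTree,
    tier: WordTier,
    token_map: TokenMap | None = None,
    *,
    contractions: Mapping[str, Sequence[str]] | None = None,
    encoding: str = "concat",
    lowercase: bool = False,
) -> AlignmentTable:
    """Align one sentence's tree with its word timestamps.

    For each timestamped word the root path of its first mapped leaf is
    sliced into incremental position prefixes, and each prefix's node tag
    fills one depth column.  Split-token leaves beyond the first generate
    no extra rows (the merge skips them), so the table has exactly one row
    per timestamped word.
    """
    leaves = tree.leaves()
    if token_map is None:
        token_map = map_tokens(leaves, tier, contractions, lowercase=lowercase)
    positions = leaf_positions(tree)
    if token_map.n_merged:
        log.info("merged %d split tokens back onto single rows", token_map.n_merged)
    rows = []
    for tier_idx, leaf_idxs in token_map.pairs:
        iv = tier[tier_idx]
        first_leaf = leaf_idxs[0]
        path = prefix_paths(positions[first_leaf])
        tags = tuple(node_tag(tree, p, encoding) for p in path)
        if len(leaf_idxs) > 1:
            # merged contraction: the row keeps the surface token from the
            # tier, whose interval spans all split parts
            log.debug("row %d merges leaves %s (%s)", tier_idx, leaf_idxs, iv.token)
        rows.append(AlignmentRow(iv.onset, iv.offset, iv.token, tags))
    return AlignmentTable(tuple(rows), encoding=encoding)


def align_corpus(
    trees: Iterable[SyntaxTree],
    tier: WordTier,
    *,
    contractions: Mapping[str, Sequence[str]] | None = None,
    encoding: str = "concat",
    lowercase: bool = False,
) -> list[AlignmentTable]:
    """Align a sequence of sentence trees against one continuous tier.

    The tier's words are consumed greedily, sentence by sentence; tags are
    unique within a sentence (the table index disambiguates across
    sentences).  Raises :class:`AlignmentError` with the sentence number
    when a sentence cannot consume a consistent prefix of the tier.
    """
    tables: list[AlignmentTable] = []
    cursor = 0
    for s, tree in enumerate(trees):
        leaves = tree.leaves()
        remaining = tier.slice(cursor, len(tier))
        if not len(remaining):
            raise AlignmentError(f"sentence {s}: no timestamped words left")
        # find how many tier words this sentence consumes: try prefixes
        last_error: AlignmentError | None = None
        token_map = None
        for n_words in range(1, len(remaining) + 1):
            window = remaining.slice(0, n_words)
            try:
                token_map = map_tokens(
                    leaves, window, contractions, lowercase=lowercase
                )
                break
            except AlignmentError as exc:
                last_error = exc
                if "left over" not in str(exc) and "no parser leaves left" not in str(exc):
                    break  # real mismatch, growing the window cannot fix it
                token_map = None
        if token_map is None:
            raise AlignmentError(f"sentence {s}: {last_error}") from last_error
        window = remaining.slice(0, len(token_map.pairs))
        tables.append(
            align(tree, window, token_map, encoding=encoding)
        )
        cursor += len(token_map.pairs)
    if cursor != len(tier):
        raise AlignmentError(
            f"{len(tier) - cursor} timestamped words left over after the last sentence"
        )
    return tables
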