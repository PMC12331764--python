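"""Synthetic sentences with consistent timestamps, plus the worked example.

Two kinds of fixtures make every stage of the pipeline testable without
any external corpus:

* the worked example — the sentence "The idea of one employee improved
  the quality of the product" with its constituency tree, eleven manually
  annotated word intervals, and the expected wide alignment table;
* seeded random material — a small recursive phrase-structure grammar
  (NP and PP recursion included, since deep nesting is precisely what the
  alignment must preserve) derives sentences, and word intervals are
  drawn from a log-normal duration model with optional inter-word pauses,
  a crude but positively skewed stand-in for natural speech timing.  No
  claim of corpus realism is made; the fixtures exist to exercise the
  invariants (sequential tiers, nested spans, depth law) at scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import AlignmentRow, AlignmentTable
from .timestamps import WordInterval, WordTier
from .tree import NodeTag, SyntaxTree, decode_position, parse_bracket

__all__ = [
    "FixtureGrammar",
    "TOY_GRAMMAR",
    "fixture_worked_example",
    "random_sentence",
    "random_timestamps",
    "random_fixture",
]


# ---------------------------------------------------------------------------
# the worked example

#: Bracket form of the worked-example sentence's constituency tree.
WORKED_EXAMPLE_BRACKET = (
    "(S (NP (NP (DT The) (NN idea)) (PP (IN of) (NP (CD one) (NN employee)))) "
    "(VP (VBD improved) (NP (NP (DT the) (NN quality)) "
    "(PP (IN of) (NP (DT the) (NN product))))))"
)

#: The printed wide table: onset, offset, word, then the tag id at each
#: nesting depth.  This is data, not computation: the aligner must
#: reproduce it from the bracket string and the intervals alone.
WORKED_EXAMPLE_ROWS: tuple[tuple, ...] = (
    (0.079, 0.223, "The", ("S/0", "NP/00", "NP/000", "DT/0000", "The/00000")),
    (0.223, 0.710, "idea", ("S/0", "NP/00", "NP/000", "NN/0001", "idea/00010")),
    (0.710, 0.936, "of", ("S/0", "NP/00", "PP/001", "IN/0010", "of/00100")),
    (0.936, 1.114, "one", ("S/0", "NP/00", "PP/001", "NP/0011", "CD/00110", "one/001100")),
    (1.114, 1.810, "employee", ("S/0", "NP/00", "PP/001", "NP/0011", "NN/00111", "employee/001110")),
    (1.810, 2.351, "improved", ("S/0", "VP/01", "VBD/010", "improved/0100")),
    (2.351, 2.472, "the", ("S/0", "VP/01", "NP/011", "NP/0110", "DT/01100", "the/011000")),
    (2.472, 3.046, "quality", ("S/0", "VP/01", "NP/011", "NP/0110", "NN/01101", "quality/011010")),
    (3.046, 3.198, "of", ("S/0", "VP/01", "NP/011", "PP/0111", "IN/01110", "of/011100")),
    (3.198, 3.272, "the", ("S/0", "VP/01", "NP/011", "PP/0111", "NP/01111", "DT/011110", "the/0111100")),
    (3.272, 3.977, "product", ("S/0", "VP/01", "NP/011", "PP/0111", "NP/01111", "NN/011111", "product/0111110")),
)


def _tag_from_id(tag_id: str) -> NodeTag:
    label, _, pos = tag_id.rpartition("/")
    return NodeTag(label, decode_position(pos, "concat"))


def fixture_worked_example() -> tuple[SyntaxTree, WordTier, AlignmentTable]:
    """The worked example: tree, eleven word intervals, expected table.

    The expected table is assembled from the printed cells themselves, so
    it is an independent reference for the aligner, not its output.
    """
    tree = parse_bracket(WORKED_EXAMPLE_BRACKET)
    tier = WordTier(
        tuple(WordInterval(w, on, off) for on, off, w, _ in WORKED_EXAMPLE_ROWS),
        source="worked-example",
    )
    rows = tuple(
        AlignmentRow(on, off, w, tuple(_tag_from_id(tid) for tid in tags))
        for on, off, w, tags in WORKED_EXAMPLE_ROWS
    )
    return tree, tier, AlignmentTable(rows)


# ---------------------------------------------------------------------------
# random sentences


@dataclass(frozen=True)
class FixtureGrammar:
    """A tiny context-free phrase-structure grammar with a PoS lexicon.

    ``rules`` maps a category to its alternative right-hand sides (each a
    sequence of categories); categories present in ``lexicon`` instead
    rewrite to a random word.  ``max_depth`` bounds recursion during
    derivation.
    """

    rules: dict = field(
        default_factory=lambda: {
            "S": [["NP", "VP"]],
            "NP": [["DT", "NN"], ["NP", "PP"], ["PRP"]],
            "VP": [["VBD", "NP"], ["VBD", "NP", "PP"], ["VBD"]],
            "PP": [["IN", "NP"]],
        }
    )
    lexicon: dict = field(
        default_factory=lambda: {
            "DT": ["the", "a", "one", "this"],
            "NN": ["idea", "employee", "quality", "product", "paper", "tree"],
            "PRP": ["I", "we", "they"],
            "VBD": ["improved", "liked", "wrote", "saw"],
            "IN": ["of", "in", "about", "with"],
        }
    )
    max_depth: int = 6

    def min_depth(self, category: str, _seen: frozenset = frozenset()) -> int:
        """Depth of the shallowest derivation of ``category``.

        Infinite (raises) when the category cannot derive a finite string
        — the productivity check.
        """
        if category in self.lexicon:
            return 1
        if category in _seen:
            return 10**9  # recursion with no terminal escape on this path
        if category not in self.rules:
            raise ValueError(f"category {category!r} has no rules and no lexicon entry")
        seen = _seen | {category}
        best = min(
            1 + max(self.min_depth(part, seen) for part in rhs) for rhs in self.rules[category]
        )
        if best >= 10**9:
            if _seen:
                return 10**9  # no terminal escape along this path; caller decides
            raise ValueError(f"category {category!r} is unproductive (derives no finite string)")
        return best


#: Default grammar used throughout the test fixtures.
TOY_GRAMMAR = FixtureGrammar()


def random_sentence(
    grammar: FixtureGrammar = TOY_GRAMMAR, seed: int = 0, start: str = "S"
) -> SyntaxTree:
    """Seeded random derivation; identical seeds give identical trees.

    Recursion is bounded by ``grammar.max_depth``: at each expansion only
    right-hand sides whose shallowest completion still fits the remaining
    budget are eligible, so the derivation always terminates.
    """
    rng = np.random.default_rng(seed)
    if grammar.min_depth(start) > grammar.max_depth:
        raise ValueError(
            f"start symbol {start!r} needs depth {grammar.min_depth(start)} "
            f"> max_depth {grammar.max_depth}"
        )

    def expand(category: str, budget: int) -> SyntaxTree:
        if category in grammar.lexicon:
            word = grammar.lexicon[category][rng.integers(len(grammar.lexicon[category]))]
            return SyntaxTree(category, (SyntaxTree(word),))
        options = [
            rhs
            for rhs in grammar.rules[category]
            if 1 + max(grammar.min_depth(p) for p in rhs) <= budget
        ]
        rhs = options[rng.integers(len(options))]
        return SyntaxTree(category, tuple(expand(p, budget - 1) for p in rhs))

    return expand(start, grammar.max_depth)


def random_timestamps(
    tree: SyntaxTree,
    word_rate: float = 3.0,
    pause_prob: float = 0.2,
    seed: int = 0,
    *,
    sigma: float = 0.4,
    mean_pause: float = 0.15,
    start_time: float = 0.0,
) -> WordTier:
    """Sequential word intervals for a tree's leaves, seeded.

    Word durations are log-normal with mean ``1/word_rate`` seconds
    (default rate 3 words/s, conversational range) and log-scale spread
    ``sigma``; with probability ``pause_prob`` a log-normal pause of mean
    ``mean_pause`` s separates consecutive words.  Intervals are strictly
    sequential by construction.
    """
    if word_rate <= 0:
        raise ValueError(f"word rate must be positive, got {word_rate}")
    leaves = tree.leaves()
    if not leaves:
        raise ValueError("tree has no leaves")
    rng = np.random.default_rng(seed)
    mu = np.log(1.0 / word_rate) - sigma**2 / 2.0  # E[lognormal] = 1/rate
    mu_pause = np.log(mean_pause) - sigma**2 / 2.0
    t = start_time
    intervals = []
    for i, word in enumerate(leaves):
        if i and rng.random() < pause_prob:
            t += float(rng.lognormal(mu_pause, sigma))
        duration = float(rng.lognormal(mu, sigma))
        intervals.append(WordInterval(word, t, t + duration))
        t += duration
    return WordTier(tuple(intervals), source=f"synthetic(seed={seed})")


def random_fixture(
    seed: int,
    grammar: FixtureGrammar = TOY_GRAMMAR,
    word_rate: float = 3.0,
    pause_prob: float = 0.2,
) -> tuple[SyntaxTree, WordTier]:
    """Convenience: a seeded (tree, matching tier) pair."""
    tree = random_sentence(grammar, seed)
    tier = random_timestamps(tree, word_rate, pause_prob, seed=seed + 1)
    return tree, tier
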