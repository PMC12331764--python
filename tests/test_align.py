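"""Token-map reconciliation and the wide alignment table."""

import pytest

from phrasealign import (
    AlignmentError,
    AlignmentTable,
    align,
    align_corpus,
    map_tokens,
    parse_bracket,
)
from phrasealign.align import normalize_token
from phrasealign.timestamps import tier_from_records
from phrasealign.tree import leaf_positions, node_at


def brute_force_row_span(tree, tier_tokens):
    """Oracle: each node's covered leaf-index interval, from the tree alone.

    Assumes the 1-1 token case (tier tokens == tree leaves).
    """
    spans = {}

    def walk(node, prefix, next_leaf):
        if node.is_terminal:
            spans[prefix] = (next_leaf, next_leaf)
            return next_leaf + 1
        start = next_leaf
        for i, child in enumerate(node.children):
            next_leaf = walk(child, prefix + (i,), next_leaf)
        spans[prefix] = (start, next_leaf - 1)
        return next_leaf

    walk(tree, (0,), 0)
    return spans


class TestMapTokens:
    def test_contraction_merging(self):
        m = map_tokens(
            ["had", "n't", "thought"],
            ["hadn't", "thought"],
            contractions={"hadn't": ["had", "n't"]},
        )
        assert m.pairs == ((0, (0, 1)), (1, (2,)))
        assert m.n_merged == 1

    def test_concatenation_fallback_without_lexicon(self):
        m = map_tokens(["had", "n't", "thought"], ["hadn't", "thought"])
        assert m.pairs == ((0, (0, 1)), (1, (2,)))

    def test_identity_fast_path(self):
        m = map_tokens(["a", "b", "c"], ["a", "b", "c"])
        assert m.is_identity

    def test_gross_mismatch_raises(self):
        with pytest.raises(AlignmentError, match="mismatch"):
            map_tokens(["a", "b"], ["c"])

    def test_leftover_leaves_raise(self):
        with pytest.raises(AlignmentError, match="left over"):
            map_tokens(["a", "b"], ["a"])

    def test_leftover_tier_words_raise(self):
        with pytest.raises(AlignmentError):
            map_tokens(["a"], ["a", "b"])

    def test_punctuation_leaves_dropped(self):
        m = map_tokens(["a", ",", "b", "."], ["a", "b"])
        assert m.pairs == ((0, (0,)), (1, (2,)))
        assert m.dropped_leaves == (1, 3)

    def test_apostrophe_variants_unified(self):
        assert normalize_token("hadn’t") == "hadn't"
        m = map_tokens(["had", "n’t"], ["hadn't"])
        assert m.pairs == ((0, (0, 1)),)

    def test_lowercase_option(self):
        with pytest.raises(AlignmentError):
            map_tokens(["The"], ["the"])
        assert map_tokens(["The"], ["the"], lowercase=True).pairs == ((0, (0,)),)


class TestAlign:
    def test_worked_example_reproduced_exactly(self, worked_example):
        tree, tier, expected = worked_example
        table = align(tree, tier)
        assert table == expected
        frame = table.to_frame()
        assert list(frame.columns) == ["onset", "offset", "words"] + [str(d) for d in range(7)]
        want = expected.to_frame()
        assert frame.equals(want)

    def test_minimal_tree_single_row(self):
        table = align(parse_bracket("(X w)"), tier_from_records([("w", 0.0, 1.0)]))
        assert len(table) == 1
        row = table.rows[0]
        assert (row.onset, row.offset, row.token) == (0.0, 1.0, "w")
        assert [t.id for t in row.tags] == ["X/0", "w/00"]

    def test_merged_contraction_keeps_first_leaf_path(self):
        tree = parse_bracket("(S (NP (PRP I)) (VP (VBD had) (RB n't) (VP (VBN thought))))")
        tier = tier_from_records([("I", 0.0, 0.2), ("hadn't", 0.2, 0.7), ("thought", 0.8, 1.3)])
        table = align(tree, tier)
        assert len(table) == 3  # one row per timestamped word, split line skipped
        had_row = table.rows[1]
        assert had_row.token == "hadn't"
        assert had_row.preterminal_tag.label == "VBD"  # first split leaf's PoS
        assert not any(t.label == "RB" for row in table.rows for t in row.tags)

    def test_column_depth_law(self, worked_table, worked_example):
        tree, _, _ = worked_example
        positions = leaf_positions(tree)
        for row, pos in zip(worked_table.rows, positions):
            assert len(row.tags) == len(pos)

    def test_sentence_tag_heads_every_row(self, worked_table):
        assert {row.tags[0].id for row in worked_table.rows} == {"S/0"}

    def test_identifier_uniqueness(self, worked_table):
        by_id = {}
        for row in worked_table.rows:
            for tag in row.tags:
                assert by_id.setdefault(tag.id, tag.position) == tag.position

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            AlignmentTable(())


class TestStructuralInvariants:
    """Row-set contiguity and nesting containment on seeded fixtures."""

    def test_tag_row_sets_contiguous(self, seeded_fixtures):
        for tree, tier in seeded_fixtures:
            table = align(tree, tier)
            for tag in table.tags():
                rows = table.rows_for(tag)
                assert rows == list(range(rows[0], rows[-1] + 1))

    def test_nesting_containment_matches_tree_oracle(self, seeded_fixtures):
        for tree, tier in seeded_fixtures:
            table = align(tree, tier)
            spans = brute_force_row_span(tree, tier.tokens)
            for tag in table.tags():
                rows = table.rows_for(tag)
                lo, hi = spans[tag.position]
                assert (rows[0], rows[-1]) == (lo, hi)
            # dominance: ancestor row-sets include descendant row-sets
            for pos, (lo, hi) in spans.items():
                for k in range(1, len(pos)):
                    plo, phi = spans[pos[:k]]
                    assert plo <= lo and hi <= phi

    def test_depth_law_on_fixtures(self, seeded_fixtures):
        for tree, tier in seeded_fixtures:
            table = align(tree, tier)
            for row, pos in zip(table.rows, leaf_positions(tree)):
                assert len(row.tags) == len(pos)


class TestCorpus:
    def test_two_sentences_consume_the_tier(self):
        trees = [parse_bracket("(S (NP (PRP I)) (VP (VBD ran)))"),
                 parse_bracket("(S (NP (PRP we)) (VP (VBD slept)))")]
        tier = tier_from_records(
            [("I", 0, 0.2), ("ran", 0.2, 0.6), ("we", 1.0, 1.2), ("slept", 1.2, 1.8)]
        )
        tables = align_corpus(trees, tier)
        assert [len(t) for t in tables] == [2, 2]
        assert tables[1].rows[0].token == "we"
        assert tables[1].rows[0].tags[0].id == "S/0"  # ids restart per sentence

    def test_leftover_words_raise(self):
        trees = [parse_bracket("(S (NP (PRP I)) (VP (VBD ran)))")]
        tier = tier_from_records([("I", 0, 0.2), ("ran", 0.2, 0.6), ("extra", 1, 2)])
        with pytest.raises(AlignmentError, match="left over"):
            align_corpus(trees, tier)

    def test_sentence_coordinate_in_error(self):
        trees = [parse_bracket("(S (NP (PRP I)) (VP (VBD ran)))"),
                 parse_bracket("(S (NP (PRP we)) (VP (VBD slept)))")]
        tier = tier_from_records([("I", 0, 0.2), ("ran", 0.2, 0.6), ("they", 1, 1.2), ("slept", 1.2, 1.8)])
        with pytest.raises(AlignmentError, match="sentence 1"):
            align_corpus(trees, tier)


class TestTableIO:
    def test_csv_round_trip(self, tmp_path, worked_table):
        path = tmp_path / "table.csv"
        worked_table.write_csv(path)
        back = AlignmentTable.read_csv(path)
        assert back == worked_table

    def test_tsv_round_trip(self, tmp_path, worked_table):
        path = tmp_path / "table.tsv"
        worked_table.write_csv(path)
        assert AlignmentTable.read_csv(path) == worked_table
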