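"""Reconcile split contractions and read timestamps from a Praat TextGrid.

Parsers tokenize "hadn't" as two leaves (had + n't) while a Praat word
tier usually carries one interval for the surface word.  The aligner
merges the split leaves back onto the single timestamped row: the first
leaf's root path is kept, the extra row is skipped, and only the
sub-lexical category of the clitic is lost.
"""

import tempfile
from pathlib import Path

from phrasealign import align, map_tokens, parse_bracket, read_textgrid, write_textgrid
from phrasealign.timestamps import tier_from_records

tree = parse_bracket(
    "(S (NP (PRP I)) (VP (VBD had) (RB n't) (VP (VBN thought) "
    "(PP (IN about) (NP (DT the) (NN tree))))))"
)
print("parser leaves:", tree.leaves())

# one interval per *surface* word, annotated e.g. in Praat
tier = tier_from_records(
    [
        ("I", 0.10, 0.22),
        ("hadn't", 0.22, 0.61),
        ("thought", 0.61, 1.02),
        ("about", 1.10, 1.33),
        ("the", 1.33, 1.41),
        ("tree", 1.41, 1.80),
    ]
)
print("timestamped words:", tier.tokens)

# round-trip through an actual TextGrid file, as Praat would exchange it
with tempfile.TemporaryDirectory() as tmp:
    grid = Path(tmp) / "words.TextGrid"
    write_textgrid(tier, grid, tier_name="words")
    tier = read_textgrid(grid, "words")

token_map = map_tokens(tree.leaves(), tier, contractions={"hadn't": ["had", "n't"]})
print("token map (tier index -> leaf indices):", token_map.pairs)
print("merged rows:", token_map.n_merged)

table = align(tree, tier, token_map)
print("\nAligned table — note the single row for \"hadn't\":\n")
print(table.to_frame().to_string(index=False))
print(
    "\nThe row keeps the finite verb's path (VBD); the clitic's RB tag is dropped,"
    "\nwhich does not disturb any node above the preterminal level."
)
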