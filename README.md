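# phrasealign

Project hierarchical syntactic structure onto the time axis of speech.

Speech units — phonemes, syllables, words — follow one another on the time
axis and never nest, so their onsets and offsets are easy to mark.
Syntactic phrases do nest: in *"The idea of one employee improved the
quality of the product"*, the noun phrase *the idea* sits inside the larger
noun phrase *the idea of one employee*, which sits inside the sentence.
Studies of neural tracking of language need the temporal references of
those covert phrasal units, yet flattening phrases onto a sequence discards
exactly the hierarchy that makes them interesting.

`phrasealign` aligns a constituency parse with word-level timestamps
*without* flattening. Every word is tagged with the labels of **all** the
nodes dominating it, each label made unique by its tree position — the
sequence of child indices addressing the node from the root, so the
sentence node is `S/0`, its first child `NP/00`, and so on. The result is a
wide table (one row per word, one column per nesting depth) from which every
phrase's onset, offset and duration follow directly, and durations convert
to frequency bands via F = 1/T for narrow-band filtering of speech or M/EEG
signals.

The library is parser-agnostic: trees enter as Penn-Treebank-style bracket
strings from any parser or manual annotation, timestamps as Praat TextGrid
interval tiers or CSV/TSV tables from any forced aligner or manual marking.

## Core definitions

For a node with tag *L/p* dominating words *w₁ … w_k*:

- **span duration** (pauses retained):
  `maxOffset(wᵢ) − minOnset(wᵢ)`; the (minOnset, maxOffset) pair is the
  phrase's own timestamp.
- **sum duration** (pauses filtered):
  `Σᵢ duration(wᵢ)` over the words carrying the tag.
- **frequency twin**: `F = 1/T` maps a duration distribution to the band
  `[1/T_max, 1/T_min]` Hz.

A word at tree position `[0,0,1]` is dominated by exactly the nodes at the
position prefixes `[0]`, `[0,0]`, `[0,0,1]` — slicing positions
incrementally enumerates the root path, which is how the table's columns
are filled.

Tokenization mismatches (a parser splits *hadn't* into *had* + *n't* while
the annotation has a single interval) are reconciled first: split leaves
merge back onto the one timestamped row, keeping the first leaf's path.

The validation toolkit compares two phrase-duration distributions (e.g.
manual vs automatic annotation): seeded random dropping to match counts,
paired quantiles, ECDFs, and an equivalence Bayesian independent-samples
*t* test — the Bayes factor for the standardized mean difference δ lying
inside a small equivalence region versus outside, under a Cauchy(0, 0.707)
prior.

## Worked example

```python
from phrasealign import align, fixture_worked_example, phrase_span, phrase_duration_sum

tree, tier, _ = fixture_worked_example()   # the 11-word example sentence
table = align(tree, tier)
print(table.to_frame().head(3).to_string(index=False))
```

```
 onset  offset words   0     1      2       3          4
 0.079   0.223   The S/0 NP/00 NP/000 DT/0000  The/00000
 0.223   0.710  idea S/0 NP/00 NP/000 NN/0001 idea/00010
 0.710   0.936    of S/0 NP/00 PP/001 IN/0010   of/00100
```

Each row is one word; column *d* holds the unique tag at nesting depth
*d + 1* on that word's root path. The subject noun phrase `NP/00` covers
the first five words, so

```python
phrase_span(table, "NP/00")          # (0.079, 1.810, 1.731)
phrase_duration_sum(table, "NP/00")  # 1.7310000000000003
```

its onset is the onset of *The* (0.079 s), its offset the offset of
*employee* (1.810 s), and with no internal pauses both duration
definitions give 1.731 s. `all_phrases(table)` returns all 10 phrasal
nodes with their temporal profiles; see `examples/01_worked_example.py`
for the full printout, `examples/02_contractions_and_textgrid.py` for
contraction merging and TextGrid I/O, and
`examples/03_validate_distributions.py` for the equivalence test
(on two same-distribution synthetic samples of ~950 phrases it prints a
Bayes factor far above 1 — decisive evidence of equivalence — and a 95%
credible interval for δ straddling 0).

## Command line

The same pipeline as a tool:

```bash
phrasealign align --trees trees.txt --textgrid rec.TextGrid --tier words --out table.csv
phrasealign phrases --table table.csv --out phrases.csv --bands bands.json
phrasealign validate manual.csv automatic.csv --seed 1 --out report.json
phrasealign simulate --seed 7 --n-sentences 20 --out-trees t.txt --out-csv w.csv
```

`align` writes the wide table (multi-sentence corpora get a `sentence`
column; tags are unique within a sentence), `phrases` extracts per-phrase
records plus an optional frequency-band spec, `validate` compares two
duration files and reports the Bayes factor with all its settings, and
`simulate` writes a seeded synthetic corpus.

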