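# Methods

## The alignment model

A constituency tree is an ordered, labeled tree whose terminals are the
words of one sentence. The package addresses every node by its *tree
position*: the sequence of child indices from a virtual super-root, so the
sentence node is `(0,)`, its first child `(0, 0)`, and a terminal's
position length equals its depth. Positions do double duty: they navigate
the tree, and their string encoding appended to the node's label
(`NP/00`) is an identifier that is unique within the sentence even when
the bare label repeats — which it always does in natural parses.

Alignment is the composition of three total functions:

1. **leaf coordinates** — a depth-first enumeration returns every
   terminal's position, in token order;
2. **path slicing** — the non-empty prefixes of a terminal's position
   enumerate exactly the nodes dominating it, shortest (the sentence
   node) first;
3. **tag filling** — each prefix resolves to its node's label-plus-position
   tag, and the tags fill the word's row of the wide table, one column per
   nesting depth.

Because every row is a root path, three structural facts hold by
construction and are enforced as tested invariants: filled cells form a
contiguous prefix of each row; the set of rows carrying any tag is a
contiguous block (constituents cover contiguous word spans); and ancestor
row-sets contain descendant row-sets. The number of filled cells in a row
equals the length of the word's position (the depth law).

### Assumptions

- One tree per sentence; words within a sentence are strictly sequential
  in time (overlap beyond a small tolerance is an error in strict mode).
  Inter-word pauses are allowed and carry no annotation.
- The parse is taken as given. The pipeline is parser-agnostic — any
  bracket-notation string from any parser or manual annotation — and no
  tagset normalization is applied: labels pass through verbatim.
- Timestamps are in seconds throughout; no unit inference.

## Tokenization reconciliation

Timestamped words and parser leaves are matched greedily left to right:
each timestamped token consumes the fewest leading leaves whose
normalized concatenation equals it (Unicode NFC, apostrophe variants
unified; case-sensitive by default). An explicit contraction lexicon
(surface form → split parts) takes precedence where supplied. When a
timestamped word maps to several leaves, the merged row keeps the *first*
leaf's root path; the later leaves contribute no rows, so their
sub-lexical categories (e.g. the clitic negation's tag) are dropped. The
choice of the first leaf is a design decision: the alternatives differ
only at the preterminal level, which the merged surface word's interval
already spans, and keeping the first part (the host, usually the finite
verb) retains the category most analyses condition on. Punctuation leaves
with no timestamped counterpart are dropped with a warning. Any residual
mismatch is a hard error that prints both token windows and the position —
gross transcript/parse divergence should be inspected, not silently
repaired.

## Position encoding

Concatenated digits (`0110`) match the conventional tabular layout but
are ambiguous once a node has ten or more children, so the encoder
refuses indices above 9 in that mode; a dot-separated mode (`0.1.1.0`)
is selectable wherever tags are produced or parsed. A literal `ROOT`/`TOP`
wrapper (or an unlabeled outer pair) with a single child is absorbed into
the virtual root rather than consuming a depth level, so the sentence
node always sits at position `0`; a wrapper with several children is kept
as the sentence node itself.

## Phrase metrics

Both duration definitions are first-class: the pause-retaining span
(`maxOffset − minOnset` over the tag's words, whose endpoints are also
the phrase's timestamps) and the pause-filtering sum of word durations.
Distributions default to the span definition, the one appropriate for
deriving filter bands from continuous speech; a flag flips to sum.
Phrase enumeration excludes preterminals (the deepest-but-one cell of
each row) and word rows by default, with flags to include both; a depth-1
sentence tag always counts as phrasal, covering single-word sentences
where the sentence node directly dominates the word. Frequencies (F = 1/T)
are computed from unrounded durations and rounded only for display, at
three decimals for both seconds and Hz.

## Validation statistics

Two phrase-duration samples are compared the way an automatic annotation
route is validated against a manual gold standard:

- **count matching** by uniform random subsampling of the larger sample
  (without replacement, order-preserving, mandatory seed recorded in the
  output);
- **Q-Q pairs** at the shared grid p = k/(n+1); for equal sizes these are
  exactly the order statistics;
- **ECDF**, right-continuous, F(t) = #{x ≤ t}/n;
- **equivalence Bayes factor**: BF = p(data | δ ∈ (l, u)) / p(data | δ
  outside), with each marginal computed under a Cauchy(0, scale) prior
  truncated to its region and the two-sample t statistic's noncentral-t
  likelihood (ncp = δ·√(n₁n₂/(n₁+n₂))), integrated numerically. The
  default scale is 0.707; the equivalence region defaults to δ ∈ (−0.5,
  0.5) and is echoed in every result because it is a consequential,
  analysis-specific choice with no canonical value. A 95% central
  credible interval for δ under the unrestricted posterior is reported
  alongside. The BF is symmetric in the samples for symmetric regions and
  invariant to common rescaling (the effect size is standardized), both
  property-tested.

### Numerical notes

scipy's noncentral-t density overflows its gamma functions for df in the
thousands, so above df = 200 the log-density is computed from the
representation T = (Z + ncp)/U, U = √(χ²_df/df): a 128-node Gauss–Legendre
quadrature over U (concentrated at 1 with spread 1/√(2df)), assembled in
log space. It matches scipy to ~1e-14 where both work and integrates to 1
at df = 5000. Region marginals clip infinite integration bounds to a
window provably containing all non-negligible likelihood (|δ̂| + 30/√n_eff
+ 1) and anchor the quadrature on the likelihood peak. With enormous
evidence the outside-region marginal can underflow to zero; the BF is then
reported as infinity rather than a spurious finite number.

## Synthetic fixtures

The worked example (tree, eleven word intervals, expected table) is
packaged as literal data assembled from the printed cells, so it is an
independent reference for the aligner rather than a regurgitation of its
output.

Random material comes from a small context-free grammar with recursive
NP → NP PP and PP → IN NP rules, because deep nesting is the regime the
alignment must preserve; derivations are seeded and bounded by a maximum
depth (at each expansion only right-hand sides whose shallowest
completion fits the remaining budget are eligible, so generation always
terminates, and an unproductive grammar is rejected up front). Word
durations are log-normal with mean 1/rate at a default 3 words/s and
log-scale spread 0.4 — positive and right-skewed like natural speech
timing — with optional inter-word pauses (probability 0.2, mean 0.15 s).
These defaults are one fixed, field-plausible operating point for
conversational speech; the generator makes no claim of matching any
corpus, and passing property suites on it demonstrates structural
correctness of the pipeline (containment, contiguity, depth law,
sequentiality), not linguistic realism. Real data differ in ways the
generator does not emulate: parse errors, disfluencies, punctuation-only
leaves, annotation slop at word boundaries, and cross-sentence prosody.

## Problem sizes

The packaged property suites and the acceptance script use 100 seeded
sentences for the structural invariants and samples of 3093 vs 3046
durations (the sizes of the two annotation routes in the motivating
validation study) for the count-matching and equivalence statistics; the
Monte-Carlo cross-check of the Bayes factor uses 10⁶ prior draws at
moderate sample size (n = 60 per group), where the estimator's variance
makes a 2% agreement check meaningful — at corpus sizes with no true
effect the BF is astronomically large and only its order of magnitude is
informative, so the acceptance script reports log₁₀ BF there.

## Known limitations

- Concatenated position encoding is refused (not silently corrupted) at
  arity ≥ 10; switch to dotted encoding for such trees.
- The greedy token matcher cannot recover from gross transcript/parse
  divergence and is not meant to: it fails loudly with both windows.
- Multi-sentence corpora re-use tag identifiers across sentences (they
  are unique only within one tree); the table's sentence column carries
  the disambiguation.
- The equivalence BF depends on the chosen equivalence region; results
  are only comparable across analyses that state the same region, which
  is why it is embedded in every report.
- TextGrid support covers the long and short text dialects (UTF-8/UTF-16)
  with interval tiers; binary TextGrids are not read.
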