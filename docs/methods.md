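# Methods

## Perturbation model

A perturbation run is governed by a `PerturbationSpec`: a type
(`typographical`, `homophone`, `redaction`), a level `ℓ ∈ (0, 1]`, a seed,
a per-word typo intensity range, and the set of POS categories eligible for
perturbation (default: adjective, adverb, verb, noun).

**Word budget.** All three perturbation types are budgeted as a fraction of
the *total* word count, `t = max(1, round_half_up(ℓ·N))`, but may touch only
valid words. This is the operational rule the calibrated levels are defined
against: in a 10-word sentence with 5 valid words, the 10% level perturbs
exactly one word (20% of the valid words). Character-based budgeting for
typos is a plausible alternative reading of "level"; we use the word-based
rule uniformly because it makes the three perturbation types directly
comparable at a given level and matches the worked example above. Rounding
is half-up with a floor of one word: a positive level never produces an
unperturbed "perturbed" variant. When `t` exceeds the valid-word supply the
engine raises `BudgetInfeasibleError` rather than silently under-perturbing;
the corpus layer's retention rule consumes that signal and drops the record
(with the failing condition logged) unless **all nine** grid conditions are
feasible.

**Grids.** Typos and redactions run at 10/30/50% of words, homophones at
10/20/30% — lower because only a minority of words have homophones at all,
which makes higher homophone rates unrealistic and usually infeasible.

**Tokenization and tagging.** Tokens are whitespace chunks with leading and
trailing punctuation peeled off; internal apostrophes/hyphens stay inside
the word. Spans are 0-based half-open into the source string, which lets
recorded edits be replayed byte-exactly. POS categories come from an
injected `token -> category` callable; the bundled default is a
deterministic rule tagger (≈330-word function/content lexicon, then suffix
heuristics, then a default of noun — the safe default for out-of-vocabulary
clinical vocabulary). Determinism was preferred over a statistical tagger so
that corpora, tests and dropped-record sets are bit-reproducible with no
model download; any spaCy/NLTK tagger can be injected where higher tagging
accuracy matters more than reproducibility.

**Typo operator.** One operator per word, drawn uniformly from insert /
delete / substitute / adjacent-transpose, applied at `k = max(1,
round_half_up(u·len))` letter positions with `u ~ U(0.20, 0.50)`. Deletions
are capped at `len−1` so a word never vanishes into a typo; single-letter
words draw from insert/substitute only. Substitution letters are uniform
over lowercase a–z excluding the original letter (keyboard-adjacency is a
possible refinement, deliberately not the default to keep the channel
unbiased). If the sampled edits happen to reproduce the input (e.g.
transposing equal letters) one forced substitution guarantees the output
differs. Untouched letters keep their case.

**Homophones.** A provider answers ordered sounds-like candidates; the
first candidate that differs in spelling replaces the word, case-adapted.
Two providers share the contract: a bundled versioned two-column TSV
dictionary (~120 entries, offline, what all tests use) and a Datamuse-style
HTTP client whose failures raise, never silently skip. If a selected word
has no homophone the engine reselects another unused valid word; only when
the budget still cannot be met is the example infeasible.

**Redaction** deletes the selected token spans, collapses whitespace runs,
and re-attaches orphaned punctuation, so "scleral icterus and" redacts to
"scleral and" and trailing question marks survive.

**Reproducibility.** Each example's generator is seeded by
`crc32(f"{seed}:{example_id}")`, so corpus-level runs are order-independent
and a (text, spec, provider version) triple fully determines the output.
Every recorded edit carries (token index, operator, before, after,
medical flag), and `apply_edits` replays them to reproduce the perturbed
text exactly — the invariant the retention and audit tests check.

## Corpus, splits, prompts

Records are CSV (`id,text,label`) or JSONL; QA records carry
(note_id, note, question, answer) and are reduced to one question per note
(lowest record id — the deterministic stand-in for an unspecified choice).
Splits carve 20% for prompt tuning, then a seeded 1,000-record test set
from the remainder, rest validation; QA splits operate on unique notes so
no note straddles splits. Prompts are 5-shot: role statement, five worked
examples (label-balanced for classification, e.g. 3–2 on a binary task),
task instructions, the input, an isolation instruction (each item is its
own session; the instruction guards hosted models against answering from
neighbouring cases), and a request for a short justification. QA prompts
additionally instruct answering only from the note.

## Adapters and scoring

The adapter contract is one stateless call per item. Real endpoints see
only the prompt (generic OpenAI-shaped HTTP client; key via environment
variable). The bundled mocks additionally receive the item and the active
(ptype, level) out of band — parsing gold labels back out of a prompt
string would be fragile, and nothing persists between calls, so session
isolation is preserved. Mocks: oracle (always gold), adversarial (never
gold), keyword classifier and extractive answerer (driven by the planted
fixture signal), and a **noisy channel** with per-condition target
accuracies `a = clip(base·(1+δ))`. The channel is quota-scheduled: the i-th
item of a condition is answered correctly iff fewer than
`round_half_up(a·i)` correct answers have been issued, so a slice of n
items realises exactly `round(a·n)` correct — the programmed relative shift
is reproduced up to rounding instead of fluctuating binomially, and bin
recovery sharpens to certainty as n grows.

Classification responses are parsed by first word-boundary label match
(case-insensitive); unparseable responses are flagged and scored wrong.
Metrics: accuracy plus macro-averaged precision/recall/F1 (macro treats the
2- and 3-class tasks symmetrically; per-class F1 is also emitted); ROUGE-L
F-measure over lowercased word tokens (the QA analysis metric) and sentence
BLEU with add-one smoothing on 2–4-gram precisions (short clinical answers
otherwise hit the zero floor). A semantic-similarity scorer (e.g. an
embedding model) is injectable into `score_qa`; the core deliberately has
no neural dependency.

## Robustness bins and statistics

`Δ = (perturbed − original)/original`; bins: increase (Δ>0), stable
(−0.05 ≤ Δ ≤ 0), decrease (−0.50 ≤ Δ < −0.05), catastrophic (Δ < −0.50).
The boundary inclusivities make the four bins a partition; "catastrophic"
means the perturbed value fell below half the original. A small epsilon
(1e−12) keeps exact −5%/−50% drops on their stated side under floating
point. Zero baselines are an error (undefined relative change).

Chi-squared is Pearson's, no continuity correction, zero-margin rows and
columns dropped with a warning. Friedman uses within-block mid-ranks with
the standard tie correction (verified against `scipy.stats
.friedmanchisquare` and an exhaustive rank oracle); all-constant blocks
give statistic 0. Conover post hoc uses the squared-rank form
`t = |R_i−R_j| / sqrt(2n(A−B)/((n−1)(k−1)))` with `A = ΣΣr²`,
`B = ΣR²/n`, df `(n−1)(k−1)`, Bonferroni multiply-and-cap; the effect size
is the r-from-t convention `r = |t|/sqrt(t²+df)` (other conventions exist;
this one is reported and named in the output). RM-ANOVA is the one-way
within-subjects sums-of-squares partition (treatment/subject/error),
missing cells are an error, and the 2-treatment case equals the squared
paired t (checked against `pingouin` in development). Dimension analyses
(`condition_matrix`) build blocks × treatments matrices from the
analysis-metric values — accuracy for classification, ROUGE-L for QA —
with incomplete blocks dropped (a model never run on a task). The level
dimension uses ordinal level names (original/low/medium/high) since the
numeric grids differ across perturbation types.

The medical-term profile computes, per example, the fraction of perturbed
words flagged medical (bundled ~90-term lowercase lexicon; injectable),
buckets examples into equal-width ratio bins (deciles by default) and
reports the median score per bucket and level.

## Synthetic fixtures: what they emulate, and what they don't

Fixture sentences are assembled from word banks whose POS tags and
homophone availability are known to the bundled tagger/dictionary: a
10-word classification frame with 7 valid words, 4 homophone-bearing, and a
15-word QA note frame with 11 valid words, 5 homophone-bearing — enough for
every grid condition, so fixture corpora pass the retention rule with zero
drops by construction. Label signal lives in designated keyword tokens
(sentiment adjectives; condition nouns), so the keyword mock classifier is
perfect on clean text and collapses to its fallback rate when the keyword
is perturbed; QA notes end in "Examination showed <answer>." so the
extractive mock recovers the reference exactly on clean notes. Defaults:
100 records, medical-noun fraction 0.4, signal strength 1.0.

The fixtures are *structural* stand-ins: they exercise budgets, feasibility,
parsing and the statistics chain end-to-end, but they have none of real
clinical text's length variation, ambiguity, OOV vocabulary or label noise.
Passing fixture tests therefore demonstrates the machinery is correct, not
that any particular model is robust on real clinical corpora.

`generate_result_table` fabricates the full 270-cell per-condition grid
(two classification tasks × 3 models × 4 metrics + QA × 2 models × 3
metrics, × 9 conditions, plus 30 original baselines): cell value = a
per-(task, model, metric) base drawn U(0.55, 0.90), times programmed
relative per-dimension effects, plus N(0, 0.03) noise, clipped to
(0.01, 0.99). With zero effects this is a null table. Null calibration is
run on the perturbation-type dimension (24 blocks × 3 treatments): there the
base cancels within blocks and blocks are independent, so the nominal
Friedman level applies; the model/task dimensions compare different base
draws that are shared across blocks, which violates block independence by
construction of the generator (not of the test) and would inflate any
rejection-rate estimate.

## Problem sizes and numerical choices

Default study sizes used by the test suite and the reproduction script:
1,000 fixture sentences × 9 conditions for the budget property; 100 runs ×
500 items for bin recovery; 1,000 simulated grids for null calibration
(observed rejection ≈ 4–6% at α = 0.05). Percentages are formatted half-up
at the printed precision of the table they feed (2 decimals for the
task/model summary, 1 for the perturbation-type summary). All seeds are
explicit; derived seeds stay below 2³¹.

## Known limitations

- The rule tagger is deterministic but coarse; genuinely ambiguous tokens
  (e.g. "patient's", auxiliaries used as main verbs) follow fixed lexicon
  choices.
- The bundled homophone dictionary is small and English-only; the remote
  provider broadens coverage at the cost of reproducibility (its results
  are version-stamped into the manifest for audit).
- No grammar-aware or keyboard-layout error models, abbreviation expansion,
  or syntactic reordering; no multilingual support.
- BERTScore-style semantic scoring is interface-only; the package ships no
  embedding model.
- RM-ANOVA is one-way per dimension; a factorial within-subjects model is
  out of scope.
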