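# Methods

`crossmine` re-implements, as an offline and fully testable pipeline, a
literature-mining workflow for comparative oncology: select human–dog
candidate cancer genes, retrieve and classify abstracts about their
therapies, recognize drug/therapy names, and extract probable drug
combinations. This note records the models, the parameters that matter,
and the design choices made where the design was genuinely open.

## Candidate genes and query construction

Candidate genes are the intersection of (a) human–dog 1-1 ortholog pairs
with percent sequence similarity ≥ a threshold (default **75**,
inclusive; similarity is consumed as a precomputed 0–100 percentage,
never recomputed) and (b) a somatic-mutation gene catalog keyed by
Entrez GeneID, bridged to Ensembl human gene ids by a supplied mapping
table. Catalog entries without a mapping are counted and excluded, never
guessed. When several ortholog rows share a human gene (paralog noise),
the highest-similarity row is kept, ties broken by lexicographic dog
gene id — consistent with a 1-1 ortholog model.

PubMed queries are left-nested boolean ORs over the per-gene term list:
synonyms in `gene_info` source order (the `-` placeholder dropped,
case-insensitive duplicates removed keeping the first), then
`HGNC: <id>`, `MIM:<id>`, `Ensembl: <human>`, `Ensembl:<dog>`. The
emitted string is `"(" * (n-1)` followed by `"t1) OR t2) … OR tn)"`
(one term yields `"(t1)"`). Note that for n ≥ 2 the closing parentheses
outnumber the opening ones by one; this matches the query format the
pipeline submits verbatim, and PubMed's parser accepts it. The identifier
spacing quirks (space after `HGNC:` and after the human `Ensembl:`, none
elsewhere) are preserved deliberately.

## Text preprocessing

Two tokenization profiles share one regex tokenizer with character
offsets:

* **entity mode** keeps punctuation tokens, keeps internal hyphens
  (`ABT-737` is one token) and treats letter-initial comparison
  expressions (`P≤0.001`, `IC50=20`) as single tokens;
* **classification mode** drops punctuation and pipes word tokens
  through lowercase → character normalization → stopword removal →
  Porter stemming.

"Spelling normalization" is implemented as deterministic character-level
normalization — Unicode NFKC, Greek letters spelled out (α→alpha),
hyphen variants unified — not edit-distance correction; this keeps the
pipeline reproducible and is a documented stand-in for an otherwise
under-specified step. The Porter stemmer is the classic 1980 algorithm
implemented in-package and checked against the algorithm's published
example stems. The stopword list is a packaged 318-word English list
(one token per line, user-replaceable).

Sentence segmentation splits after sentence-final punctuation followed
by whitespace and an upper-case/digit/quote opener, with guards for
common abbreviations and single-capital initials; decimal points never
split because no whitespace follows them.

Classifier features are raw counts of word **trigrams** (first-occurrence
vocabulary order, scipy sparse matrix); a config switch allows 1–3-grams
but is off by default.

## Outcome classification

A random forest (default **300 trees**, fixed seed, single thread) over
trigram counts of `title + " " + abstract` classifies articles as
treatment success (1) or failure (0). Evaluation is stratified k-fold
cross-validation (default **k = 10**) with all out-of-fold predictions
pooled into one confusion table; precision/recall/F are reported for the
positive (success) class, macro averages are logged additionally.
Pooled positive-class scoring was chosen because it stays well defined
under the ~17%/83% class imbalance the generator emulates. Class
weighting exists as an option and is off by default. Degenerate inputs:
a single-class corpus or a minority class smaller than k raise errors; a
document sharing no trigram with the training vocabulary is still
classified, with a logged warning.

## Drug/therapy NER

The trainable tagger is a per-token logistic-regression classifier (the
maximum-entropy/log-linear family) over: token identity, lowercase form,
2–4-character prefixes and suffixes, word shape (case/digit/hyphen
pattern, plus a run-collapsed variant), and the lowercase neighbors
within distance 2 (padded at edges). Maximal runs of positive tokens
become mentions with character offsets. Training is deterministic given
the seed (lbfgs, C=10, 500 iterations).

A second recognizer does longest-match, case-insensitive,
token-boundary-anchored lexicon lookup (no substring hits:
`carboplatin` does not match inside `carboplatinum`). Model and lexicon
mentions are unioned and deduplicated by span, model-sourced mentions
preferred on exact ties.

**False-positive filter.** A mention is dropped iff some rule's pattern
matches its *full* surface. The shipped set has 27 rules: the
comparison-expression rule — a letter-initial token containing one of
`< > = ≤ ≥ <= >=` followed by a numeric tail (this is the prose
semantics; the one-character ≤/≥ forms are required for the canonical
example `P≤0.001`) — plus percentages, p-values, dose expressions, and
generic pharmacology words (`inhibitor`, `receptor`, …). Filtering is
order-preserving and idempotent; it can only raise precision, never
recall on true drugs, provided the rules target non-drug shapes.

## Combination extraction

For each of 27 cue-phrase rules (numbered stably; rule 9 is
`in combination with`), every match in an abstract spawns a context
structure: the **control phrase** at the root — the cue extended by up
to `window` (default **5**) tokens on each side — and left/right child
nodes holding the next up-to-5 tokens beyond it. The root stores the
extended fragment by default; a `extend_control=False` switch stores the
cue alone, since the source material is ambiguous about the root's
extent, and neither reading is asserted as canonical. Tokens are the
entity-mode tokens (punctuation counts toward the window); this is the
documented window unit.

Drug mentions intersecting any of the three regions are collected;
≥ 2 distinct names (after case-insensitive canonicalization:
NFKC, casefold, hyphen/space unification) yield one record holding
*all* of them — arity > 2 is not exploded into pairs unless requested
(`explode_pairs` / the `--pairs` CLI flag). Drugs inside the control
phrase count by default (`include_control=False` restricts the search to
the child nodes). Corpus-level extraction deduplicates identical
(article, drug-set) records keeping the lowest rule id and sorts output
deterministically.

The window-monotonicity property holds at the *pair* level: enlarging
the window can grow a record's drug set (a pair becomes a triple), so
records are compared after pair explosion. The 27 shipped cue patterns
are the package's own choice — the mechanism and count are fixed, the
phrasing inventory is user-replaceable YAML. Negation scope ("not
combined with") is not handled; that is a known limitation.

## Cross-referencing

Extracted names are canonicalized and looked up in an ordered list of
offline database tables (default priority drugbank > pubchem >
chemspider), names and synonyms both matching; the first listing table
wins, and unmatched names are flagged `new`. Mapped/unmapped always
partition the input, so reordering tables changes attribution only.
Name/synonym string matching (not structure or identifier matching) is
an explicit assumption.

## Synthetic corpora

The generator emulates the statistical structure the pipeline assumes,
not biomedical prose. Defaults are the study conditions: 17% failure
articles, a drug lexicon split drugbank/pubchem/chemspider/new =
50/35/8/7% (largest-remainder rounding), combination articles at rate
0.3, abstracts of 3–8 template sentences (the combination sentence runs
longer — see below). Success and failure articles draw outcome sentences
from two phrase vocabularies; `vocab_separation` s mixes them (own-class
with probability s, pooled otherwise), so s = 1 is perfectly separable
and s = 0 carries no signal. Distractor sentences plant comparison
expressions to exercise the filter. Real anchor drugs (ABT-737,
paclitaxel, imatinib with synonyms Gleevec/Glivec) are always present so
worked examples run against generated lexicons; remaining names are
pronounceable synthetic strings with drug-like suffixes plus a few
`XX-123`-style codes.

Each combination article contains exactly one cue with one drug
immediately before and one immediately after, and ≥ 10 tokens of
in-sentence padding on each side. Since the extractor's maximal reach is
2·window = 10 tokens beyond the cue at the default window, every other
drug mention sits outside the windows and the planted combinations are
exactly the recoverable ones; an independent windowed co-occurrence
oracle verifies this in the tests. Everything (articles, labels, spans,
lexicon) is byte-identically reproducible per seed.

What passing on these corpora does **not** show: robustness to real
biomedical prose (hedging, coordination ellipsis, novel drug-name
morphology, OCR noise), to annotation disagreement, or to reporting
language outside the template vocabularies. The published corpus-scale
figures (hundreds of thousands of articles, thousands of drugs) depend
on dated external database versions and manually annotated corpora that
are not redistributable, so they are expressly out of reproduction
scope; the test suite validates mechanisms against oracles and planted
ground truth instead.

## Problem sizes and numerical choices

The verification harness uses: classifier cross-validation at n = 2000
articles (10 folds, 300 trees) plus five label-permutation nulls; NER at
500 articles with an 80/20 split; combination extraction at 200
all-combination abstracts with windows {3, 5, 8}; candidate-gene checks
on 50 random 1000-pair tables; cross-referencing on a 1308-name lexicon
split 656/451/104/97. These sizes make every stage's behavior measurable
while keeping a full run in minutes on one CPU. Metric ratios with empty
denominators are reported as 0.0. All randomness flows from explicit
seeds; scikit-learn estimators run single-threaded for reproducibility.
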