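# Methods

`deidkit` labels protected health information (PHI) in clinical narrative
text, cast as token-level sequence labeling with IOB tags over the 23 i2b2
PHI subcategories (DATE, DOCTOR, PATIENT, HOSPITAL, AGE, PHONE, ZIP, …).
Three submodels propose PHI spans and a stacked meta-classifier arbitrates.
This note records the models, the tunable parameters and why they hold
their defaults, what the synthetic corpus does and does not emulate, and
the numerical/design choices made where the design was genuinely open.

## Subword tokenization

Whitespace tokens routinely glue PHI to surrounding characters
("Dr.Smith" contains the name "Smith"), making exact spans unreachable for
a token-level tagger. Tokenization therefore proceeds in three steps:

1. every character is split apart except maximal runs of letters and
   maximal runs of digits (Unicode categories decide "letter"/"digit");
2. letter runs are split immediately before each internal uppercase letter
   ("HealthCare" → Health, Care; "Edwin" stays whole);
3. byte pair encoding (BPE) merges the most frequent adjacent token pair,
   repeatedly, to undo over-splitting of frequent units.

"48-year-old in Edwin HealthCare" tokenizes to
(48, -, year, -, old, in, Edwin, Health, Care). Every token carries its
half-open character span; merges never cross a whitespace boundary, so the
source text is always reconstructible and character offsets stay exact.
BPE details the method leaves open were fixed as follows: frequency ties
break lexicographically on the pair; learning stops early when no pair
occurs twice (merging hapax pairs cannot reduce sparseness); the merge
count defaults to 1,000 for the standalone API and 200 in the pipeline
(the synthetic corpus vocabulary is small; more merges change nothing).
`phi_alignment_error_rate` measures the fraction of gold entities whose
boundary falls strictly inside a token — the quantity this tokenizer
exists to minimize; it is 0 on the synthetic corpus and bounds achievable
recall on any corpus.

Sentence boundaries (needed for the sentence-length feature) are newline
or `[.?!]` followed by whitespace and an uppercase letter; the splitter is
pluggable.

## Unified feature set

All learners consume one feature inventory: token-level (surface form,
length, all-digits flag, initial-uppercase flag, Porter-style stem,
prefixes/suffixes of lengths 1–4), global (sentence length in tokens,
section label derived from header lines such as `Record date:` or `HPI:`),
and tagging-based (POS and coarse NER labels from a pluggable external
tagger; a built-in surface-shape heuristic fills the slots by default, and
`NA` sentinels are emitted when no tagger is configured). Feature crosses
conjoin base features at token offsets in −2…+2 into composite features;
the default inventory of 49 crosses (`data/crosses_default.txt`) is
configuration, not code — the exact published inventory is not
recoverable, so the shipped set is a declared approximation built from
token/shape/POS/section features in a ±1 window. Extraction is pure:
identical inputs give identical vectors.

## Rule-based submodel: regex + transformation-based learning

The initial-state annotator is an ordered list of regular expressions,
each assigning an IOB tag. Patterns match the raw text (one published
pattern contains a space, so matching the token stream would lose it) and
matches project onto tokens: only tokens fully inside a match are tagged;
conflicts resolve by priority, then longer match, then leftmost. The
shipped file keeps the five published rows verbatim — including the
duplicated `\d{4}` alternative in the DATE row — plus a few structured-PHI
patterns (dates with separators, phone, 7-digit record number, 5-digit
zip) at higher priority. The initial annotator is deliberately weak
(strict F1 ≈ 38 on the synthetic benchmark); its job is to give the rule
learner something to correct.

Transformation-based error-driven learning then greedily induces an
ordered rule list. At each iteration, every position where the working tag
differs from gold instantiates one candidate rule per template ("if the
bound feature values hold here, rewrite from-tag to to-tag"); each
candidate's benefit is

    s(r) = errors fixed − correct tags broken,

counted over the whole corpus; the best rule is appended and applied.
Open details were fixed as follows:

* **Benefit** is the classic fixed-minus-broken convention.
* **Application is simultaneous**: conditions are evaluated against the
  pre-application tags everywhere, then all firing positions rewrite. This
  makes the corpus error count drop by exactly the selected benefit, so
  the training error sequence is strictly decreasing and training
  terminates.
* **Ties** break by fewer broken, then smaller template arity, then the
  lexicographic rule string — full determinism.
* **Stopping**: `min_score` defaults to 1 (no rule is kept unless it
  strictly reduces error) and `max_iters` to 200. The number of learned
  rules is a data-dependent outcome, not a setting (77 on the synthetic
  benchmark at seed 1).
* **Templates** are configuration (`data/templates_default.txt`): nine
  templates over token/length/digit-shape/affix/section/POS slots plus the
  current-tag slot at offset −1. Only the `tag` feature re-evaluates as
  rules rewrite tags; all other features are computed once from the text,
  keeping scoring linear in corpus size.

Scoring inside training buckets positions by (template, bound values,
current tag) and reads each candidate's fixed/broken counts from the
buckets — algebraically identical to scoring candidates one at a time (the
tests verify greedy selection against exhaustive enumeration of every
bindable rule) but one corpus pass per template per iteration.

Learned rules serialize to a human-readable ordered text file
(`IF token@0='Hospital' AND tag@-1='O' THEN O->I(HOSPITAL) # score=17`)
that parses back losslessly.

## CRF submodel

A linear-chain conditional random field with indicator feature functions:
one weight per (observation feature, tag) pair and one per tag bigram,
normalized by the partition function Z computed with the forward
algorithm. Observation features are the unified feature set plus crosses,
rendered as `name=value` strings. Training maximizes the L2-penalized
conditional log-likelihood (penalty λ‖w‖², λ = 0.0003); the gradient is
empirical minus expected feature counts via forward–backward. The
optimizer is batch gradient ascent whose initial step is the configured
learning rate (0.0005); a deterministic backtracking line search halves
the step on a decrease and grows it by 1.2 on success, which makes the
per-epoch training log-likelihood non-decreasing by construction — a fixed
step could not guarantee that. scipy's L-BFGS is available as an
alternative optimizer. Epochs default to 100 (40 in the pipeline, where
six fits run per training job); the stopping epoch is a free choice, as no
criterion is prescribed for it.

Decoding is Viterbi with ties broken toward the lowest tag index;
observation features unseen in training contribute nothing. IOB transition
constraints are not imposed at decode time; ill-formed output (an I tag
with no matching B) is repaired by reading each stray I as B of its
category, a convention shared by every tagger in the package. Correctness
is pinned by enumeration oracles: Viterbi against brute-force argmax,
total probability mass 1 within 1e−9, and the analytic gradient against
central finite differences within 1e−5 relative error.

## Stacking ensemble

Each registered submodel (rule-based, CRF, and optionally any object with
`fit(docs)`/`predict(doc)` — the slot intended for a neural tagger)
proposes entities per document. Identical (start, end, category) proposals
merge into one candidate with the union of sources; overlapping but
non-identical proposals remain separate candidates. Candidate features:
one indicator per registered submodel, the number of overlapping
candidates and the maximum character-overlap fraction, a category one-hot,
and the candidate's length in subword tokens. A binary RBF-kernel SVM
scores candidates; per-class misclassification weights default to 5.2
(positive) and 12.48 (negative) with kernel width γ = 0.009. Features are
standardized to zero mean and unit variance before the SVM: the feature
block is a mix of {0,1} indicators and small counts, and at γ = 0.009 the
kernel is nearly flat over raw differences of that scale, leaving the
classifier unable to condition on, e.g., the category one-hot.

Stacker training labels come from out-of-fold submodel predictions
(default 5 folds; submodels are retrained on each fold's complement), so
the meta-classifier never sees in-sample submodel output; a candidate is
positive iff it strictly matches a gold entity. At selection time,
candidates scoring above the decision threshold (default 0, the SVM's
native boundary) are kept and residual overlaps resolve greedily by
descending score, so the output is always a sorted, non-overlapping subset
of the candidate pool — the ensemble never invents spans.

## Evaluation

Strict entity-level micro-averaged precision, recall and F1: a prediction
counts only when start offset, end offset and category all equal a gold
entity's, each gold entity matching at most one prediction. Percentages
are reported to two decimals, with a per-category breakdown whose counts
sum to the overall counts. Duplicate identical predictions are
deduplicated before matching — the defensible convention where the
original challenge scorer is unavailable. F1 is 0 when either denominator
is empty.

## Synthetic corpus

The reference corpus (1,304 records, 28,867 PHI annotations) is
distributed only under a data use agreement, so the generator produces
surrogate notes: templated sentences, each carrying at most one PHI value
drawn from clearly fictional lexicons or format recipes, with exact
character offsets recorded at insertion. Category frequencies default to
the published training-set distribution (DATE 7,502; DOCTOR 2,885;
PATIENT 1,316; … BIOID 1), sampled i.i.d. per slot, so empirical
proportions converge to the weights (within ±3 points at 1,000 entities).
Documents carry `Record date:`/`HPI:` headers so section features are
exercised; DATE, PHONE, ZIP, EMAIL, USERNAME and MEDICALRECORD values are
constructed in formats the default regex patterns can match.

`hard=True` injects the confusion structure that makes ensembling
non-trivial: four-digit laboratory values ("A CK of 1028 was noted.") that
a bare `\d{4}` date pattern false-positives on, and a shared context pool
for CITY/STATE/COUNTRY so the context no longer identifies the geographic
category — only the surface form does. This gives the submodels
complementary strengths (the rule learner memorizes decisive surface
forms with high precision; the CRF generalizes context) without scripting
their outputs.

What the generator does **not** emulate: real clinical language (no
misspellings, abbreviations, copy-paste noise, or free narrative), PHI
co-reference across records, misaligned annotations, and the long tail of
date/phone formats. Passing tests therefore demonstrate correctness of
the machinery and the qualitative ensemble behavior, not the absolute
scores reachable on the restricted corpus — those depend on data the
package cannot ship.

`plant_rule_corpus` builds rule-learner recovery fixtures: a planted
corruption rewrites the gold tag at every site matching an expressible
template condition, and training must drive the error back to zero within
one iteration per corruption.

## Problem sizes and reproducibility

The benchmark used by the tests and by `scripts/acceptance.py` is 100
training and 50 test documents in hard mode (roughly 10,000 training
tokens, ~600 training entities) — large enough for every common category
to appear on both sides while a full train→tag→evaluate→ablate cycle
completes in a few minutes on one CPU. One root seed flows into every
random draw (generation, fold shuffling); two runs with the same seed
produce byte-identical rule files, model containers and evaluation
reports. The libsvm solver underlying the stacker is deterministic for a
fixed input order, and document order is fixed by generation.

## Known limitations

* The rule learner rescans the corpus every iteration (no
  Ramshaw–Marcus index); fine at desk scale, slow beyond ~10⁶ tokens.
* The CRF trains full-batch; no mini-batch or GPU path.
* The default cross inventory and rule templates are approximations of
  inventories the method's description leaves unspecified.
* The evaluation's duplicate handling may differ from the original
  challenge scorer in edge cases.
* No redaction/surrogate-replacement output: the system labels PHI, it
  does not rewrite text.
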