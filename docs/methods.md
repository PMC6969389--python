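# Methods

This note documents the models and procedures implemented in `forumminer`,
the parameters that matter, the synthetic study conditions, and the design
choices made where the design was genuinely open.

## Concept annotation

The annotator is a deterministic stand-in for a full biomedical
named-entity mapper (MetaMap-style tools add lexical variant generation,
candidate scoring and word-sense disambiguation, none of which are modeled
here). Text is normalized once, with one convention shared by the term
index, the matcher, and the classifier's tokenizer: lowercase, punctuation
stripped to token boundaries, whitespace tokenization.

Matching is greedy left-to-right longest match over token n-grams up to the
longest indexed term. At each position the longest indexed n-gram wins and
its tokens are consumed, so matches never overlap; a term resolving to
several CUIs emits one annotation per CUI (CUI-sorted), matching the
ambiguity semantics of large meta-vocabularies. Greedy longest match was
chosen over scored candidate generation because it is auditable and exactly
reproducible; its known failure mode (a long match shadowing a better short
one) is immaterial for the vocabulary sizes used here. An optional
stemming-aware mode (off by default) Porter-stems both query tokens and the
index so inflected mentions reach terms indexed in another inflection.

Two semantic types are analyzed — "Sign or Symptom" and "Disease or
Syndrome", belonging to the Symptoms and Disorders semantic groups. A
concept may carry several semantic types but exactly one group; the
annotation records the concept's target type (Sign or Symptom preferred,
then Disease or Syndrome, else the lexicographically first) so filtering is
well defined for multi-type concepts. Whether other semantic types inside
those two groups should also be kept is an open labeling question in this
domain; the filter is a plain `keep` set, so widening it is a one-argument
change.

The blocklist suppresses (term, CUI) *mappings*, not concepts: slang
homographs ("mod", "ect", "pic") must stop resolving to their colliding
medical concepts while legitimate mentions of those concepts through other
terms survive. `apply_blocklist` is idempotent and recomputes the maximum
term length.

Frequency is counted in **distinct posts per concept** everywhere: a
concept mentioned twice in one post counts once. Ties in every ranking are
broken by CUI so output ordering is total and stable.

## Health-sentiment classifier

"Sentiment" is health-outcome polarity, not emotional tone: Negative =
adverse effect co-occurring with e-cigarette use; Positive = improvement or
recovery when switching from smoking; Neutral = neither.

Feature extraction follows a five-step recipe: lowercase; remove stopwords;
stem; keep only terms whose **total corpus occurrence count** is at least 2;
retain unigrams, bigrams and trigrams. The occurrence threshold is read as a
total count rather than a document frequency (an n-gram seen twice in one
post and nowhere else is kept); this is configurable via
`VectorizerConfig.min_term_count`. The stemmer is a self-contained Porter
(1980) implementation and the stopword list is a frozen, deliberately small
English list vendored in `forumminer.text`, so vocabularies are bit-stable
across environments; aggressive stopword lists were avoided because
negations and modals carry signal in health complaints. Vocabulary order is
lexicographic, making feature indices deterministic.

Ancestor augmentation appends the lowercased preferred names of each
mentioned concept's hierarchy ancestors (default depth 1, i.e. direct
parents; configurable up to the full closure) to the post text,
deduplicated, in CUI-sorted order, with the original text preserved as a
prefix. Depth 1 is the default because "ancestors" is ambiguous between
direct parents and the full closure; direct parents add the least noise
while already enabling generalization across sibling conditions.

Class imbalance is addressed by duplicating Positive posts **in the
training partition only**. The default factor 112/67 restores the pilot
mixture (67 Positive of 400 growing to 112); the exact duplication rule for
a fractional factor is unspecified in this workflow's description, so every
target post is copied `floor(factor)` times and a seed-determined random
subset once more, reaching `round(n · factor)` exactly. The partition API
enforces the leakage rule: `split` returns typed train/test partitions and
`oversample` rejects the test partition outright.

The classifier is a scikit-learn Random Forest with 100 trees and a fixed
seed (no hyperparameters are prescribed for this pipeline; 100 trees with
default split criteria is the conventional baseline). Evaluation reports
per-class precision, recall and F (harmonic mean, 0 where undefined),
supports, the 3×3 confusion matrix in fixed (Negative, Neutral, Positive)
order, support-weighted means, and accuracy. Support-weighted recall equals
accuracy algebraically; the test suite asserts this to guard the weighting.

## Intercoder reliability

Average pairwise percent agreement over a fully crossed item × coder
matrix: for each unordered coder pair, 100 times the fraction of items
labeled identically; then the unweighted mean over pairs. The measure is
invariant under item and coder permutations and bounded in [0, 100]. No
chance-corrected coefficient (e.g. Fleiss' κ) is provided, deliberately:
the labeling workflow this mirrors used the uncorrected measure, and adding
a corrected one would invite silent substitution.

## System categorization

Conditions are consolidated into 12 organ systems / anatomical regions:
neurological, respiratory, digestive, mouth and throat, integumentary,
immune, circulatory, endocrine, muscular/skeletal, sensory, chest, whole
body/other. The first ten are well-attested category names in forum
health-effect reporting; "chest" and "whole body/other" cover thoracic pain
and general malaise. The list is provisional by construction and lives in a
user-editable TSV. "Strongest fit" for a condition with several candidate
systems (improved sense of taste: sensory, though arguably mouth and
throat) is operationalized as a static per-row priority rank resolved at
taxonomy load time — no algorithmic fit rule exists, so resolution is made
explicit, auditable data. Unmapped CUIs fall back to a reserved
"unclassified" system with one log line per CUI rather than failing a whole
tabulation.

Frequency tables are tidy/long, one row per (key, sentiment, year), where a
post contributes at most once per (system, concept); the grand total
therefore equals the number of distinct (post, concept) pairs in the
requested semantic group. Posts without timestamps are excluded and
tallied. Edge calendar years whose observed coverage does not span the year
(collection starting or stopping mid-year) are flagged in
`FrequencyTable.partial_years`. Top-condition rankings use a strict
threshold (post_count > min_posts, default 100), ties by CUI.

## Symptom co-occurrence

The pairing unit is the post (thread-level pairing is a deliberate
non-default: complaints in one post are the strongest co-report signal).
For each post, all unordered pairs of distinct symptom-group concepts count
once, canonicalized with the smaller CUI first; pairs above a strict
threshold are returned descending. The conventional "frequently reported"
tier (> 30 posts) is exposed as `FREQUENT_PAIR_TIER`. Restriction to the
Symptoms group is the default but overridable, since symptom-disorder
pairing is a plausible variant.

## Synthetic study conditions

The generator's defaults are the study conditions used throughout the test
suite and acceptance script:

- class mixture Negative 44.75% / Neutral 38.50% / Positive 16.75%, drawn
  per post from one seeded categorical draw;
- dates uniform over 2008-01-01..2015-06-30 (the final year a half year);
- Negative posts embed 1–3 conditions in complaint templates, Positive
  posts one condition in a switching/improvement template, Neutral posts
  gear talk only;
- homograph noise rate 0.10: a tenth of posts (all classes) carry one of
  "mod"/"ect"/"pic", prepended or appended so noise can never split an
  embedded multi-word term;
- every surface term in the fixture vocabulary resolves to exactly one
  concept, so generator bookkeeping equals ideal annotator output exactly.

Ground truth is written to a sidecar JSON keyed by post id, never into
fields the pipeline reads. What passing tests show: the matcher, counters
and tables are exact on text whose mentions are verbatim vocabulary terms.
What they do not show: robustness to misspellings, negation ("no headache
anymore"), inflection beyond the optional stemming mode, or creative slang
— real forum text is far harder, and classifier scores on the synthetic
corpus (near-perfect, since templates are separable) say nothing about
real-text accuracy.

A dedicated probe corpus isolates the value of ancestor augmentation: all
classes share one sentiment-neutral template; train-Positive posts spread
over several lung-disorder children (pneumonia, asthma, COPD) so no single
surface term separates the class, and test-Positive posts use different
children (bronchitis, lung infection). Without augmentation the held-out
Positive surface forms are out of vocabulary and recall collapses; with
augmentation the shared parent name carries the class. The effect is
asserted as a majority over 5 seeds, not per-seed, because Random Forest
vote splits make single seeds noisy.

## Numerical and interface choices

- Token spans are 0-based half-open everywhere.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  config + seed reproduces corpora byte for byte.
- Undefined precision/recall/F (empty denominators) are reported as 0.
- Degenerate inputs fail loudly: empty corpus for vocabulary building,
  single-class training sets, oversampling an absent class, evaluating an
  empty prediction list, <2 coders or missing cells in reliability.
- Problem sizes in the default test and acceptance runs (corpora of
  100–3000 posts, 2000 for exact parameter recovery) were chosen as the
  smallest sizes at which every count of interest is comfortably nonzero;
  the pipeline itself is linear in corpus size.

## Known limitations

- The matcher has no spelling correction, negation handling or acronym
  expansion; it annotates what is literally written.
- The 12-system taxonomy and the fixture vocabulary are synthetic curation,
  not a licensed vocabulary excerpt; CUIs beyond the handful of well-known
  ones are placeholders.
- Percent agreement is not chance-corrected; with three balanced classes,
  chance agreement alone is ~33%.
- The classifier pipeline reproduces a recipe, not a benchmark: no
  hyperparameter search, no alternative models, and no claim about accuracy
  on real forum corpora, which are not distributable.
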