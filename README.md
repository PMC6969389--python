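# forumminer

Automated mining of self-reported health effects from e-cigarette forum
posts. Users of vaping forums describe symptoms ("headache every night since
I started vaping"), diagnosed disorders ("my asthma is back"), and
improvements after switching from smoking. `forumminer` turns a corpus of
such free-text posts into structured, analyzable tables for infodemiology
and adverse-event surveillance work:

1. **Concept annotation** — a deterministic dictionary matcher (greedy
   left-to-right longest match over token n-grams) maps post text to a
   controlled medical vocabulary in which every concept carries a CUI,
   surface synonyms, semantic types, one semantic group, and parent
   concepts. Only the *Sign or Symptom* and *Disease or Syndrome* semantic
   types are kept, and a (term, CUI) blocklist suppresses mappings triggered
   by forum slang homographs ("mod" → Type 2 diabetes mellitus, "ect" →
   Benign Rolandic epilepsy, "pic" → Punctate inner choroidopathy).
2. **Health-sentiment classification** — each post is labeled Negative
   (adverse effect co-occurring with e-cigarette use), Positive (health
   improvement after switching from smoking), or Neutral. Features are
   counts of stemmed, stopword-filtered word n-grams (n = 1..3, total
   occurrence ≥ 2); post text is augmented with the names of each mentioned
   concept's hierarchy ancestors (pneumonia contributes "disorder of lung");
   the minority Positive class is oversampled by duplication in the training
   partition only; the classifier is a 100-tree Random Forest.
3. **Reliability** — average pairwise percent agreement over the coders who
   produced the manual labels: the mean over coder pairs of
   100 · |items labeled identically| / |items|.
4. **Categorization** — annotated conditions are consolidated into 12 organ
   systems / anatomical regions (neurological, respiratory, …), with
   strongest-fit resolution for multi-system candidates, and tallied as
   tidy (key, sentiment, year, post_count) tables where `post_count` is
   always *distinct posts per concept*.
5. **Co-occurrence** — unordered pairs of distinct symptom concepts
   mentioned within one post, counted once per post and ranked.

Because real forum corpora of this kind are not redistributable, the package
ships a first-class synthetic-data module: a ~100-concept fixture
vocabulary/taxonomy (synthetic, but covering all 12 systems, multi-word
terms, a multi-level parent chain and the three homograph collisions) and a
corpus generator that emits posts together with exact ground truth, so every
stage is testable end to end.

## Worked example

```python
from forumminer import (Post, annotate_post, apply_blocklist,
                        concept_frequencies, fixture_blocklist, fixture_lexicon)

lex = apply_blocklist(fixture_lexicon(), fixture_blocklist())
posts = [
    Post(post_id="a", text="I've had a sore throat and coughing since last week"),
    Post(post_id="b", text="my new mod arrived today, loving it"),
    Post(post_id="c", text="constant headache, plus pain in throat at night"),
]
for p in posts:
    print(p.post_id, [(a.cui, a.matched_term) for a in annotate_post(p, lex)])
print(concept_frequencies([(p, annotate_post(p, lex)) for p in posts], lex))
```

prints

```
a [('C0242429', 'sore throat'), ('C0010200', 'coughing')]
b []
c [('C0018681', 'headache'), ('C0242429', 'pain in throat')]
        cui preferred_name  post_count
0  C0242429 Pain in throat           2
1  C0010200       Coughing           1
2  C0018681       Headache           1
```

Post *b* mentions "mod" — without the blocklist it would be annotated with
Type 2 diabetes mellitus (C0011860); with it, nothing. "sore throat" and
"pain in throat" are synonyms of one concept, so it is counted in two
distinct posts, and the repeated mention in post *c* does not double-count.

The scripts in `examples/` walk through each capability (corpus generation,
annotation, classifier training, reliability, system frequency tables,
symptom pairs) and print the numbers they compute.

## Command line

A thin CLI mirrors the pipeline stages and writes per-stage manifests
(config echo, seed, input checksums, row counts):

```bash
forumminer all --seed 3 --out run/           # generate → annotate → train
                                             # → evaluate → categorize → pairs
forumminer annotate --config cfg.yaml --out run/
```

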