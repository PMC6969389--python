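"""Train and evaluate the three-class health-sentiment classifier.

The full recipe: bag of stemmed, stopword-filtered 1-3-grams kept at a
total-occurrence threshold of 2, ancestor-concept augmentation of the post
text, Positive-class oversampling in the training partition only, and a
100-tree Random Forest.
"""

import numpy as np

from forumminer import (
    GeneratorConfig,
    VectorizerConfig,
    annotate_post,
    apply_blocklist,
    augment_ancestors,
    build_vocabulary,
    evaluate,
    fixture_blocklist,
    fixture_lexicon,
    generate_corpus,
    oversample,
    split,
    train,
    vectorize_corpus,
)
from forumminer.sentiment import LabeledPost
from forumminer.synthetic import labeled_posts

lex = apply_blocklist(fixture_lexicon(), fixture_blocklist())
posts, truth = generate_corpus(GeneratorConfig(n_posts=1080, seed=7))
data = []
for item in labeled_posts(posts, truth):
    anns = annotate_post(item.post, lex)
    data.append(
        LabeledPost(post=augment_ancestors(item.post, anns, lex, depth=1),
                    label=item.label)
    )

train_part, test_part = split(data, 962, 118, seed=7)
balanced = oversample(train_part, "Positive", 112 / 67, seed=7)
print(f"train {len(train_part)} -> {len(balanced)} after Positive oversampling; "
      f"test {len(test_part)}")

cfg = VectorizerConfig()
vocab = build_vocabulary(balanced, cfg)
model = train(vectorize_corpus([d.post for d in balanced], vocab, cfg),
              [d.label for d in balanced], seed=7)
pred = model.predict(vectorize_corpus([d.post for d in test_part], vocab, cfg))
report = evaluate(list(zip([d.label for d in test_part], pred)))

print(f"vocabulary size {len(vocab)}")
print(f"accuracy {report.accuracy:.4f}")
for label, stats in report.per_class.items():
    print(f"  {label:9s} P={stats['precision']:.2f} R={stats['recall']:.2f} "
          f"F={stats['f_measure']:.2f} n={stats['support']}")
print(f"  weighted  P={report.weighted_precision:.2f} "
      f"R={report.weighted_recall:.2f} F={report.weighted_f:.2f}")
# Synthetic templates are fully separable, so near-perfect scores here just
# confirm the plumbing; real forum text is far harder.
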