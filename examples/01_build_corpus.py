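"""Generate a synthetic forum corpus with exact ground truth.

Builds a seed-reproducible corpus that mimics the structure of e-cigarette
forum health posts: a Negative/Neutral/Positive health-sentiment mixture of
44.75/38.50/16.75 percent, complaint posts embedding 1-3 known conditions,
improvement posts referencing one condition, and slang homograph tokens
("mod", "ect", "pic") sprinkled in as annotation noise.
"""

from collections import Counter

from forumminer import GeneratorConfig, generate_corpus

cfg = GeneratorConfig(n_posts=1000, seed=42)
posts, truth = generate_corpus(cfg)

counts = Counter(rec["sentiment"] for rec in truth.per_post.values())
print(f"generated {len(posts)} posts spanning "
      f"{min(p.timestamp for p in posts)} .. {max(p.timestamp for p in posts)}")
for label in ("Negative", "Neutral", "Positive"):
    print(f"  {label:9s} {counts[label]:4d} ({100 * counts[label] / len(posts):.2f}%)")

example = posts[0]
print(f"\nsample post {example.post_id} ({example.timestamp}):")
print(f"  {example.text!r}")
print(f"  embedded concepts: {truth.per_post[example.post_id]['cuis']}")
# The class shares land near the configured mixture; each post's embedded
# CUIs are the exact annotations a perfect concept mapper should recover.
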