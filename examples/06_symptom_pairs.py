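"""Count symptom pairs co-reported within single posts.

Every unordered pair of distinct symptom concepts mentioned in the same post
counts once for that post; ranking the pairs shows which complaints travel
together (e.g. nausea with headache).
"""

from forumminer import (
    GeneratorConfig,
    annotate_post,
    apply_blocklist,
    assign_system,
    fixture_blocklist,
    fixture_lexicon,
    fixture_taxonomy,
    generate_corpus,
    symptom_pairs,
)

lex = apply_blocklist(fixture_lexicon(), fixture_blocklist())
tax = fixture_taxonomy()
posts, _truth = generate_corpus(GeneratorConfig(n_posts=3000, seed=13))
annotated = [(p, annotate_post(p, lex)) for p in posts]

pairs = symptom_pairs(annotated, min_posts=0)
print(f"{len(pairs)} distinct symptom pairs observed; top 8:")
for p in pairs[:8]:
    name_a, name_b = lex.get(p.cui_a).preferred_name, lex.get(p.cui_b).preferred_name
    sys_a, sys_b = assign_system(p.cui_a, tax), assign_system(p.cui_b, tax)
    print(f"  {name_a} ({sys_a}) + {name_b} ({sys_b}): {p.post_count} posts")
# Pair counts are symmetric and post-level: repeating either symptom inside
# one post never inflates the pair's count.
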