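"""Consolidate reported conditions into organ systems and stratify counts.

Each annotated condition maps to one of 12 organ systems / anatomical
regions; frequency tables count distinct posts per concept, split by
sentiment and calendar year, and a >100-post threshold picks out the most
commonly reported conditions.
"""

from forumminer import (
    GeneratorConfig,
    annotate_post,
    apply_blocklist,
    fixture_blocklist,
    fixture_lexicon,
    fixture_taxonomy,
    frequency_by_condition,
    frequency_by_system,
    generate_corpus,
    top_conditions,
)

lex = apply_blocklist(fixture_lexicon(), fixture_blocklist())
tax = fixture_taxonomy()
posts, truth = generate_corpus(GeneratorConfig(n_posts=3000, seed=11))
labels = truth.labels()
rows = [(p, annotate_post(p, lex), labels[p.post_id]) for p in posts]

freq = frequency_by_system(rows, tax, "Symptoms")
print("top symptom systems (all sentiments/years pooled):")
print(freq.totals().head(5).to_string(index=False))
print(f"partial coverage years: {freq.partial_years}")

by_year = (
    freq.table[freq.table.sentiment == "Negative"]
    .groupby("year")["post_count"].sum()
)
print("\nnegative symptom reports per year:")
print(by_year.to_string())

cond = frequency_by_condition(rows, "Symptoms")
print("\nsymptoms reported in more than 30 posts:")
for cui, count in top_conditions(cond, min_posts=30):
    print(f"  {lex.get(cui).preferred_name:30s} {count:4d}")
# Counts are distinct posts per concept; a post mentioning a symptom twice
# still counts once, matching how report frequencies are tallied.
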