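"""Map post text to medical concepts and suppress slang homographs.

The annotator runs greedy longest-match over the vocabulary's term index,
keeps the "Sign or Symptom" / "Disease or Syndrome" semantic types, and the
blocklist removes mappings triggered by forum slang ("mod" is a vaping
device, not diabetes).
"""

from forumminer import (
    Post,
    annotate_post,
    apply_blocklist,
    concept_frequencies,
    fixture_blocklist,
    fixture_lexicon,
)

plain = fixture_lexicon()
lex = apply_blocklist(plain, fixture_blocklist())

posts = [
    Post(post_id="a", text="I've had a sore throat and coughing since last week"),
    Post(post_id="b", text="my new mod arrived today, loving it"),
    Post(post_id="c", text="constant headache, plus pain in throat at night"),
]

for post in posts:
    without = {a.cui for a in annotate_post(post, plain)}
    with_bl = [(a.cui, a.matched_term) for a in annotate_post(post, lex)]
    print(f"{post.post_id}: {post.text!r}")
    print(f"   annotations: {with_bl}")
    if without - {c for c, _t in with_bl}:
        print(f"   blocklist suppressed: {sorted(without - {c for c, _ in with_bl})}")

annotated = [(p, annotate_post(p, lex)) for p in posts]
print("\nconcept frequency (distinct posts per concept):")
print(concept_frequencies(annotated, lex).to_string(index=False))
# "pain in throat" and "sore throat" resolve to the same concept, so it is
# counted in two distinct posts; "mod" maps to nothing once blocked.
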