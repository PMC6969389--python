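"""Map normalized post text to lexicon concepts.

The matcher is a deterministic, auditable stand-in for a full biomedical
named-entity mapper: greedy left-to-right longest match over token n-grams,
up to the longest indexed term. Matches never overlap; an ambiguous term
emits one annotation per concept it resolves to. Semantic-type filtering then
keeps the two types this pipeline analyzes — "Sign or Symptom" and
"Disease or Syndrome" — which belong to the Symptoms and Disorders semantic
groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io import Post
from .lexicon import Concept, Lexicon
from .text import normalize, porter_stem

__all__ = [
    "Annotation",
    "DEFAULT_SEMANTIC_TYPES",
    "normalize",
    "match_concepts",
    "annotate_post",
    "filter_semantic_types",
    "concept_frequencies",
    "write_annotations_csv",
]

#: The two semantic types analyzed by the pipeline.
DEFAULT_SEMANTIC_TYPES = frozenset({"Sign or Symptom", "Disease or Syndrome"})

# Preference order used to pick the single reported semantic type for a
# concept carrying several.
_TYPE_PREFERENCE = ("Sign or Symptom", "Disease or Syndrome")


@dataclass(frozen=True)
class Annotation:
    """One (post, concept, matched span) record.

    ``token_span`` is 0-based half-open over the normalized token sequence;
    ``matched_term`` equals the tokens in the span joined by single spaces.
    """

    post_id: str
    cui: str
    matched_term: str
    token_span: tuple[int, int]
    semantic_type: str
    semantic_group: str

    def __post_init__(self) -> None:
        if self.token_span[1] <= self.token_span[0]:
            raise ValueError("token_span end must exceed start")


def _reported_type(concept: Concept) -> str:
    for name in _TYPE_PREFERENCE:
        if name in concept.semantic_types:
            return name
    return min(concept.semantic_types) if concept.semantic_types else ""


def match_concepts(
    tokens: Sequence[str],
    lex: Lexicon,
    post_id: str = "",
    stem: bool = False,
) -> list[Annotation]:
    """Greedy left-to-right longest-match annotation of a token sequence.

    At each position the longest indexed n-gram (up to ``lex.max_term_length``
    tokens) wins; matched tokens are consumed so spans never overlap. A term
    resolving to several CUIs emits one annotation per CUI (sorted). Blocked
    (term, cui) pairs are absent from the index of a blocklist-filtered
    lexicon and therefore never surface here.

    With ``stem=True`` both the query tokens and the index are Porter-stemmed
    before comparison, so inflected mentions ("headaches") reach terms
    indexed in another inflection.
    """
    if stem:
        index = lex.stemmed_index()
        query = [porter_stem(tok) for tok in tokens]
    else:
        index = lex.term_index
        query = list(tokens)

    annotations: list[Annotation] = []
    n = len(query)
    max_len = lex.max_term_length
    i = 0
    while i < n:
        matched = False
        for length in range(min(max_len, n - i), 0, -1):
            term = " ".join(query[i : i + length])
            cuis = index.get(term)
            if cuis:
                surface = " ".join(tokens[i : i + length])
                for cui in sorted(cuis):
                    concept = lex.get(cui)
                    annotations.append(
                        Annotation(
                            post_id=post_id,
                            cui=cui,
                            matched_term=surface,
                            token_span=(i, i + length),
                            semantic_type=_reported_type(concept),
                            semantic_group=concept.semantic_group,
                        )
                    )
                i += length
                matched = True
                break
        if not matched:
            i += 1
    return annotations


def annotate_post(
    post: Post,
    lex: Lexicon,
    keep: frozenset[str] | set[str] | None = DEFAULT_SEMANTIC_TYPES,
    stem: bool = False,
) -> list[Annotation]:
    """Normalize a post's text, match concepts, and filter semantic types.

    ``keep=None`` skips the semantic-type filter.
    """
    anns = match_concepts(normalize(post.text), lex, post_id=post.post_id, stem=stem)
    if keep is None:
        return anns
    return filter_semantic_types(anns, keep)


def filter_semantic_types(
    ann: Iterable[Annotation], keep: frozenset[str] | set[str]
) -> list[Annotation]:
    """Retain annotations whose semantic type is in ``keep`` (stable order)."""
    return [a for a in ann if a.semantic_type in keep]


def concept_frequencies(
    annotated_posts: Iterable[tuple[Post, Sequence[Annotation]]],
    lex: Lexicon,
) -> pd.DataFrame:
    """Concepts ordered by how many DISTINCT posts mention them.

    A concept mentioned twice in one post counts once — post counts, not
    mention counts, are the frequency unit throughout the pipeline. Rows are
    sorted by descending count, ties broken by CUI.
    """
    seen: dict[str, set[str]] = {}
    for post, anns in annotated_posts:
        for a in anns:
            seen.setdefault(a.cui, set()).add(post.post_id)
    rows = [
        (cui, lex.get(cui).preferred_name, len(posts))
        for cui, posts in seen.items()
    ]
    rows.sort(key=lambda r: (-r[2], r[0]))
    return pd.DataFrame(rows, columns=["cui", "preferred_name", "post_count"])


def write_annotations_csv(
    annotated_posts: Iterable[tuple[Post, Sequence[Annotation]]],
    lex: Lexicon,
    path: str | Path,
) -> int:
    """Write annotations as CSV; returns the number of rows written."""
    rows = []
    for _post, anns in annotated_posts:
        for a in anns:
            rows.append(
                {
                    "post_id": a.post_id,
                    "cui": a.cui,
                    "preferred_name": lex.get(a.cui).preferred_name,
                    "matched_term": a.matched_term,
                    "span_start": a.token_span[0],
                    "span_end": a.token_span[1],
                    "semantic_type": a.semantic_type,
                    "semantic_group": a.semantic_group,
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "post_id", "cui", "preferred_name", "matched_term",
            "span_start", "span_end", "semantic_type", "semantic_group",
        ],
    )
    frame.to_csv(path, index=False)
    return len(frame)
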