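"""Paired-symptom counting: conditions co-reported within single posts.

Users frequently report linked symptoms (nausea with headache, wheezing
with coughing). The pairing unit is the post: every unordered pair of
distinct concepts mentioned in one post counts once for that post, however
often either is repeated. Pairs are canonicalized with the lexicographically
smaller CUI first.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotator import Annotation
from .categorizer import SystemTaxonomy, assign_system
from .io import Post
from .lexicon import Lexicon

__all__ = ["SymptomPair", "FREQUENT_PAIR_TIER", "symptom_pairs", "write_pairs_csv"]

#: Report tier separating "frequently reported" pairs (strictly more posts
#: than this) from the long tail.
FREQUENT_PAIR_TIER = 30


@dataclass(frozen=True)
class SymptomPair:
    """Unordered concept pair with its distinct-post count (cui_a < cui_b)."""

    cui_a: str
    cui_b: str
    post_count: int

    def __post_init__(self) -> None:
        if self.cui_a >= self.cui_b:
            raise ValueError("pair must be canonical: cui_a < cui_b")
        if self.post_count < 1:
            raise ValueError("post_count must be >= 1")

    def matches(self, x: str, y: str) -> bool:
        return {x, y} == {self.cui_a, self.cui_b}


def symptom_pairs(
    annotated_posts: Iterable[tuple[Post, Sequence[Annotation]]],
    min_posts: int = 0,
    group: str | None = "Symptoms",
) -> list[SymptomPair]:
    """Rank unordered concept pairs by the number of posts reporting both.

    ``group`` restricts annotations to one semantic group before pairing
    (``None`` pairs across groups); callers that pre-filtered can pass the
    group their annotations already satisfy. Pairs with post_count strictly
    greater than ``min_posts`` are returned descending, ties broken by
    (cui_a, cui_b).
    """
    counts: dict[tuple[str, str], int] = {}
    for _post, anns in annotated_posts:
        cuis = {a.cui for a in anns if group is None or a.semantic_group == group}
        for pair in combinations(sorted(cuis), 2):
            counts[pair] = counts.get(pair, 0) + 1
    pairs = [
        SymptomPair(a, b, c) for (a, b), c in counts.items() if c > min_posts
    ]
    pairs.sort(key=lambda p: (-p.post_count, p.cui_a, p.cui_b))
    return pairs


def write_pairs_csv(
    pairs: Sequence[SymptomPair],
    lex: Lexicon,
    tax: SystemTaxonomy,
    path: str | Path,
) -> int:
    """Write ranked pairs with names and systems; returns rows written."""
    rows = [
        {
            "cui_a": p.cui_a,
            "name_a": lex.get(p.cui_a).preferred_name,
            "system_a": assign_system(p.cui_a, tax),
            "cui_b": p.cui_b,
            "name_b": lex.get(p.cui_b).preferred_name,
            "system_b": assign_system(p.cui_b, tax),
            "post_count": p.post_count,
        }
        for p in pairs
    ]
    frame = pd.DataFrame(
        rows,
        columns=["cui_a", "name_a", "system_a", "cui_b", "name_b", "system_b", "post_count"],
    )
    frame.to_csv(path, index=False)
    return len(frame)
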