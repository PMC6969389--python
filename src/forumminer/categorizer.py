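"""Group annotated conditions into organ systems and build frequency tables.

Reported symptoms and disorders are consolidated into 12 organ systems /
anatomical regions ("systems"). A condition that could plausibly belong to
several systems is resolved once, at taxonomy load time, to the system with
the strongest fit — operationalized as a static priority rank, since no
algorithmic fit rule exists. Frequency tables are tidy/long: one row per
(key, sentiment, year) where the key is a system or an individual concept,
and the counting unit is always distinct posts per concept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotator import Annotation
from .io import Post

__all__ = [
    "DEFAULT_SYSTEMS",
    "UNCLASSIFIED",
    "SystemTaxonomy",
    "FrequencyTable",
    "load_taxonomy",
    "assign_system",
    "frequency_by_system",
    "frequency_by_condition",
    "top_conditions",
]

logger = logging.getLogger(__name__)

#: Default 12-system list. Provisional by construction: ten systems are
#: well-attested category names in forum health-effect reports; "chest" and
#: "whole body/other" cover thoracic pain and general malaise. The taxonomy
#: is an editable TSV so a corrected list drops in without code changes.
DEFAULT_SYSTEMS = (
    "neurological",
    "respiratory",
    "digestive",
    "mouth and throat",
    "integumentary",
    "immune",
    "circulatory",
    "endocrine",
    "muscular/skeletal",
    "sensory",
    "chest",
    "whole body/other",
)

#: Reserved fallback system for concepts absent from the taxonomy.
UNCLASSIFIED = "unclassified"


@dataclass
class SystemTaxonomy:
    """Concept → system assignment with strongest-fit resolution.

    The source TSV may list a CUI under several candidate systems; the row
    with the smallest priority rank wins at load time, so lookup afterwards
    is a pure map access.
    """

    systems: tuple[str, ...]
    assignment: dict[str, str]
    priority: dict[str, int]
    _warned: set = field(default_factory=set, repr=False)


def load_taxonomy(path, systems: Sequence[str] = DEFAULT_SYSTEMS) -> SystemTaxonomy:
    """Load a taxonomy TSV (columns ``cui``, ``system``, ``priority``).

    Multi-system candidates are resolved to the lowest priority rank
    (ties broken by system name for determinism).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("cui", "system", "priority"):
        if col not in frame.columns:
            raise ValueError(f"taxonomy file missing column: {col}")
    if len(set(systems)) != len(tuple(systems)):
        raise ValueError("systems list contains duplicates")

    best: dict[str, tuple[int, str]] = {}
    priority: dict[str, int] = {}
    for row in frame.itertuples(index=False):
        rank = int(row.priority)
        key = (rank, row.system)
        if row.cui not in best or key < best[row.cui]:
            best[row.cui] = key
        priority.setdefault(row.system, rank)
    return SystemTaxonomy(
        systems=tuple(systems),
        assignment={cui: system for cui, (_rank, system) in best.items()},
        priority=priority,
    )


def assign_system(cui: str, tax: SystemTaxonomy) -> str:
    """The single system a concept maps to; ``"unclassified"`` if unmapped.

    An unmapped CUI is logged once (per taxonomy object) and falls back to
    the reserved system rather than failing the whole tabulation.
    """
    system = tax.assignment.get(cui)
    if system is None:
        if cui not in tax._warned:
            tax._warned.add(cui)
            logger.warning("cui %s has no taxonomy entry; using %r", cui, UNCLASSIFIED)
        return UNCLASSIFIED
    return system


@dataclass
class FrequencyTable:
    """Tidy (key, sentiment, year, post_count) counts.

    ``table`` columns: key, key_type ("system" or "cui"), semantic_group,
    sentiment, year, post_count. ``n_excluded`` counts posts dropped for a
    missing timestamp; ``partial_years`` flags calendar years whose coverage
    does not span the full year (e.g. collection started or stopped
    mid-year), inferred from the corpus date range.
    """

    table: pd.DataFrame
    key_type: str
    n_excluded: int = 0
    partial_years: tuple[int, ...] = ()

    def totals(self) -> pd.DataFrame:
        """Sentiment- and year-agnostic totals per key, descending."""
        out = (
            self.table.groupby("key", as_index=False)["post_count"]
            .sum()
            .sort_values(["post_count", "key"], ascending=[False, True], kind="mergesort")
            .reset_index(drop=True)
        )
        return out


def _build_table(
    annotated_posts: Iterable[tuple[Post, Sequence[Annotation], str]],
    group: str,
    key_of,
    key_type: str,
) -> FrequencyTable:
    counts: dict[tuple[str, str, int], set[tuple[str, str]]] = {}
    n_excluded = 0
    dates = []
    for post, anns, sentiment in annotated_posts:
        if post.timestamp is None:
            n_excluded += 1
            continue
        dates.append(post.timestamp)
        year = post.timestamp.year
        # Distinct (post, concept): repeat mentions never double-count.
        for cui in {a.cui for a in anns if a.semantic_group == group}:
            key = key_of(cui)
            counts.setdefault((key, sentiment, year), set()).add((post.post_id, cui))

    rows = [
        {
            "key": key,
            "key_type": key_type,
            "semantic_group": group,
            "sentiment": sentiment,
            "year": year,
            "post_count": len(pairs),
        }
        for (key, sentiment, year), pairs in sorted(counts.items())
    ]
    table = pd.DataFrame(
        rows,
        columns=["key", "key_type", "semantic_group", "sentiment", "year", "post_count"],
    )
    # Edge years whose observed coverage does not span the calendar year are
    # flagged so per-year comparisons can note the partial windows.
    partial: list[int] = []
    if dates:
        lo, hi = min(dates), max(dates)
        if (lo.month, lo.day) != (1, 1):
            partial.append(lo.year)
        if (hi.month, hi.day) < (12, 1) and hi.year not in partial:
            partial.append(hi.year)
    return FrequencyTable(
        table=table, key_type=key_type, n_excluded=n_excluded,
        partial_years=tuple(partial),
    )


def frequency_by_system(
    annotated_posts: Iterable[tuple[Post, Sequence[Annotation], str]],
    tax: SystemTaxonomy,
    group: str,
) -> FrequencyTable:
    """Distinct-post condition counts consolidated into systems.

    ``group`` restricts annotations to one semantic group ("Symptoms" or
    "Disorders"). A post contributes at most once per (system, concept):
    two distinct neurological concepts in one post add 2 to neurological,
    a concept mentioned twice adds 1. Posts without timestamps are excluded
    and tallied in ``n_excluded``.
    """
    return _build_table(
        annotated_posts, group, lambda cui: assign_system(cui, tax), "system"
    )


def frequency_by_condition(
    annotated_posts: Iterable[tuple[Post, Sequence[Annotation], str]],
    group: str,
) -> FrequencyTable:
    """Per-concept (CUI-granularity) sentiment/year frequency table."""
    return _build_table(annotated_posts, group, lambda cui: cui, "cui")


def top_conditions(
    freq: FrequencyTable, min_posts: int = 100
) -> list[tuple[str, int]]:
    """Conditions whose total post count strictly exceeds ``min_posts``.

    Returned descending by count, ties broken by CUI. The default threshold
    of 100 posts matches the reporting cut used for per-condition frequency
    distributions.
    """
    if min_posts < 0:
        raise ValueError("min_posts must be >= 0")
    totals = freq.totals()
    kept = totals[totals["post_count"] > min_posts]
    return [(row.key, int(row.post_count)) for row in kept.itertuples(index=False)]
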