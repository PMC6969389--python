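"""Medical-concept vocabulary: loading, validation, hierarchy, blocklist.

The vocabulary plays the role a large controlled biomedical vocabulary plays
in concept-annotation pipelines: every concept has a stable identifier (CUI),
a preferred name, surface synonyms, one or more fine-grained semantic types,
exactly one coarse semantic group, and zero or more parent concepts. The file
format is a flat TSV (columns ``cui``, ``preferred_name``, ``synonyms``,
``semantic_types``, ``semantic_group``, ``parent_cuis``; multi-valued columns
pipe-separated) so a self-contained fixture vocabulary can ship with the
repository instead of a license-restricted release.

The blocklist suppresses individual (term, CUI) mappings — the mechanism used
to remove mappings triggered by community slang homographs (e.g. "mod" for a
vaping device colliding with a diabetes concept) while keeping legitimate
mentions of the same concept through its other terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .text import normalize, porter_stem

__all__ = [
    "Concept",
    "Lexicon",
    "Blocklist",
    "LexiconError",
    "load_lexicon",
    "load_blocklist",
    "ancestors",
    "apply_blocklist",
]

logger = logging.getLogger(__name__)


class LexiconError(ValueError):
    """Raised when a vocabulary file violates a structural invariant."""


def _norm_term(term: str) -> str:
    """Canonical index key: normalized tokens joined by single spaces."""
    return " ".join(normalize(term))


@dataclass(frozen=True)
class Concept:
    """One vocabulary entry.

    A concept may carry several semantic types but belongs to exactly one
    semantic group; ``terms`` always includes the preferred name.
    """

    cui: str
    preferred_name: str
    terms: frozenset[str]
    semantic_types: frozenset[str]
    semantic_group: str
    parent_cuis: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.terms:
            raise LexiconError(f"{self.cui}: terms must be nonempty")
        if self.cui in self.parent_cuis:
            raise LexiconError(f"{self.cui}: concept lists itself as a parent")


class Lexicon:
    """An indexed concept vocabulary.

    ``term_index`` maps each normalized surface term to the set of CUIs it
    resolves to; ``max_term_length`` is the token length of the longest
    indexed term, bounding the n-gram window the annotator scans.
    """

    def __init__(
        self,
        concepts: Mapping[str, Concept],
        term_index: Mapping[str, frozenset[str]] | None = None,
    ) -> None:
        self.concepts: dict[str, Concept] = dict(concepts)
        if term_index is None:
            term_index = self._build_index(self.concepts)
        # Drop index entries that resolve to nothing (invariant).
        self.term_index: dict[str, frozenset[str]] = {
            t: frozenset(cuis) for t, cuis in term_index.items() if cuis
        }
        self.max_term_length: int = max(
            (len(t.split()) for t in self.term_index), default=0
        )
        self._stemmed_index: dict[str, frozenset[str]] | None = None
        self._validate()

    @staticmethod
    def _build_index(concepts: Mapping[str, Concept]) -> dict[str, frozenset[str]]:
        index: dict[str, set[str]] = {}
        for concept in concepts.values():
            for term in concept.terms:
                key = _norm_term(term)
                if key:
                    index.setdefault(key, set()).add(concept.cui)
        return {t: frozenset(cuis) for t, cuis in index.items()}

    def _validate(self) -> None:
        for term, cuis in self.term_index.items():
            unknown = cuis - self.concepts.keys()
            if unknown:
                raise LexiconError(
                    f"term {term!r} maps to unknown cui(s) {sorted(unknown)}"
                )
        cycle = self._find_cycle()
        if cycle:
            raise LexiconError("cycle in parent hierarchy: " + " -> ".join(cycle))

    def _find_cycle(self) -> list[str] | None:
        """Iterative DFS over the parent graph; returns one cycle if present."""
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {cui: WHITE for cui in self.concepts}
        for root in self.concepts:
            if color[root] != WHITE:
                continue
            stack: list[tuple[str, iter]] = [(root, iter(self._parents_of(root)))]
            color[root] = GRAY
            path = [root]
            while stack:
                node, children = stack[-1]
                advanced = False
                for child in children:
                    if color.get(child, BLACK) == WHITE:
                        color[child] = GRAY
                        stack.append((child, iter(self._parents_of(child))))
                        path.append(child)
                        advanced = True
                        break
                    if color.get(child) == GRAY:
                        return path[path.index(child):] + [child]
                if not advanced:
                    color[node] = BLACK
                    stack.pop()
                    path.pop()
        return None

    def _parents_of(self, cui: str) -> list[str]:
        concept = self.concepts.get(cui)
        if concept is None:
            return []
        return sorted(p for p in concept.parent_cuis if p in self.concepts)

    # -- queries ------------------------------------------------------------

    def __contains__(self, cui: str) -> bool:
        return cui in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    def get(self, cui: str) -> Concept:
        try:
            return self.concepts[cui]
        except KeyError:
            raise KeyError(f"unknown cui: {cui}") from None

    def lookup(self, normalized_term: str) -> frozenset[str]:
        """CUIs for an exact normalized term; empty set if unindexed."""
        return self.term_index.get(normalized_term, frozenset())

    def stemmed_index(self) -> dict[str, frozenset[str]]:
        """Term index with every token Porter-stemmed (built lazily).

        Used by stemming-aware matching; distinct surface terms that stem to
        the same key have their CUI sets merged.
        """
        if self._stemmed_index is None:
            merged: dict[str, set[str]] = {}
            for term, cuis in self.term_index.items():
                key = " ".join(porter_stem(tok) for tok in term.split())
                merged.setdefault(key, set()).update(cuis)
            self._stemmed_index = {t: frozenset(c) for t, c in merged.items()}
        return self._stemmed_index


@dataclass(frozen=True)
class Blocklist:
    """Set of (normalized term, cui) mapping suppressions."""

    entries: frozenset[tuple[str, str]] = frozenset()

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Blocklist":
        return cls(frozenset((_norm_term(t), c) for t, c in pairs))


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

_LEXICON_COLUMNS = [
    "cui",
    "preferred_name",
    "synonyms",
    "semantic_types",
    "semantic_group",
    "parent_cuis",
]


def _split_multi(value) -> list[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return []
    return [part.strip() for part in str(value).split("|") if part.strip()]


def load_lexicon(path) -> Lexicon:
    """Load and validate a lexicon TSV.

    Raises :class:`LexiconError` on duplicate CUIs, on a concept listing more
    than one semantic group, or on a cycle in the parent hierarchy.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _LEXICON_COLUMNS if c not in frame.columns]
    if missing:
        raise LexiconError(f"lexicon file missing column(s): {missing}")

    concepts: dict[str, Concept] = {}
    for row in frame.itertuples(index=False):
        cui = row.cui.strip()
        if cui in concepts:
            raise LexiconError(f"duplicate cui: {cui}")
        groups = _split_multi(row.semantic_group)
        if len(groups) != 1:
            raise LexiconError(
                f"{cui}: expected exactly 1 semantic group, got {groups!r}"
            )
        terms = {row.preferred_name.strip()} | set(_split_multi(row.synonyms))
        concepts[cui] = Concept(
            cui=cui,
            preferred_name=row.preferred_name.strip(),
            terms=frozenset(t for t in terms if t),
            semantic_types=frozenset(_split_multi(row.semantic_types)),
            semantic_group=groups[0],
            parent_cuis=frozenset(_split_multi(row.parent_cuis)),
        )
    return Lexicon(concepts)


def load_blocklist(path) -> Blocklist:
    """Load a blocklist TSV with columns ``term`` and ``cui``."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("term", "cui"):
        if col not in frame.columns:
            raise LexiconError(f"blocklist file missing column: {col}")
    return Blocklist.from_pairs(
        (row.term, row.cui.strip()) for row in frame.itertuples(index=False)
    )


# ---------------------------------------------------------------------------
# Hierarchy and blocklist operations
# ---------------------------------------------------------------------------


def ancestors(lex: Lexicon, cui: str, depth: int | None = 1) -> set[Concept]:
    """Transitive parent concepts of ``cui`` up to ``depth`` levels.

    ``depth=None`` returns the full ancestor closure. The query concept is
    never part of the result; parents not present in the lexicon are skipped.
    """
    if cui not in lex.concepts:
        raise KeyError(f"unknown cui: {cui}")
    if depth is not None and depth < 0:
        raise ValueError("depth must be >= 0")
    result: set[str] = set()
    frontier = {cui}
    level = 0
    while frontier and (depth is None or level < depth):
        next_frontier: set[str] = set()
        for node in frontier:
            concept = lex.concepts.get(node)
            if concept is None:
                continue
            for parent in concept.parent_cuis:
                if parent in lex.concepts and parent not in result and parent != cui:
                    result.add(parent)
                    next_frontier.add(parent)
        frontier = next_frontier
        level += 1
    return {lex.concepts[c] for c in result}


def apply_blocklist(lex: Lexicon, bl: Blocklist) -> Lexicon:
    """Return a lexicon whose term index no longer maps blocked terms to
    their blocked CUIs.

    Concepts themselves are retained — their other terms still resolve.
    Blocklist entries naming a CUI absent from the lexicon are ignored with
    a warning. Idempotent.
    """
    blocked: dict[str, set[str]] = {}
    for term, cui in bl.entries:
        if cui not in lex.concepts:
            logger.warning("blocklist entry (%r, %s): cui not in lexicon; ignored", term, cui)
            continue
        blocked.setdefault(term, set()).add(cui)

    new_index = {
        term: (cuis - frozenset(blocked.get(term, ())))
        for term, cuis in lex.term_index.items()
    }
    return Lexicon(lex.concepts, term_index=new_index)
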