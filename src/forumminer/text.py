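"""Shared text normalization, stemming, and stopwords.

One normalization convention is used everywhere — lexicon term index,
annotator queries, and classifier features — so the matching and feature
spaces coincide. The stemmer is a self-contained Porter (1980) implementation
and the stopword list is frozen in this module, so that vocabularies built
from the same corpus are bit-stable across environments.
"""

from __future__ import annotations

import re

__all__ = ["normalize", "porter_stem", "STOPWORDS"]

_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def normalize(text: str) -> list[str]:
    """Lowercase, strip punctuation to token boundaries, split on whitespace.

    A total, deterministic function: any punctuation or symbol character acts
    as a token separator, so ``"I have a Headache!!"`` becomes
    ``["i", "have", "a", "headache"]`` and the empty string yields ``[]``.
    """
    if not text:
        return []
    return [tok for tok in _NON_ALNUM.split(text.lower()) if tok]


# ---------------------------------------------------------------------------
# Porter stemmer
# ---------------------------------------------------------------------------

_VOWELS = "aeiou"


def _is_cons(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of vowel→consonant transitions ("m" in Porter's notation)."""
    n = 0
    i = 0
    length = len(stem)
    while i < length and _is_cons(stem, i):
        i += 1
    while i < length:
        while i < length and not _is_cons(stem, i):
            i += 1
        if i >= length:
            break
        n += 1
        while i < length and _is_cons(stem, i):
            i += 1
    return n


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_cons(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    if not (
        _is_cons(word, len(word) - 3)
        and not _is_cons(word, len(word) - 2)
        and _is_cons(word, len(word) - 1)
    ):
        return False
    return word[-1] not in "wxy"


def _replace_suffix(word: str, suffix: str, repl: str, min_measure: int) -> str | None:
    """If word ends in suffix and the remaining stem has measure > min_measure,
    return the word with the suffix replaced; otherwise None."""
    if not word.endswith(suffix):
        return None
    stem = word[: len(word) - len(suffix)]
    if _measure(stem) > min_measure:
        return stem + repl
    return word  # suffix matched but condition failed: stop this step


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def porter_stem(word: str) -> str:
    """Stem a single lowercase token with the classic Porter algorithm."""
    if len(word) <= 2:
        return word
    w = word

    # Step 1a: plurals
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif not w.endswith("ss") and w.endswith("s"):
        w = w[:-1]

    # Step 1b: -ed / -ing
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    else:
        flag = False
        if w.endswith("ed") and _has_vowel(w[:-2]):
            w = w[:-2]
            flag = True
        elif w.endswith("ing") and _has_vowel(w[:-3]):
            w = w[:-3]
            flag = True
        if flag:
            if w.endswith(("at", "bl", "iz")):
                w += "e"
            elif _ends_double_cons(w) and w[-1] not in "lsz":
                w = w[:-1]
            elif _measure(w) == 1 and _ends_cvc(w):
                w += "e"

    # Step 1c: y → i
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"

    # Steps 2 and 3: derivational suffixes, longest match per step
    for table in (_STEP2, _STEP3):
        for suffix, repl in table:
            if w.endswith(suffix):
                stem = w[: len(w) - len(suffix)]
                if _measure(stem) > 0:
                    w = stem + repl
                break

    # Step 4: drop suffix when measure of the stem exceeds 1
    for suffix in _STEP4:
        if w.endswith(suffix):
            stem = w[: len(w) - len(suffix)]
            if suffix == "ion" and (not stem or stem[-1] not in "st"):
                break
            if _measure(stem) > 1:
                w = stem
            break

    # Step 5a: trailing e
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            w = stem

    # Step 5b: -ll → -l
    if _measure(w) > 1 and _ends_double_cons(w) and w.endswith("l"):
        w = w[:-1]

    return w


# A frozen, minimal English stopword list. Deliberately small: forum posts are
# short and over-aggressive stopword removal erases negations and modals that
# matter to health-sentiment classification.
STOPWORDS = frozenset(
    """
    a about above after again all am an and any are as at be because been
    before being below between both but by could did do does doing down
    during each few for from further had has have having he her here hers
    him his how i if in into is it its itself just me more most my myself
    of off on once only or other our ours out over own same she so some
    such than that the their theirs them then there these they this those
    through to too under until up very was we were what when where which
    while who whom why will with you your yours yourself
    """.split()
)
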