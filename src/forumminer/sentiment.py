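"""Three-class health-sentiment classification.

"Sentiment" here is health-outcome polarity, not emotional tone: Negative
posts report an adverse effect co-occurring with e-cigarette use, Positive
posts report a health improvement after switching from smoking, Neutral
posts express neither. The recipe: bag-of-n-grams features (lowercase,
stopword removal, Porter stemming, unigram–trigram, minimum total occurrence
count), optional augmentation of post text with ancestor-concept names,
oversampling of the minority Positive class in the training partition only,
and a Random Forest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .io import Post
from .lexicon import Lexicon, ancestors
from .annotator import Annotation
from .text import STOPWORDS, normalize, porter_stem

__all__ = [
    "LABELS",
    "LabeledPost",
    "VectorizerConfig",
    "EvalReport",
    "TrainPartition",
    "TestPartition",
    "build_vocabulary",
    "vectorize",
    "vectorize_corpus",
    "augment_ancestors",
    "oversample",
    "split",
    "train",
    "evaluate",
    "support_weighted_mean",
]

#: Closed label set, in fixed canonical order (used for confusion rows).
LABELS = ("Negative", "Neutral", "Positive")


@dataclass(frozen=True)
class LabeledPost:
    post: Post
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass(frozen=True)
class VectorizerConfig:
    """Feature-extraction settings.

    ``min_term_count`` is a TOTAL corpus occurrence threshold (an n-gram seen
    twice in one post and nowhere else is kept), not a document frequency.
    """

    lowercase: bool = True  # normalize() always lowercases; kept for config echo
    remove_stopwords: bool = True
    stem: bool = True
    min_term_count: int = 2
    ngram_range: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        lo, hi = self.ngram_range
        if lo > hi or lo < 1:
            raise ValueError("ngram_range must satisfy 1 <= low <= high")
        if self.min_term_count < 1:
            raise ValueError("min_term_count must be >= 1")


def _process_tokens(text: str, cfg: VectorizerConfig) -> list[str]:
    tokens = normalize(text)
    if cfg.remove_stopwords:
        tokens = [t for t in tokens if t not in STOPWORDS]
    if cfg.stem:
        tokens = [porter_stem(t) for t in tokens]
    return tokens


def _ngrams(tokens: Sequence[str], lo: int, hi: int) -> Iterable[str]:
    for n in range(lo, hi + 1):
        for i in range(len(tokens) - n + 1):
            yield " ".join(tokens[i : i + n])


def build_vocabulary(
    corpus: Sequence[LabeledPost], cfg: VectorizerConfig = VectorizerConfig()
) -> list[str]:
    """All n-grams whose total corpus occurrence count meets the threshold.

    Returned in lexicographic order so feature indices are deterministic.
    """
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    counts: dict[str, int] = {}
    lo, hi = cfg.ngram_range
    for lp in corpus:
        for gram in _ngrams(_process_tokens(lp.post.text, cfg), lo, hi):
            counts[gram] = counts.get(gram, 0) + 1
    return sorted(g for g, c in counts.items() if c >= cfg.min_term_count)


def vectorize(
    post: Post, vocab: Sequence[str], cfg: VectorizerConfig = VectorizerConfig()
) -> np.ndarray:
    """Term-count feature vector over ``vocab`` (out-of-vocabulary ignored)."""
    index = {term: i for i, term in enumerate(vocab)}
    vec = np.zeros(len(vocab), dtype=np.int64)
    lo, hi = cfg.ngram_range
    for gram in _ngrams(_process_tokens(post.text, cfg), lo, hi):
        j = index.get(gram)
        if j is not None:
            vec[j] += 1
    return vec


def vectorize_corpus(
    posts: Sequence[Post], vocab: Sequence[str], cfg: VectorizerConfig = VectorizerConfig()
) -> np.ndarray:
    """Stack of :func:`vectorize` rows, shape (n_posts, len(vocab))."""
    index = {term: i for i, term in enumerate(vocab)}
    mat = np.zeros((len(posts), len(vocab)), dtype=np.int64)
    lo, hi = cfg.ngram_range
    for r, post in enumerate(posts):
        for gram in _ngrams(_process_tokens(post.text, cfg), lo, hi):
            j = index.get(gram)
            if j is not None:
                mat[r, j] += 1
    return mat


def augment_ancestors(
    post: Post,
    ann: Sequence[Annotation],
    lex: Lexicon,
    depth: int | None = 1,
) -> Post:
    """Append ancestor-concept names to a post's text as extra features.

    For every annotated concept, the preferred names of its ancestors up to
    ``depth`` levels (``None`` = full closure) are appended, lowercased,
    deduplicated, in deterministic (CUI-sorted) order. The original text is
    preserved as a prefix; a post with no annotations is returned unchanged.
    This lets a classifier generalize across sibling conditions (a mention of
    pneumonia also contributes "disorder of lung").
    """
    if not ann:
        return post
    found: dict[str, str] = {}
    for a in ann:
        if a.cui not in lex.concepts:
            continue
        for anc in ancestors(lex, a.cui, depth=depth):
            found[anc.cui] = anc.preferred_name.lower()
    if not found:
        return post
    suffix = " ".join(found[cui] for cui in sorted(found))
    return post.with_text(post.text + " " + suffix)


class TrainPartition(list):
    """The training side of a split; the only input oversample accepts."""


class TestPartition(list):
    """The held-out side of a split; never oversampled."""

    __test__ = False  # not a pytest collection target


def split(
    data: Sequence[LabeledPost], n_train: int, n_test: int, seed: int
) -> tuple[TrainPartition, TestPartition]:
    """Seed-reproducible disjoint random partition of the required sizes."""
    if n_train + n_test > len(data):
        raise ValueError(
            f"requested {n_train}+{n_test} items from a corpus of {len(data)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(data))
    train = TrainPartition(data[i] for i in order[:n_train])
    test = TestPartition(data[i] for i in order[n_train : n_train + n_test])
    return train, test


def oversample(
    train: Sequence[LabeledPost],
    target: str,
    factor: float,
    seed: int,
) -> list[LabeledPost]:
    """Duplicate target-class posts so their count becomes round(n * factor).

    Every target post appears floor(factor) times; a seed-determined random
    subset appears once more to reach the rounded total. Non-target posts are
    untouched. The output order is shuffled by the seed. The test partition is
    rejected outright — rebalancing must never touch held-out data.
    """
    if isinstance(train, TestPartition):
        raise TypeError("oversample must not be applied to the test partition")
    if factor < 1:
        raise ValueError("oversample factor must be >= 1")
    targets = [lp for lp in train if lp.label == target]
    others = [lp for lp in train if lp.label != target]
    if not targets:
        raise ValueError(f"no posts of class {target!r} to oversample")

    n = len(targets)
    goal = round(n * factor)
    base = goal // n
    extra = goal - base * n
    rng = np.random.default_rng(seed)
    extra_idx = set(rng.choice(n, size=extra, replace=False)) if extra else set()
    out: list[LabeledPost] = list(others)
    for i, lp in enumerate(targets):
        out.extend([lp] * (base + (1 if i in extra_idx else 0)))
    rng.shuffle(out)  # in-place seeded shuffle of the python list
    return out


def train(
    X: np.ndarray,
    y: Sequence[str],
    seed: int = 0,
    n_trees: int = 100,
) -> RandomForestClassifier:
    """Fit the Random Forest sentiment classifier.

    The forest size and seed fully determine the model for fixed data.
    Raises on a single-class training set (nothing to discriminate).
    """
    if len(set(y)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    model.fit(np.asarray(X), np.asarray(y))
    return model


@dataclass
class EvalReport:
    """Per-class and support-weighted precision/recall/F plus confusion.

    ``confusion`` rows/columns follow :data:`LABELS` order (rows = true).
    Weighted metrics are support-weighted means of the per-class values;
    accuracy is the confusion-matrix trace over its total.
    """

    per_class: dict[str, dict[str, float]]
    weighted_precision: float
    weighted_recall: float
    weighted_f: float
    accuracy: float
    confusion: np.ndarray
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f": self.weighted_f,
            "accuracy": self.accuracy,
            "labels": list(LABELS),
            "confusion": self.confusion.tolist(),
            "config": self.config,
        }


def support_weighted_mean(values: Sequence[float], supports: Sequence[int]) -> float:
    """Mean of per-class values weighted by class supports."""
    total = sum(supports)
    if total == 0:
        raise ValueError("supports sum to zero")
    return float(sum(v * s for v, s in zip(values, supports, strict=True)) / total)


def evaluate(
    predictions: Sequence[tuple[str, str]], config: Mapping | None = None
) -> EvalReport:
    """Score (true, predicted) label pairs.

    Per-class precision = TP/(TP+FP), recall = TP/(TP+FN), F = 2PR/(P+R),
    with 0 where undefined.
    """
    if not predictions:
        raise ValueError("cannot evaluate an empty prediction list")
    y_true = [t for t, _ in predictions]
    y_pred = [p for _, p in predictions]
    bad = (set(y_true) | set(y_pred)) - set(LABELS)
    if bad:
        raise ValueError(f"labels outside {LABELS}: {sorted(bad)}")

    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=list(LABELS), zero_division=0
    )
    conf = confusion_matrix(y_true, y_pred, labels=list(LABELS))
    per_class = {
        label: {
            "precision": float(prec[i]),
            "recall": float(rec[i]),
            "f_measure": float(f1[i]),
            "support": int(support[i]),
        }
        for i, label in enumerate(LABELS)
    }
    return EvalReport(
        per_class=per_class,
        weighted_precision=support_weighted_mean(prec, support),
        weighted_recall=support_weighted_mean(rec, support),
        weighted_f=support_weighted_mean(f1, support),
        accuracy=float(np.trace(conf) / conf.sum()),
        confusion=conf,
        config=dict(config or {}),
    )
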