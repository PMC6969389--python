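from collections import Counter

import numpy as np
import pytest

from forumminer.annotator import annotate_post
from forumminer.io import Post
from forumminer.sentiment import (
    LABELS,
    LabeledPost,
    TestPartition,
    VectorizerConfig,
    augment_ancestors,
    build_vocabulary,
    evaluate,
    oversample,
    split,
    support_weighted_mean,
    train,
    vectorize,
    vectorize_corpus,
)
from forumminer.synthetic import GeneratorConfig, generate_corpus, labeled_posts
from forumminer.text import STOPWORDS, normalize, porter_stem

RAW = VectorizerConfig(remove_stopwords=False, stem=False, min_term_count=2,
                       ngram_range=(1, 1))


def lp(text, label="Neutral", pid="p"):
    return LabeledPost(post=Post(post_id=pid, text=text), label=label)


class TestVocabulary:
    def test_hand_counted_unigrams(self):
        corpus = [lp("vape good good"), lp("vape bad")]
        assert build_vocabulary(corpus, RAW) == ["good", "vape"]

    def test_min_count_one_keeps_everything(self):
        corpus = [lp("vape good good"), lp("vape bad")]
        cfg = VectorizerConfig(remove_stopwords=False, stem=False,
                               min_term_count=1, ngram_range=(1, 1))
        assert build_vocabulary(corpus, cfg) == ["bad", "good", "vape"]

    def test_empty_corpus_raises(self):
        with pytest.raises(ValueError):
            build_vocabulary([], RAW)

    def test_matches_brute_force_ngram_counter(self):
        rng = np.random.default_rng(3)
        words = ["vape", "coil", "good", "bad", "the", "throat", "dry"]
        corpus = [
            lp(" ".join(words[int(j)] for j in rng.integers(0, len(words), size=8)))
            for _ in range(30)
        ]
        cfg = VectorizerConfig(min_term_count=2, ngram_range=(1, 3))
        # independent counter applying the same published preprocessing recipe
        counts = Counter()
        for item in corpus:
            toks = [porter_stem(t) for t in normalize(item.post.text)
                    if t not in STOPWORDS]
            for n in (1, 2, 3):
                for i in range(len(toks) - n + 1):
                    counts[" ".join(toks[i:i + n])] += 1
        expected = sorted(g for g, c in counts.items() if c >= 2)
        assert build_vocabulary(corpus, cfg) == expected


class TestVectorize:
    def test_out_of_vocabulary_post_is_zero_vector(self):
        vec = vectorize(Post(post_id="p", text="completely unrelated"),
                        ["vape", "coil"], RAW)
        assert vec.tolist() == [0, 0]

    def test_single_vocab_term_is_one_hot(self):
        vec = vectorize(Post(post_id="p", text="vape"), ["coil", "vape"], RAW)
        assert vec.tolist() == [0, 1]

    def test_counts_match_sliding_window_oracle(self):
        rng = np.random.default_rng(9)
        words = ["dry", "throat", "vape", "coil", "good"]
        cfg = VectorizerConfig(remove_stopwords=False, stem=False,
                               min_term_count=1, ngram_range=(1, 2))
        posts = [
            Post(post_id=str(k),
                 text=" ".join(words[int(j)] for j in rng.integers(0, 5, size=10)))
            for k in range(20)
        ]
        vocab = build_vocabulary([LabeledPost(post=p, label="Neutral") for p in posts], cfg)
        mat = vectorize_corpus(posts, vocab, cfg)
        for r, post in enumerate(posts):
            toks = post.text.split()
            for c, term in enumerate(vocab):
                size = len(term.split())
                expected = sum(
                    1 for i in range(len(toks) - size + 1)
                    if " ".join(toks[i:i + size]) == term
                )
                assert mat[r, c] == expected
                assert vectorize(post, vocab, cfg)[c] == expected


class TestAugmentAncestors:
    def test_pneumonia_gains_disorder_of_lung(self, lex):
        post = Post(post_id="p", text="i think i have pneumonia")
        anns = annotate_post(post, lex)
        out = augment_ancestors(post, anns, lex, depth=1)
        assert out.text.startswith(post.text)
        assert out.text.endswith("disorder of lung")

    def test_no_annotations_is_identity(self, lex):
        post = Post(post_id="p", text="nothing medical here")
        assert augment_ancestors(post, [], lex) == post

    def test_shared_ancestor_appended_once(self, lex):
        from forumminer.lexicon import ancestors

        post = Post(post_id="p", text="pneumonia and bronchitis again")
        anns = annotate_post(post, lex)
        out = augment_ancestors(post, anns, lex, depth=1)
        # oracle: union of the two concepts' ancestor sets
        union = {
            c.preferred_name.lower()
            for cui in ("C0032285", "C0006277")
            for c in ancestors(lex, cui, depth=1)
        }
        suffix = out.text[len(post.text):].strip()
        assert {suffix} == union  # appended exactly once despite two children

    def test_augmentation_never_decreases_term_counts(self, lex):
        cfg = VectorizerConfig(min_term_count=1)
        posts, _ = generate_corpus(GeneratorConfig(n_posts=40, seed=2))
        for post in posts:
            anns = annotate_post(post, lex)
            augmented = augment_ancestors(post, anns, lex, depth=None)
            vocab = build_vocabulary([LabeledPost(post=post, label="Neutral")], cfg)
            before = vectorize(post, vocab, cfg)
            after = vectorize(augmented, vocab, cfg)
            assert (after >= before).all()


class TestOversample:
    def make(self, n_pos=67, n_other=233):
        data = [lp("pos", "Positive", f"P{i}") for i in range(n_pos)]
        data += [lp("neg", "Negative", f"N{i}") for i in range(n_other)]
        return data

    def test_positive_67_to_112(self):
        out = oversample(self.make(), "Positive", 112 / 67, seed=0)
        counts = Counter(item.label for item in out)
        assert counts["Positive"] == 112
        assert counts["Negative"] == 233

    def test_factor_one_is_multiset_identity(self):
        data = self.make(10, 20)
        out = oversample(data, "Positive", 1.0, seed=0)
        assert Counter((x.post.post_id, x.label) for x in out) == Counter(
            (x.post.post_id, x.label) for x in data
        )

    def test_fractional_factor_copy_counts(self):
        data = [lp("pos", "Positive", f"P{i}") for i in range(10)]
        out = oversample(data, "Positive", 2.5, seed=4)
        per_post = Counter(x.post.post_id for x in out)
        assert sum(per_post.values()) == 25
        assert set(per_post.values()) == {2, 3}
        assert sorted(per_post.values()).count(3) == 5

    def test_missing_class_raises(self):
        with pytest.raises(ValueError):
            oversample([lp("a", "Negative")], "Positive", 2.0, seed=0)

    def test_test_partition_rejected(self):
        part = TestPartition([lp("a", "Positive")])
        with pytest.raises(TypeError):
            oversample(part, "Positive", 2.0, seed=0)


class TestSplit:
    def test_paper_sized_partition(self):
        data = [lp("x", "Neutral", str(i)) for i in range(1080)]
        train_part, test_part = split(data, 962, 118, seed=1)
        assert len(train_part) == 962 and len(test_part) == 118
        assert not {x.post.post_id for x in train_part} & {
            x.post.post_id for x in test_part
        }

    def test_same_seed_reproduces(self):
        data = [lp("x", "Neutral", str(i)) for i in range(50)]
        assert split(data, 40, 10, seed=9) == split(data, 40, 10, seed=9)

    def test_disjoint_exhaustive_over_seeds(self):
        data = [lp("x", "Neutral", str(i)) for i in range(20)]
        for seed in range(100):
            tr, te = split(data, 15, 5, seed=seed)
            ids_tr = {x.post.post_id for x in tr}
            ids_te = {x.post.post_id for x in te}
            assert not ids_tr & ids_te
            assert len(ids_tr | ids_te) == 20

    def test_oversized_request_raises(self):
        with pytest.raises(ValueError):
            split([lp("x")], 1, 1, seed=0)


class TestTrainAndEvaluate:
    def test_separable_corpus_memorized(self):
        marker = {"Negative": "aaa", "Neutral": "bbb", "Positive": "ccc"}
        data = [lp(f"{marker[c]} text", c, f"{c}{i}")
                for c in LABELS for i in range(10)]
        cfg = VectorizerConfig(min_term_count=1)
        vocab = build_vocabulary(data, cfg)
        X = vectorize_corpus([d.post for d in data], vocab, cfg)
        model = train(X, [d.label for d in data], seed=0)
        assert (model.predict(X) == np.array([d.label for d in data])).all()

    def test_seeded_determinism(self):
        posts, truth = generate_corpus(GeneratorConfig(n_posts=120, seed=6))
        data = labeled_posts(posts, truth)
        cfg = VectorizerConfig()
        vocab = build_vocabulary(data, cfg)
        X = vectorize_corpus([d.post for d in data], vocab, cfg)
        y = [d.label for d in data]
        p1 = train(X[:100], y[:100], seed=3).predict(X[100:])
        p2 = train(X[:100], y[:100], seed=3).predict(X[100:])
        assert (p1 == p2).all()

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            train(np.zeros((3, 2)), ["Neutral"] * 3, seed=0)

    def test_marker_mode_holdout_accuracy(self):
        cfg = GeneratorConfig(n_posts=200, seed=7, marker_mode=True)
        posts, truth = generate_corpus(cfg)
        data = labeled_posts(posts, truth)
        tr, te = split(data, 160, 40, seed=7)
        vcfg = VectorizerConfig()
        vocab = build_vocabulary(list(tr), vcfg)
        model = train(
            vectorize_corpus([d.post for d in tr], vocab, vcfg),
            [d.label for d in tr], seed=7,
        )
        pred = model.predict(vectorize_corpus([d.post for d in te], vocab, vcfg))
        acc = float((pred == np.array([d.label for d in te])).mean())
        assert acc >= 0.95


class TestEvaluate:
    def test_all_correct(self):
        report = evaluate([(c, c) for c in LABELS for _ in range(4)])
        assert report.accuracy == 1.0
        for stats in report.per_class.values():
            assert stats["precision"] == stats["recall"] == stats["f_measure"] == 1.0

    def test_weighted_metrics_from_printed_per_class_rows(self):
        # support-weighted averages over (Positive, Neutral, Negative) rows
        assert round(support_weighted_mean([0.73, 0.67, 0.84], [21, 39, 58]), 2) == 0.76
        assert round(support_weighted_mean([0.72, 0.77, 0.74], [21, 39, 58]), 2) == 0.75

    def test_metrics_match_direct_counting_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            pairs = [
                (LABELS[int(rng.integers(3))], LABELS[int(rng.integers(3))])
                for _ in range(int(rng.integers(10, 60)))
            ]
            report = evaluate(pairs)
            for label in LABELS:
                tp = sum(1 for t, p in pairs if t == label and p == label)
                fp = sum(1 for t, p in pairs if t != label and p == label)
                fn = sum(1 for t, p in pairs if t == label and p != label)
                prec = tp / (tp + fp) if tp + fp else 0.0
                rec = tp / (tp + fn) if tp + fn else 0.0
                f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
                stats = report.per_class[label]
                assert stats["precision"] == pytest.approx(prec, abs=1e-12)
                assert stats["recall"] == pytest.approx(rec, abs=1e-12)
                assert stats["f_measure"] == pytest.approx(f, abs=1e-12)
                assert stats["support"] == tp + fn
            assert report.accuracy == pytest.approx(
                sum(1 for t, p in pairs if t == p) / len(pairs)
            )

    def test_confusion_row_sums_equal_supports(self):
        rng = np.random.default_rng(1)
        pairs = [(LABELS[int(rng.integers(3))], LABELS[int(rng.integers(3))])
                 for _ in range(80)]
        report = evaluate(pairs)
        for i, label in enumerate(LABELS):
            assert report.confusion[i].sum() == report.per_class[label]["support"]

    def test_weighted_recall_equals_micro_accuracy(self):
        # support-weighted recall is algebraically the confusion trace / total
        rng = np.random.default_rng(2)
        pairs = [(LABELS[int(rng.integers(3))], LABELS[int(rng.integers(3))])
                 for _ in range(120)]
        report = evaluate(pairs)
        assert report.weighted_recall == pytest.approx(report.accuracy, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            evaluate([])


class TestAncestorAugmentationProperty:
    def test_augmentation_improves_positive_recall_majority_of_seeds(self, lex):
        from forumminer.synthetic import generate_ancestor_probe

        wins = 0
        for seed in range(5):
            tr, te = generate_ancestor_probe(seed)
            recalls = {}
            for augment in (False, True):
                def prep(items):
                    out = []
                    for item in items:
                        post = item.post
                        if augment:
                            anns = annotate_post(post, lex)
                            post = augment_ancestors(post, anns, lex, depth=1)
                        out.append(LabeledPost(post=post, label=item.label))
                    return out

                tr_a, te_a = prep(tr), prep(te)
                vcfg = VectorizerConfig()
                vocab = build_vocabulary(tr_a, vcfg)
                model = train(
                    vectorize_corpus([d.post for d in tr_a], vocab, vcfg),
                    [d.label for d in tr_a], seed=seed,
                )
                pred = model.predict(
                    vectorize_corpus([d.post for d in te_a], vocab, vcfg)
                )
                truth = np.array([d.label for d in te_a])
                pos = truth == "Positive"
                recalls[augment] = float((pred[pos] == "Positive").mean())
            if recalls[True] > recalls[False]:
                wins += 1
        assert wins >= 3
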