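"""Synthetic forum corpora and fixture vocabulary with known ground truth.

Nothing in this module is real forum text or a real vocabulary excerpt: the
fixture lexicon, taxonomy and blocklist are synthetic, hand-curated to cover
the conditions this kind of e-cigarette health-effect mining encounters —
about a hundred symptom/disorder concepts spanning all twelve organ systems,
multi-word terms, a parent chain several levels deep, and the three forum
slang homographs ("mod", "ect", "pic") that collide with medical vocabulary
entries. Generated posts use intentionally simple templates: the point is
structural fidelity (class mixture, embedded concepts, homograph noise,
timestamps), not linguistic realism, so that every pipeline stage can be
checked against exact generator bookkeeping.
"""

from __future__ import annotations

import datetime as _dt
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Post
from .lexicon import Blocklist, Lexicon, load_blocklist, load_lexicon
from .categorizer import DEFAULT_SYSTEMS, SystemTaxonomy, load_taxonomy
from .sentiment import LABELS, LabeledPost

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_corpus",
    "generate_ancestor_probe",
    "write_fixtures",
    "fixture_lexicon",
    "fixture_blocklist",
    "fixture_taxonomy",
    "fixture_lexicon_tsv",
    "fixture_blocklist_tsv",
    "fixture_taxonomy_tsv",
    "HOMOGRAPHS",
]

# ---------------------------------------------------------------------------
# Fixture vocabulary (synthetic)
# ---------------------------------------------------------------------------

_SYM = "Sign or Symptom"
_DIS = "Disease or Syndrome"
_GROUP = {_SYM: "Symptoms", _DIS: "Disorders"}

#: Forum-slang homograph token -> CUI its surface form collides with.
HOMOGRAPHS = {"mod": "C0011860", "ect": "C2363129", "pic": "C0730321"}

# (cui, preferred_name, synonyms, semantic_type, system, parent_cuis)
# CUIs printed in the source analyses are kept verbatim; the rest are
# synthetic C-codes. Every surface term is unique to one concept so that
# generator bookkeeping equals annotator output exactly.
_CONCEPTS: list[tuple[str, str, list[str], str, str, list[str]]] = [
    # --- neurological ---
    ("C0018681", "Headache", ["headaches"], _SYM, "neurological", ["C0018546"]),
    ("C0015672", "Fatigue", ["tiredness", "malaise"], _SYM, "neurological", []),
    ("C0027497", "Nausea", ["queasiness"], _SYM, "neurological", []),
    ("C0012833", "Dizziness", ["dizzy spells"], _SYM, "neurological", []),
    ("C0023380", "Lightheadedness", [], _SYM, "neurological", []),
    ("C0917801", "Insomnia", ["sleeplessness"], _SYM, "neurological", []),
    ("C0022107", "Irritability", [], _SYM, "neurological", []),
    ("C0003467", "Anxiety", ["jitters"], _SYM, "neurological", []),
    ("C0233794", "Memory impairment", ["brain fog"], _SYM, "neurological", []),
    ("C0011175", "Dehydration", [], _DIS, "neurological", []),
    ("C0149931", "Migraine", ["migraines"], _DIS, "neurological", ["C0018546"]),
    ("C2363129", "Benign Rolandic epilepsy", ["ect"], _DIS, "neurological", ["C0014544"]),
    ("C0014544", "Epilepsy", [], _DIS, "neurological", []),
    ("C0042571", "Vertigo", [], _DIS, "neurological", []),
    ("C0018546", "Headache disorder", [], _DIS, "neurological", []),
    # --- respiratory ---
    ("C0010200", "Coughing", ["cough", "coughs"], _SYM, "respiratory", []),
    ("C0043144", "Wheezing", ["wheeze"], _SYM, "respiratory", []),
    ("C0013404", "Dyspnea", ["shortness of breath", "breathlessness"], _SYM, "respiratory", []),
    ("C0020672", "Hyperventilation", ["excessively deep breathing"], _SYM, "respiratory", []),
    ("C0239134", "Productive cough", ["phlegmy cough"], _SYM, "respiratory", []),
    ("C0037383", "Sneezing", ["sneeze"], _SYM, "respiratory", []),
    ("C0004096", "Asthma", [], _DIS, "respiratory", ["C0024115"]),
    ("C0024117", "Chronic obstructive pulmonary disease", ["copd"], _DIS, "respiratory", ["C0024115"]),
    ("C0032285", "Pneumonia", [], _DIS, "respiratory", ["C0024115"]),
    ("C0006277", "Bronchitis", [], _DIS, "respiratory", ["C0024115"]),
    ("C0024109", "Lung infection", [], _DIS, "respiratory", ["C0024115"]),
    ("C0024115", "Disorder of lung", [], _DIS, "respiratory", ["C0035204"]),
    ("C0035204", "Respiratory tract disorder", [], _DIS, "respiratory", ["C0012634"]),
    # --- digestive ---
    ("C0018834", "Heartburn", [], _SYM, "digestive", []),
    ("C0026821", "Cramping", ["cramp", "cramps"], _SYM, "digestive", []),
    ("C0016204", "Flatulence", ["flatus"], _SYM, "digestive", []),
    ("C0009806", "Constipation", [], _SYM, "digestive", []),
    ("C0011991", "Diarrhea", [], _SYM, "digestive", []),
    ("C0000737", "Abdominal pain", ["stomach ache"], _SYM, "digestive", []),
    ("C0232602", "Bloating", [], _SYM, "digestive", []),
    ("C0017152", "Gastritis", [], _DIS, "digestive", []),
    ("C0022104", "Irritable bowel syndrome", ["ibs"], _DIS, "digestive", []),
    ("C0030920", "Peptic ulcer", [], _DIS, "digestive", []),
    # --- mouth and throat ---
    ("C0242429", "Pain in throat", ["sore throat", "throat pain"], _SYM, "mouth and throat", []),
    ("C0019825", "Hoarseness", ["harsh voice quality"], _SYM, "mouth and throat", []),
    ("C0241934", "Pharyngeal dryness", ["dry throat"], _SYM, "mouth and throat", []),
    ("C0018520", "Halitosis", ["bad breath"], _SYM, "mouth and throat", []),
    ("C0030193", "Mouth pain", [], _SYM, "mouth and throat", []),
    ("C0031350", "Pharyngitis", [], _DIS, "mouth and throat", []),
    ("C0043352", "Aptyalism", ["dry mouth"], _DIS, "mouth and throat", []),
    ("C0026639", "Ulcer of mouth", ["mouth ulcer", "mouth sores"], _DIS, "mouth and throat", []),
    ("C0017563", "Gingivitis", ["sore gums"], _DIS, "mouth and throat", []),
    # --- integumentary ---
    ("C0033774", "Itching", ["pruritus", "itchy skin"], _SYM, "integumentary", []),
    ("C0151908", "Dry skin", ["skin dryness"], _SYM, "integumentary", []),
    ("C0015230", "Rash", ["skin rash"], _SYM, "integumentary", []),
    ("C0237849", "Flaking skin", ["peeling skin"], _SYM, "integumentary", []),
    ("C0001144", "Acne", [], _DIS, "integumentary", []),
    ("C0013595", "Eczema", [], _DIS, "integumentary", []),
    ("C0011603", "Dermatitis", [], _DIS, "integumentary", []),
    ("C0033860", "Psoriasis", [], _DIS, "integumentary", []),
    # --- immune ---
    ("C0015967", "Fever", ["high temperature"], _SYM, "immune", []),
    ("C0085593", "Chills", ["shivering"], _SYM, "immune", []),
    ("C0497156", "Lymphadenopathy", ["swollen glands"], _SYM, "immune", []),
    ("C0009443", "Common cold", ["head cold"], _DIS, "immune", []),
    ("C0021400", "Influenza", ["flu"], _DIS, "immune", []),
    ("C0020517", "Allergy", ["allergies", "allergic reaction"], _DIS, "immune", []),
    ("C0037199", "Sinusitis", [], _DIS, "immune", []),
    # --- circulatory ---
    ("C0030252", "Palpitations", ["heart palpitations"], _SYM, "circulatory", []),
    ("C0039231", "Tachycardia", ["racing heart"], _SYM, "circulatory", []),
    ("C0016382", "Flushing", [], _SYM, "circulatory", []),
    ("C0020538", "Hypertension", ["high blood pressure"], _DIS, "circulatory", []),
    ("C0002871", "Anemia", [], _DIS, "circulatory", []),
    ("C0018799", "Heart disease", [], _DIS, "circulatory", ["C0012634"]),
    # --- endocrine ---
    ("C0085602", "Polydipsia", ["increased thirst", "excessive thirst"], _SYM, "endocrine", []),
    ("C0038990", "Sweating", ["sweats"], _SYM, "endocrine", []),
    ("C0232461", "Increased appetite", [], _SYM, "endocrine", []),
    ("C0011860", "Type 2 diabetes mellitus", ["mod", "type 2 diabetes", "diabetes"], _DIS, "endocrine", ["C0011849"]),
    ("C0020615", "Hypoglycemia", ["low blood sugar"], _DIS, "endocrine", []),
    ("C0040128", "Thyroid disease", ["thyroid disorder"], _DIS, "endocrine", ["C0014130"]),
    ("C0011849", "Diabetes mellitus", [], _DIS, "endocrine", ["C0014130"]),
    ("C0014130", "Endocrine system disease", [], _DIS, "endocrine", ["C0012634"]),
    # --- muscular/skeletal ---
    ("C0231528", "Myalgia", ["muscle ache", "muscle aches", "sore muscles"], _SYM, "muscular/skeletal", []),
    ("C0003862", "Arthralgia", ["joint pain", "aching joints"], _SYM, "muscular/skeletal", []),
    ("C0004604", "Back pain", ["backache"], _SYM, "muscular/skeletal", []),
    ("C0231530", "Muscle twitching", [], _SYM, "muscular/skeletal", []),
    ("C0003864", "Arthritis", [], _DIS, "muscular/skeletal", []),
    ("C0016053", "Fibromyalgia", [], _DIS, "muscular/skeletal", []),
    # --- sensory ---
    ("C0013119", "Dysgeusia", ["altered taste"], _SYM, "sensory", []),
    ("C5200001", "Improved sense of taste", [], _SYM, "sensory", []),
    ("C0040264", "Tinnitus", ["ringing ears"], _SYM, "sensory", []),
    ("C0344232", "Blurred vision", [], _SYM, "sensory", []),
    ("C0013238", "Dry eyes", [], _SYM, "sensory", []),
    ("C0730321", "Punctate inner choroidopathy", ["pic"], _DIS, "sensory", []),
    ("C0009763", "Conjunctivitis", ["pink eye"], _DIS, "sensory", []),
    # --- chest ---
    ("C0008031", "Chest pain", ["chest pains", "pain in chest"], _SYM, "chest", []),
    ("C0232292", "Chest tightness", ["tight chest"], _SYM, "chest", []),
    ("C0002962", "Angina pectoris", ["angina"], _DIS, "chest", ["C0018799"]),
    ("C0032231", "Pleurisy", [], _DIS, "chest", []),
    # --- whole body/other ---
    ("C0043096", "Weight loss", [], _SYM, "whole body/other", []),
    ("C0043094", "Weight gain", [], _SYM, "whole body/other", []),
    ("C3714552", "Weakness", ["feeling weak"], _SYM, "whole body/other", []),
    ("C0392680", "Shakiness", ["trembling"], _SYM, "whole body/other", []),
    ("C0281856", "Body aches", [], _SYM, "whole body/other", []),
    ("C0015674", "Chronic fatigue syndrome", [], _DIS, "whole body/other", ["C0012634"]),
    ("C0028043", "Nicotine dependence", [], _DIS, "whole body/other", []),
    ("C0012634", "Disease", [], _DIS, "whole body/other", []),
]

#: CUIs that exist only as hierarchy ancestors; never embedded in posts so
#: that ancestor augmentation adds genuinely new text.
_ANCESTOR_ONLY = {
    "C0018546", "C0014544", "C0024115", "C0035204", "C0012634",
    "C0011849", "C0014130", "C0018799",
}

_CUI_SYSTEM = {c[0]: c[4] for c in _CONCEPTS}
_CUI_GROUP = {c[0]: _GROUP[c[3]] for c in _CONCEPTS}
_CUI_NAME = {c[0]: c[1] for c in _CONCEPTS}


def fixture_lexicon_tsv() -> str:
    """The synthetic fixture vocabulary as lexicon-TSV text."""
    lines = ["cui\tpreferred_name\tsynonyms\tsemantic_types\tsemantic_group\tparent_cuis"]
    for cui, name, syns, stype, _system, parents in _CONCEPTS:
        lines.append(
            "\t".join([cui, name, "|".join(syns), stype, _GROUP[stype], "|".join(parents)])
        )
    return "\n".join(lines) + "\n"


def fixture_blocklist_tsv() -> str:
    """Blocklist TSV suppressing the three slang homograph mappings."""
    lines = ["term\tcui"]
    for term, cui in sorted(HOMOGRAPHS.items()):
        lines.append(f"{term}\t{cui}")
    return "\n".join(lines) + "\n"


def fixture_taxonomy_tsv() -> str:
    """Taxonomy TSV mapping every fixture CUI to one of the 12 systems.

    One concept (improved sense of taste) is listed under two candidate
    systems to exercise strongest-fit resolution: its sensory row carries the
    stronger (lower) rank, so it resolves to sensory rather than mouth and
    throat.
    """
    lines = ["cui\tsystem\tpriority"]
    for cui, _name, _syns, _stype, system, _parents in _CONCEPTS:
        lines.append(f"{cui}\t{system}\t1")
        if cui == "C5200001":
            lines.append(f"{cui}\tmouth and throat\t2")
    return "\n".join(lines) + "\n"


def fixture_lexicon() -> Lexicon:
    return load_lexicon(_io.StringIO(fixture_lexicon_tsv()))


def fixture_blocklist() -> Blocklist:
    return load_blocklist(_io.StringIO(fixture_blocklist_tsv()))


def fixture_taxonomy() -> SystemTaxonomy:
    return load_taxonomy(_io.StringIO(fixture_taxonomy_tsv()))


def write_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write lexicon/blocklist/taxonomy TSVs; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "lexicon": out / "lexicon.tsv",
        "blocklist": out / "blocklist.tsv",
        "taxonomy": out / "taxonomy.tsv",
    }
    paths["lexicon"].write_text(fixture_lexicon_tsv(), encoding="utf-8")
    paths["blocklist"].write_text(fixture_blocklist_tsv(), encoding="utf-8")
    paths["taxonomy"].write_text(fixture_taxonomy_tsv(), encoding="utf-8")
    return paths


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

#: Class mixture of the manual pilot labeling this generator emulates.
DEFAULT_CLASS_MIX = {"Negative": 0.4475, "Neutral": 0.3850, "Positive": 0.1675}

_NEG_TEMPLATES = (
    "i have been getting {} every night since i started vaping",
    "my {} will not go away and it keeps getting worse",
    "anyone else get {} when using this juice",
    "i keep getting {} after longer vaping sessions",
)
_POS_TEMPLATES = (
    "my {} got so much better after switching to vaping",
    "no more {} since i quit smoking analogs",
    "i noticed my {} is basically gone after i switched over",
)
_NEU_TEMPLATES = (
    "anyone tried the new {0} {1} setup yet",
    "just ordered a {0} {1} and the shipping was fast",
    "what wattage do you run on the {0} {1}",
    "thinking about a {0} {1} for my next build",
)

_FILLER_BASE = (
    "coil", "tank", "battery", "wattage", "juice", "flavor", "atomizer",
    "drip", "tip", "starter", "kit", "bottle", "nic", "level", "menthol",
    "vanilla", "custard", "steeping", "resistance", "ohm", "cotton", "wick",
    "clone", "authentic", "vendor", "sale", "review", "thread", "build",
    "charger",
)

_MARKERS = {"Negative": "qversetoken", "Neutral": "qmiddletoken", "Positive": "qupliftoken"}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic corpus.

    Defaults mirror the manual-labeling class mixture (Negative 44.75%,
    Neutral 38.50%, Positive 16.75%) over the 2008–mid-2015 collection
    window; negative posts embed 1–3 conditions; a tenth of posts carry one
    slang homograph token.
    """

    n_posts: int = 1000
    seed: int = 0
    class_mix: tuple[tuple[str, float], ...] = tuple(sorted(DEFAULT_CLASS_MIX.items()))
    date_range: tuple[_dt.date, _dt.date] = (_dt.date(2008, 1, 1), _dt.date(2015, 6, 30))
    concepts_per_negative_post: tuple[int, int] = (1, 3)
    homograph_noise_rate: float = 0.1
    filler_vocab_size: int = 30
    marker_mode: bool = False

    def __post_init__(self) -> None:
        mix = dict(self.class_mix)
        if set(mix) != set(LABELS):
            raise ValueError(f"class_mix must cover exactly {LABELS}")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if self.n_posts < 0:
            raise ValueError("n_posts must be >= 0")
        if not 0 <= self.homograph_noise_rate <= 1:
            raise ValueError("homograph_noise_rate must be in [0, 1]")
        lo, hi = self.concepts_per_negative_post
        if not 1 <= lo <= hi:
            raise ValueError("concepts_per_negative_post must satisfy 1 <= lo <= hi")


@dataclass
class GroundTruth:
    """Per-post generator bookkeeping plus exact corpus-level aggregations."""

    per_post: dict[str, dict] = field(default_factory=dict)

    def add(self, post_id: str, sentiment: str, cuis: list[str], year: int | None) -> None:
        self.per_post[post_id] = {"sentiment": sentiment, "cuis": cuis, "year": year}

    def concept_table(self) -> pd.DataFrame:
        """Distinct posts per embedded CUI, descending, ties by CUI."""
        counts: dict[str, int] = {}
        for rec in self.per_post.values():
            for cui in set(rec["cuis"]):
                counts[cui] = counts.get(cui, 0) + 1
        rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(rows, columns=["cui", "post_count"])

    def system_table(self, group: str) -> pd.DataFrame:
        """(system, sentiment, year, post_count) for one semantic group."""
        counts: dict[tuple[str, str, int], int] = {}
        for rec in self.per_post.values():
            if rec["year"] is None:
                continue
            for cui in set(rec["cuis"]):
                if _CUI_GROUP.get(cui) != group:
                    continue
                key = (_CUI_SYSTEM[cui], rec["sentiment"], rec["year"])
                counts[key] = counts.get(key, 0) + 1
        rows = [
            {"key": k[0], "sentiment": k[1], "year": k[2], "post_count": c}
            for k, c in sorted(counts.items())
        ]
        return pd.DataFrame(rows, columns=["key", "sentiment", "year", "post_count"])

    def pair_table(self, group: str = "Symptoms") -> pd.DataFrame:
        """Unordered within-post concept pairs for one semantic group."""
        counts: dict[tuple[str, str], int] = {}
        for rec in self.per_post.values():
            cuis = sorted({c for c in rec["cuis"] if _CUI_GROUP.get(c) == group})
            for i in range(len(cuis)):
                for j in range(i + 1, len(cuis)):
                    pair = (cuis[i], cuis[j])
                    counts[pair] = counts.get(pair, 0) + 1
        rows = [
            {"cui_a": a, "cui_b": b, "post_count": c}
            for (a, b), c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        return pd.DataFrame(rows, columns=["cui_a", "cui_b", "post_count"])

    def labels(self) -> dict[str, str]:
        return {pid: rec["sentiment"] for pid, rec in self.per_post.items()}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.per_post, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(per_post=json.load(fh))


def _filler_vocab(size: int) -> list[str]:
    vocab = list(_FILLER_BASE[:size])
    vocab += [f"gadget{i}" for i in range(len(vocab), size)]
    return vocab


def _embed_term(cui: str) -> str:
    return _CUI_NAME[cui].lower()


def generate_corpus(cfg: GeneratorConfig) -> tuple[list[Post], GroundTruth]:
    """Generate a seed-reproducible corpus with exact ground truth.

    Negative posts embed 1–k conditions in complaint templates, Positive
    posts embed one condition in an improvement/switching template, Neutral
    posts contain gear talk only. Homograph tokens are prepended/appended at
    the configured rate in every class and are never part of the ground
    truth. Timestamps are uniform over the date range. The same config and
    seed always produce byte-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    mix = dict(cfg.class_mix)
    classes = sorted(mix)
    probs = [mix[c] for c in classes]
    labels = rng.choice(classes, size=cfg.n_posts, p=probs) if cfg.n_posts else []

    pool = sorted(cui for cui in _CUI_SYSTEM if cui not in _ANCESTOR_ONLY)
    filler = _filler_vocab(cfg.filler_vocab_size)
    start, end = cfg.date_range
    n_days = (end - start).days + 1
    homographs = sorted(HOMOGRAPHS)

    posts: list[Post] = []
    truth = GroundTruth()
    for i in range(cfg.n_posts):
        label = str(labels[i])
        date = start + _dt.timedelta(days=int(rng.integers(n_days)))
        cuis: list[str] = []
        if label == "Negative":
            lo, hi = cfg.concepts_per_negative_post
            k = int(rng.integers(lo, hi + 1))
            cuis = [pool[j] for j in rng.choice(len(pool), size=k, replace=False)]
            slot = " and also ".join(_embed_term(c) for c in cuis)
            text = _NEG_TEMPLATES[int(rng.integers(len(_NEG_TEMPLATES)))].format(slot)
        elif label == "Positive":
            cuis = [pool[int(rng.integers(len(pool)))]]
            text = _POS_TEMPLATES[int(rng.integers(len(_POS_TEMPLATES)))].format(
                _embed_term(cuis[0])
            )
        else:
            w1, w2 = (filler[int(j)] for j in rng.choice(len(filler), size=2, replace=False))
            text = _NEU_TEMPLATES[int(rng.integers(len(_NEU_TEMPLATES)))].format(w1, w2)

        if rng.random() < cfg.homograph_noise_rate:
            tok = homographs[int(rng.integers(len(homographs)))]
            # Prepend or append only: noise must never split an embedded term.
            text = f"{tok} {text}" if rng.random() < 0.5 else f"{text} {tok}"
        if cfg.marker_mode:
            text = f"{text} {_MARKERS[label]}"

        post_id = f"p{i:06d}"
        posts.append(
            Post(
                post_id=post_id,
                thread_id=f"t{int(rng.integers(200)):04d}",
                subforum="health",
                timestamp=date,
                text=text,
            )
        )
        truth.add(post_id, label, cuis, date.year)
    return posts, truth


def labeled_posts(posts: list[Post], truth: GroundTruth) -> list[LabeledPost]:
    """Join generated posts with their ground-truth sentiment labels."""
    labels = truth.labels()
    return [LabeledPost(post=p, label=labels[p.post_id]) for p in posts]


# ---------------------------------------------------------------------------
# Ancestor-probe corpus
# ---------------------------------------------------------------------------

#: Lung-disorder children used by the probe. Train Positive posts spread over
#: several children so no single surface term separates the class (the shared
#: ancestor is then the dominant signal); test Positive posts use different
#: children, so train and test share no condition surface form — only the
#: common ancestor.
_PROBE_TRAIN_POS = ("C0032285", "C0004096", "C0024117")  # pneumonia, asthma, COPD
_PROBE_TEST_POS = ("C0006277", "C0024109")               # bronchitis, lung infection
_PROBE_NEG = ("C0018681",)                    # headache (parent: headache disorder)

_PROBE_TEMPLATE = "been dealing with {} a lot lately not sure what to make of it"


def generate_ancestor_probe(
    seed: int,
    n_train: tuple[int, int, int] = (40, 30, 15),
    n_test: tuple[int, int, int] = (20, 15, 10),
) -> tuple[list[LabeledPost], list[LabeledPost]]:
    """Corpus design isolating the value of ancestor augmentation.

    All classes share one neutral template; the only signal is the condition
    word. Positive conditions are disjoint between train and test but share
    the ancestor "Disorder of lung", so without augmentation a classifier
    cannot recognize held-out Positive posts, while with augmentation the
    appended ancestor name carries the class. Class sizes follow the
    Negative-heavy mixture (``n_*`` are (Negative, Neutral, Positive)
    counts) so ambiguous posts default away from Positive.
    """
    rng = np.random.default_rng(seed)
    filler = _filler_vocab(20)

    def build(counts: tuple[int, int, int], pos_pool: tuple[str, ...], tag: str) -> list[LabeledPost]:
        out: list[LabeledPost] = []
        n_neg, n_neu, n_pos = counts
        specs = (
            [("Negative", _PROBE_NEG)] * n_neg
            + [("Neutral", None)] * n_neu
            + [("Positive", pos_pool)] * n_pos
        )
        for i, (label, cui_pool) in enumerate(specs):
            if cui_pool is None:
                slot = filler[int(rng.integers(len(filler)))]
            else:
                slot = _embed_term(cui_pool[int(rng.integers(len(cui_pool)))])
            extra = filler[int(rng.integers(len(filler)))]
            text = _PROBE_TEMPLATE.format(slot) + " " + extra
            post = Post(
                post_id=f"{tag}{i:04d}",
                subforum="health",
                timestamp=_dt.date(2012, 6, 1),
                text=text,
            )
            out.append(LabeledPost(post=post, label=label))
        return out

    return build(n_train, _PROBE_TRAIN_POS, "tr"), build(n_test, _PROBE_TEST_POS, "te")
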