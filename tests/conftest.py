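import io

import pytest

from forumminer.lexicon import (
    Blocklist,
    Concept,
    Lexicon,
    apply_blocklist,
    load_lexicon,
)
from forumminer.synthetic import fixture_blocklist, fixture_lexicon, fixture_taxonomy


@pytest.fixture(scope="session")
def lex():
    return fixture_lexicon()


@pytest.fixture(scope="session")
def blocked_lex():
    return apply_blocklist(fixture_lexicon(), fixture_blocklist())


@pytest.fixture(scope="session")
def bl():
    return fixture_blocklist()


@pytest.fixture(scope="session")
def tax():
    return fixture_taxonomy()


def make_lexicon(rows):
    """Build a Lexicon from (cui, name, synonyms, stype, group, parents) rows."""
    concepts = {}
    for cui, name, syns, stype, group, parents in rows:
        concepts[cui] = Concept(
            cui=cui,
            preferred_name=name,
            terms=frozenset([name, *syns]),
            semantic_types=frozenset([stype]),
            semantic_group=group,
            parent_cuis=frozenset(parents),
        )
    return Lexicon(concepts)


def lexicon_from_tsv(text):
    return load_lexicon(io.StringIO(text))
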