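import pytest

from bioevent.candidates import (
    TriggerDictionary,
    generate_pairs,
    generate_triplets,
    label_candidates,
)
from bioevent.pipeline import load_corpus
from bioevent.synth import generate_fixture_corpus

# Table-like worked example database (six dependency-label sequences)
WORKED_DB = [
    ("amod", "prep_to", "prep_in", "nn"),
    ("prep_to", "nn", "prep_in"),
    ("amod", "nn"),
    ("prep_to", "dobj", "prep_in", "nn"),
    ("dobj", "amod", "prep_to", "nn"),
    ("prep_to", "nn"),
]


@pytest.fixture(scope="session")
def small_corpus_dir(tmp_path_factory):
    """A 30-document synthetic corpus at the canonical 1:13.163 imbalance."""
    out = tmp_path_factory.mktemp("corpus") / "small"
    generate_fixture_corpus(str(out), n_docs=30, imbalance=13.163, seed=1)
    return str(out)


@pytest.fixture(scope="session")
def small_docs(small_corpus_dir):
    return load_corpus(small_corpus_dir, with_events=True)


@pytest.fixture(scope="session")
def small_candidates(small_docs):
    """(tdict, labelled pairs, labelled triplets) over the small corpus."""
    tdict = TriggerDictionary.from_documents(small_docs)
    pairs, triplets = [], []
    for doc in small_docs:
        for sent in doc.sentences:
            p = generate_pairs(doc, sent, tdict)
            t = generate_triplets(doc, sent, tdict)
            label_candidates(doc, p, t)
            pairs.extend(p)
            triplets.extend(t)
    return tdict, pairs, triplets
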