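"""Candidate generation, dependency paths and feature extraction."""

from collections import deque

import pytest

from bioevent.candidates import (
    TriggerDictionary,
    dep_path,
    generate_pairs,
    generate_triplets,
)
from bioevent.features import (
    char_ngrams,
    extract_pair_features,
    serialize_features,
    token_shape,
)
from bioevent.standoff import read_dependencies, read_standoff, tokenize


def _doc(text, a1, a2, dep):
    doc = tokenize(read_standoff(text, a1, a2))
    read_dependencies(dep, doc)
    return doc


@pytest.fixture()
def fig_doc():
    """'IFN-alpha induced expression of IRF-4 .' with a small parse."""
    text = "IFN-alpha induced expression of IRF-4 .\n"
    a1 = "T1\tProtein 0 9\tIFN-alpha\nT2\tProtein 32 37\tIRF-4\n"
    a2 = (
        "T3\tGene_expression 18 28\texpression\n"
        "T4\tPositive_regulation 10 17\tinduced\n"
        "E1\tGene_expression:T3 Theme:T2\n"
        "E2\tPositive_regulation:T4 Theme:E1 Cause:T1\n"
    )
    dep = "#sent 0\n1 0 nsubj\n1 2 dobj\n2 3 prep_of\n3 4 nn\n"
    return _doc(text, a1, a2, dep)


@pytest.fixture()
def fig_tdict(fig_doc):
    return TriggerDictionary.from_documents([fig_doc])


def test_pairs_include_trigger_protein_combinations(fig_doc, fig_tdict):
    pairs = generate_pairs(fig_doc, fig_doc.sentences[0], fig_tdict)
    combos = {(fig_doc.sentences[0].tokens[p.trigger_index].text, p.argument.ref)
              for p in pairs}
    assert ("expression", "T2") in combos  # (expression, IRF-4)
    assert ("induced", "T1") in combos  # (induced, IFN-alpha)
    # entity argument for the nested theme: induced -> expression token
    assert any(
        p.argument.kind == "entity" and p.argument.token_index == 2
        and fig_doc.sentences[0].tokens[p.trigger_index].text == "induced"
        for p in pairs
    )


def test_no_dictionary_match_yields_no_pairs(fig_doc):
    empty = TriggerDictionary()
    assert generate_pairs(fig_doc, fig_doc.sentences[0], empty) == []


def test_pair_count_bounded_by_triggers_times_arguments(small_docs, small_candidates):
    tdict, _, _ = small_candidates
    for doc in small_docs[:5]:
        for sent in doc.sentences:
            pairs = generate_pairs(doc, sent, tdict)
            n_trig = len({p.trigger_index for p in pairs}) or 1
            n_args = len({(p.argument.kind, p.argument.ref) for p in pairs})
            assert len(pairs) <= n_trig * n_args


def test_binding_triplets_are_unordered_protein_combinations():
    text = "binding of IL-2 and IL-4 with STAT1 .\n"
    a1 = (
        "T1\tProtein 11 15\tIL-2\nT2\tProtein 20 24\tIL-4\n"
        "T3\tProtein 30 35\tSTAT1\n"
    )
    a2 = "T4\tBinding 0 7\tbinding\nE1\tBinding:T4 Theme:T1 Theme2:T2\n"
    dep = "#sent 0\n0 1 prep\n1 2 pobj\n2 3 cc\n3 4 conj\n4 5 prep\n5 6 pobj\n"
    doc = _doc(text, a1, a2, dep)
    tdict = TriggerDictionary.from_documents([doc])
    trips = generate_triplets(doc, doc.sentences[0], tdict)
    unordered = [t for t in trips if not t.ordered]
    assert len(unordered) == 3  # C(3, 2) protein pairs


def test_reg_triplets_are_ordered_pairs(fig_doc, fig_tdict):
    trips = generate_triplets(fig_doc, fig_doc.sentences[0], fig_tdict)
    ordered = [t for t in trips if t.ordered and t.trigger_index == 1]
    # arguments: T1, T2 and the entity 'expression' -> 3 * 2 ordered pairs
    assert len(ordered) == 6
    assert all(t.arg1 != t.arg2 for t in ordered)


def test_dep_path_matches_bfs_distance(small_docs):
    """Shortest-path labels agree in length with a BFS oracle."""

    def bfs(edges, src, dst):
        adj = {}
        for g, d, _ in edges:
            adj.setdefault(g, set()).add(d)
            adj.setdefault(d, set()).add(g)
        dist = {src: 0}
        q = deque([src])
        while q:
            n = q.popleft()
            for o in adj.get(n, ()):
                if o not in dist:
                    dist[o] = dist[n] + 1
                    q.append(o)
        return dist.get(dst)

    checked = 0
    for doc in small_docs[:5]:
        for sent in doc.sentences:
            n = len(sent.tokens)
            for src in range(0, n, 3):
                for dst in range(1, n, 4):
                    if src == dst:
                        continue
                    expected = bfs(sent.deps.edges, src, dst)
                    path = dep_path(sent, src, dst)
                    if expected is None:
                        assert path is None
                    else:
                        assert path is not None and len(path) == expected
                    checked += 1
    assert checked > 50


def test_disconnected_pair_has_no_path_and_flag_feature(fig_doc, fig_tdict):
    sent = fig_doc.sentences[0]
    sent.deps.edges.clear()
    pairs = generate_pairs(fig_doc, sent, fig_tdict)
    assert all(p.path is None for p in pairs)
    feats = extract_pair_features(pairs[0], sent, n_entities=2)
    assert feats.get("no_path") == 1.0


def test_token_surface_features():
    assert token_shape("IRF-4") == "X-d"
    assert set(char_ngrams("irf-4", 1)) == {"i", "r", "f", "-", "4"}
    assert char_ngrams("cat", 3) == ["cat"]
    with pytest.raises(ValueError):
        char_ngrams("cat", 0)


def test_feature_extraction_is_pure(fig_doc, fig_tdict):
    sent = fig_doc.sentences[0]
    pairs = generate_pairs(fig_doc, sent, fig_tdict)
    a = extract_pair_features(pairs[0], sent, n_entities=2)
    b = extract_pair_features(pairs[0], sent, n_entities=2)
    assert a == b
    assert serialize_features(a) == serialize_features(b)
    # adjacent pair: single-label path feature present
    adj = [p for p in pairs if p.path is not None and len(p.path) == 1]
    assert adj
    f = extract_pair_features(adj[0], sent, n_entities=2)
    assert any(k.startswith("path=") and "." not in k[5:] for k in f)


def test_hypernym_features_optional(fig_doc, fig_tdict):
    sent = fig_doc.sentences[0]
    pairs = generate_pairs(fig_doc, sent, fig_tdict)
    without = extract_pair_features(pairs[0], sent, n_entities=2)
    with_h = extract_pair_features(
        pairs[0], sent, n_entities=2,
        hypernyms={pairs[0].trigger_stem and sent.tokens[pairs[0].trigger_index].stem: ["process"]},
    )
    assert "trg_hyper=process" in with_h
    assert "trg_hyper=process" not in without
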