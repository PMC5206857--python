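"""Word hashing, similarity backends, trigger importance and joint score."""

import numpy as np
import pytest

from bioevent.jointscore import (
    CDSSMBackend,
    ScoreConfig,
    TriggerStats,
    TrigramBackend,
    cdssm_forward,
    filter_by_score,
    joint_score,
    relevance,
    sentence_similarity,
    trigger_importance,
    word_hash,
)


@pytest.mark.parametrize(
    "term,n,expected",
    [
        ("cat", 3, {"#ca": 1, "cat": 1, "at#": 1}),
        ("aaa", 3, {"#aa": 1, "aaa": 1, "aa#": 1}),
        ("", 3, {}),
        ("a", 1, {"#": 2, "a": 1}),
    ],
)
def test_word_hash(term, n, expected):
    assert word_hash(term, n) == expected
    assert word_hash(term, n) == word_hash(term, n)


def test_word_hash_rejects_bad_n():
    with pytest.raises(ValueError):
        word_hash("cat", 0)


def test_relevance_bounds_and_symmetry():
    rng = np.random.default_rng(0)
    a, b = rng.normal(size=16), rng.normal(size=16)
    assert relevance(a, a) == pytest.approx(1.0)
    assert relevance(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0
    assert relevance(a, b) == pytest.approx(relevance(b, a))
    assert -1.0 <= relevance(a, b) <= 1.0
    with pytest.warns(UserWarning):
        assert relevance(np.zeros(4), a) == 0.0


def test_sentence_similarity_boundaries():
    s = ["IRF-4", "expression"]
    assert sentence_similarity(s, []) == 0.0
    assert sentence_similarity(s, [list(s)]) == pytest.approx(1.0)


def test_sentence_similarity_equals_loop_maximum():
    backend = TrigramBackend(dim=512)
    s = ["expression", "of", "IRF-4"]
    d = [["binding", "of", "IL-2"], ["expression", "of", "IL-4"], ["no", "overlap"]]
    got = sentence_similarity(s, d, backend)
    e = backend.embed(s)
    expected = max(relevance(e, backend.embed(x)) for x in d)
    assert got == pytest.approx(expected)


def test_cdssm_zero_weights_give_zero_vector():
    dim = 64
    zeros = {
        "W1": np.zeros((8, dim)), "Wc": np.zeros((4, 3 * 8)), "bc": np.zeros(4),
        "Ws": np.zeros((2, 4)), "bs": np.zeros(2),
    }
    model = CDSSMBackend(dim=dim, weights=zeros)
    out = cdssm_forward(["expression", "of"], model)
    assert np.allclose(out, 0.0)  # tanh(0) = 0 through every layer


def test_cdssm_single_token_and_determinism():
    model = CDSSMBackend(dim=128, latent_dim=16, conv_dim=8, semantic_dim=4, seed=3)
    one = cdssm_forward(["expression"], model)
    again = cdssm_forward(["expression"], model)
    assert np.array_equal(one, again)
    model2 = CDSSMBackend(dim=128, latent_dim=16, conv_dim=8, semantic_dim=4, seed=3)
    assert np.array_equal(one, cdssm_forward(["expression"], model2))
    assert one.shape == (4,)


def test_cdssm_identity_config_reproduces_trigram_cosine():
    dim = 256
    trig = TrigramBackend(dim=dim)
    ident = CDSSMBackend.identity(dim)
    s1 = ["expression", "of", "IRF-4"]
    s2 = ["IFN-alpha", "induced", "expression"]
    r_trig = relevance(trig.embed(s1), trig.embed(s2))
    r_ident = relevance(ident.embed(s1), ident.embed(s2))
    assert r_ident == pytest.approx(r_trig, abs=1e-12)


def test_cdssm_rejects_mismatched_weights():
    with pytest.raises(ValueError):
        CDSSMBackend(
            dim=16,
            weights={"W1": np.zeros((8, 16)), "Wc": np.zeros((4, 99)),
                     "bc": np.zeros(4), "Ws": np.zeros((2, 4)), "bs": np.zeros(2)},
        )


def _stats(counts, extra_total=0):
    s = TriggerStats()
    from collections import Counter

    for stem, c in counts.items():
        s.type_counts[stem] = Counter(c)
    if extra_total:
        s.type_counts["__other__"] = Counter({"Binding": extra_total})
    return s


def test_trigger_importance_derived_arithmetic():
    """f(expr^GE)=4, f(expr^PR)=1, grand total 10, w1=2, w2=3."""
    stats = _stats(
        {"expr": {"Gene_expression": 4, "Positive_regulation": 1}}, extra_total=5
    )
    p1, p2, p = trigger_importance("expr", "Gene_expression", stats, w1=2, w2=3)
    assert p1 == pytest.approx(0.8, abs=1e-12)
    assert p2 == pytest.approx(0.5, abs=1e-12)
    assert p == pytest.approx(0.62, abs=1e-12)


def test_trigger_importance_degenerate_cases():
    stats = _stats({"only": {"Binding": 3}})
    p1, p2, p = trigger_importance("only", "Binding", stats, w1=1, w2=1)
    assert (p1, p2, p) == (1.0, 1.0, 1.0)
    # w1 = 0 -> weighted mean degenerates to P2
    stats2 = _stats({"expr": {"Gene_expression": 4, "Positive_regulation": 1}},
                    extra_total=5)
    _, p2_, p_ = trigger_importance("expr", "Gene_expression", stats2, w1=0, w2=3)
    assert p_ == pytest.approx(p2_)
    # unseen trigger -> zeros
    assert trigger_importance("nope", "Binding", stats, 1, 1) == (0.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        trigger_importance("only", "Binding", stats, 0, 0)


def test_p1_sums_to_one_over_types(small_docs):
    stats = TriggerStats.from_documents(small_docs)
    assert stats.type_counts  # fixture has triggers
    for stem, counts in stats.type_counts.items():
        total = sum(stats.p1(stem, t) for t in counts)
        assert total == pytest.approx(1.0, abs=1e-12)
        assert stats.trigger_total(stem) == sum(counts.values())


def test_joint_score_arithmetic_and_degenerate_weights():
    cfg = ScoreConfig(sigma=0.7)
    assert joint_score(0.62, 0.5, cfg) == pytest.approx(0.536, abs=1e-12)
    assert joint_score(0.3, 0.9, ScoreConfig(sigma=1.0)) == pytest.approx(0.9)
    assert joint_score(0.3, 0.9, ScoreConfig(sigma=0.0)) == pytest.approx(0.3)
    assert joint_score(0.5, -0.4, cfg) == pytest.approx(0.5 * 0.3)  # clamped


def test_joint_score_monotone_in_both_inputs():
    cfg = ScoreConfig(sigma=0.7)
    grid = [i / 10 for i in range(11)]
    for p in grid:
        scores = [joint_score(p, s, cfg) for s in grid]
        assert scores == sorted(scores)
    for s in grid:
        scores = [joint_score(p, s, cfg) for p in grid]
        assert scores == sorted(scores)
        assert all(0.0 <= x <= 1.0 for x in scores)


def test_score_config_validation():
    with pytest.raises(ValueError):
        ScoreConfig(sigma=1.5)
    with pytest.raises(ValueError):
        ScoreConfig(delta=-0.1)


class _Scored:
    def __init__(self, score):
        self.components = {"Score": score}

    def __repr__(self):
        return f"scored({self.components['Score']})"


def test_filter_by_score_partitions_and_monotone_in_delta():
    preds = [_Scored(s) for s in (0.1, 0.4, 0.5, 0.9)]
    kept, removed = filter_by_score(preds, ScoreConfig(delta=0.5))
    assert [p.components["Score"] for p in kept] == [0.5, 0.9]
    assert [p.components["Score"] for p in removed] == [0.1, 0.4]
    kept0, _ = filter_by_score(preds, ScoreConfig(delta=0.0))
    assert len(kept0) == len(preds)
    kept1, _ = filter_by_score(preds, ScoreConfig(delta=1.0))
    assert kept1 == []
    sizes = [len(filter_by_score(preds, ScoreConfig(delta=d / 10))[0]) for d in range(11)]
    assert sizes == sorted(sizes, reverse=True)
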