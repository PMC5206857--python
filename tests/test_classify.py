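"""Model training determinism, prediction and pair/triplet integration."""

import pytest

from bioevent.candidates import Argument, CandidatePair, CandidateTriplet
from bioevent.classify import (
    EventPrediction,
    PredictionSet,
    integrate,
    predict,
    train,
)
from bioevent.schema import NEGATIVE_LABEL


def _pair(trigger_index=0, arg="T1", tok=1, doc="d", sent=0):
    return CandidatePair(
        doc_id=doc, sent_index=sent, trigger_index=trigger_index,
        trigger_stem="trig", argument=Argument("protein", arg, tok),
        path=("nsubj",),
    )


def _triplet(arg1="T1", tok1=1, arg2="T2", tok2=2, ordered=False):
    return CandidateTriplet(
        doc_id="d", sent_index=0, trigger_index=0, trigger_stem="trig",
        arg1=Argument("protein", arg1, tok1), arg2=Argument("protein", arg2, tok2),
        path1=("nsubj",), path2=("dobj",), ordered=ordered,
    )


def _toy_training():
    feats = [{"a": 1.0}, {"a": 1.0, "b": 1.0}, {"c": 1.0}, {"c": 1.0, "d": 1.0}] * 4
    labels = (["Gene_expression", "Gene_expression", NEGATIVE_LABEL, NEGATIVE_LABEL]) * 4
    return feats, labels


def test_training_is_deterministic():
    feats, labels = _toy_training()
    b1 = train(feats, labels, [], [], seed=5)
    b2 = train(feats, labels, [], [], seed=5)
    w1 = b1.pair_model.clf.coef_
    w2 = b2.pair_model.clf.coef_
    assert (w1 == w2).all()


def test_single_class_triplet_model_predicts_nothing():
    feats, labels = _toy_training()
    bundle = train(feats, labels, [{"x": 1.0}] * 3, [NEGATIVE_LABEL] * 3)
    trips = [_triplet()]
    preds = predict(bundle, [], [], trips, [{"x": 1.0}])
    assert preds.triplets == []


def test_learned_model_beats_majority_on_separable_features():
    feats, labels = _toy_training()
    bundle = train(feats, labels, [], [], seed=0)
    preds = predict(
        bundle,
        [_pair(), _pair(arg="T2", tok=2)],
        [{"a": 1.0, "b": 1.0}, {"c": 1.0}],
        [], [],
    )
    assert len(preds.pairs) == 1
    label, cand, margin = preds.pairs[0]
    assert label == "Gene_expression" and cand.argument.ref == "T1"
    assert margin > 0


def test_binding_triplet_subsumes_its_pairs():
    """Triplet Binding(c, a1, a2) + pairs to a1, a2, a3 -> two events."""
    pairs = [
        ("Binding", _pair(arg="T1", tok=1), 1.0),
        ("Binding", _pair(arg="T2", tok=2), 1.0),
        ("Binding", _pair(arg="T3", tok=3), 1.0),
    ]
    triplets = [("Binding", _triplet("T1", 1, "T2", 2), 2.0)]
    events = integrate(PredictionSet(pairs=pairs, triplets=triplets))
    assert len(events) == 2
    two_theme = [e for e in events if e.arg2 is not None]
    assert len(two_theme) == 1
    assert {two_theme[0].theme.ref, two_theme[0].arg2.ref} == {"T1", "T2"}
    assert two_theme[0].arg2_role == "Theme2"
    single = [e for e in events if e.arg2 is None]
    assert single[0].theme.ref == "T3"


def test_reg_triplet_emits_cause_argument():
    triplets = [("Positive_regulation", _triplet("T1", 1, "T2", 2, ordered=True), 1.0)]
    events = integrate(PredictionSet(triplets=triplets))
    assert len(events) == 1
    assert events[0].theme.ref == "T1"
    assert events[0].arg2.ref == "T2" and events[0].arg2_role == "Cause"


def test_integration_without_triplets_is_identity_on_pairs():
    pairs = [
        ("Gene_expression", _pair(arg="T1", tok=1), 1.0),
        ("Binding", _pair(arg="T2", tok=2), 0.5),
    ]
    events = integrate(PredictionSet(pairs=pairs))
    assert {(e.type, e.theme.ref) for e in events} == {
        ("Gene_expression", "T1"), ("Binding", "T2"),
    }


def test_integration_is_idempotent():
    pairs = [
        ("Binding", _pair(arg="T1", tok=1), 1.0),
        ("Binding", _pair(arg="T3", tok=3), 1.0),
    ]
    triplets = [("Binding", _triplet("T1", 1, "T2", 2), 2.0)]
    events = integrate(PredictionSet(pairs=pairs, triplets=triplets))
    # re-express the integrated events as pair/triplet predictions
    re_pairs, re_triplets = [], []
    for e in events:
        if e.arg2 is None:
            re_pairs.append((e.type, _pair(arg=e.theme.ref, tok=e.theme.token_index), e.margin))
        else:
            re_triplets.append(
                (e.type, _triplet(e.theme.ref, e.theme.token_index,
                                  e.arg2.ref, e.arg2.token_index), e.margin)
            )
    again = integrate(PredictionSet(pairs=re_pairs, triplets=re_triplets))
    key = lambda e: (e.type, e.theme.ref, e.arg2.ref if e.arg2 else None)
    assert sorted(map(key, again)) == sorted(map(key, events))


def test_type_conflict_resolved_by_margin():
    pairs = [
        ("Gene_expression", _pair(arg="T1", tok=1), 0.2),
        ("Transcription", _pair(arg="T1", tok=1), 0.9),
    ]
    events = integrate(PredictionSet(pairs=pairs))
    assert len(events) == 1 and events[0].type == "Transcription"


def test_integrate_never_fabricates_triggers():
    pairs = [("Gene_expression", _pair(trigger_index=4, arg="T1", tok=1), 1.0)]
    events = integrate(PredictionSet(pairs=pairs))
    assert {e.trigger_index for e in events} == {4}
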