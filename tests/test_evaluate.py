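"""Internal approximate-span, recursive evaluator."""

import pytest

from bioevent.evaluate import Metrics, evaluate_corpus
from bioevent.standoff import read_standoff, tokenize

TEXT = "IFN-alpha induced expression of IRF-4 .\nSTAT1 binding of IL-2 .\n"
A1 = (
    "T1\tProtein 0 9\tIFN-alpha\nT2\tProtein 32 37\tIRF-4\n"
    "T3\tProtein 40 45\tSTAT1\nT4\tProtein 57 61\tIL-2\n"
)
GOLD_A2 = (
    "T5\tGene_expression 18 28\texpression\n"
    "T6\tPositive_regulation 10 17\tinduced\n"
    "E1\tGene_expression:T5 Theme:T2\n"
    "E2\tPositive_regulation:T6 Theme:E1 Cause:T1\n"
)


def _doc(a2, doc_id="d1"):
    return tokenize(read_standoff(TEXT, A1, a2, doc_id=doc_id))


def test_perfect_predictions_score_hundred():
    res = evaluate_corpus([_doc(GOLD_A2)], [_doc(GOLD_A2)])
    assert res.total.recall == 100.0
    assert res.total.precision == 100.0
    assert res.total.fscore == 100.0


def test_empty_predictions_have_zero_recall():
    res = evaluate_corpus([_doc(GOLD_A2)], [_doc("")])
    assert res.total.recall == 0.0
    assert res.total.n_gold == 2


def test_half_recall_full_precision_f_two_thirds():
    """One of two gold events found, no false positives -> F = 66.67."""
    pred = (
        "T5\tGene_expression 18 28\texpression\n"
        "E1\tGene_expression:T5 Theme:T2\n"
    )
    res = evaluate_corpus([_doc(GOLD_A2)], [_doc(pred)])
    assert res.total.recall == pytest.approx(50.0)
    assert res.total.precision == pytest.approx(100.0)
    assert res.total.fscore == pytest.approx(66.67, abs=0.01)


def test_nested_event_requires_matching_inner_event():
    # the REG event alone cannot match: its Theme event is absent
    pred = (
        "T6\tPositive_regulation 10 17\tinduced\n"
        "T5\tGene_expression 18 28\texpression\n"
        "E1\tGene_expression:T5 Theme:T1\n"  # wrong Theme protein
        "E2\tPositive_regulation:T6 Theme:E1 Cause:T1\n"
    )
    res = evaluate_corpus([_doc(GOLD_A2)], [_doc(pred)])
    assert res.total.tp == 0


def test_trigger_span_tolerance_of_one_token():
    # trigger on the adjacent token 'of' (28..31 is whitespace; use 29..31)
    pred = (
        "T5\tGene_expression 29 31\tof\n"
        "E1\tGene_expression:T5 Theme:T2\n"
    )
    res = evaluate_corpus([_doc(GOLD_A2)], [_doc(pred)])
    assert res.per_type["Gene_expression"].tp == 1
    # two tokens away must not match
    pred_far = (
        "T5\tGene_expression 0 9\tIFN-alpha\n"
        "E1\tGene_expression:T5 Theme:T2\n"
    )
    res_far = evaluate_corpus([_doc(GOLD_A2)], [_doc(pred_far)])
    assert res_far.per_type["Gene_expression"].tp == 0


def test_cause_must_match_when_gold_has_cause():
    pred = (
        "T5\tGene_expression 18 28\texpression\n"
        "T6\tPositive_regulation 10 17\tinduced\n"
        "E1\tGene_expression:T5 Theme:T2\n"
        "E2\tPositive_regulation:T6 Theme:E1\n"  # missing Cause
    )
    res = evaluate_corpus([_doc(GOLD_A2)], [_doc(pred)])
    assert res.per_type["Positive_regulation"].tp == 0
    assert res.per_type["Gene_expression"].tp == 1


def test_binding_theme_set_is_unordered():
    gold = (
        "T5\tBinding 46 53\tbinding\n"
        "E1\tBinding:T5 Theme:T3 Theme2:T4\n"
    )
    pred = (
        "T5\tBinding 46 53\tbinding\n"
        "E1\tBinding:T5 Theme:T4 Theme2:T3\n"
    )
    res = evaluate_corpus([_doc(gold)], [_doc(pred)])
    assert res.per_type["Binding"].tp == 1


def test_misaligned_corpora_rejected():
    with pytest.raises(ValueError):
        evaluate_corpus([_doc(GOLD_A2, "a")], [_doc(GOLD_A2, "b")])


def test_metrics_counts_consistent():
    m = Metrics(tp=3, n_gold=4, n_pred=6)
    assert m.tp <= m.n_gold and m.tp <= m.n_pred
    assert m.fscore == pytest.approx(2 * m.precision * m.recall / (m.precision + m.recall))
    assert Metrics().fscore == 0.0
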