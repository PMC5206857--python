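"""Sequence-database construction and pattern-based sample selection."""

import pytest

from bioevent.candidates import CandidatePair, Argument
from bioevent.sample_select import (
    FilterConfig,
    LabeledPairPath,
    build_sequence_db,
    filter_triplet_candidates,
    match_count,
    select_samples,
)
from bioevent.seqmine import FrequentPatternSet, is_subsequence, mine_frequent_patterns

from .conftest import WORKED_DB


def _pair(path, label="neg"):
    return CandidatePair(
        doc_id="d", sent_index=0, trigger_index=0, trigger_stem="t",
        argument=Argument("protein", "T1", 1), path=path, label=label,
    )


def _labeled(path, label="Gene_expression"):
    return LabeledPairPath("c", "a", path, label)


def test_build_sequence_db_multiset_order_and_skips():
    labeled = [_labeled(p) for p in WORKED_DB]
    assert build_sequence_db(labeled) == [tuple(s) for s in WORKED_DB]
    assert build_sequence_db([]) == []
    dup = [_labeled(("nn",)), _labeled(("nn",))]
    assert build_sequence_db(dup) == [("nn",), ("nn",)]
    with_gap = [_labeled(None), _labeled(("nn",))]
    assert build_sequence_db(with_gap) == [("nn",)]


# The worked selection example: LS holds alpha, beta, gamma; the candidate
# path gamma contains all three, so F = 3 > theta = 2 and it is selected.
WORKED_LS = FrequentPatternSet(
    [(("prep_of", "nn"), 3), (("nn",), 5), (("nsubj", "prep_of", "nn"), 3)],
    minsup=3,
)


def test_match_count_worked_example():
    assert match_count(("nsubj", "prep_of", "nn"), WORKED_LS) == 3
    assert match_count(("nsubj", "prep_of", "nn"), FrequentPatternSet([], 1)) == 0


def test_select_samples_worked_example():
    cand = _pair(("nsubj", "prep_of", "nn"))
    kept, report = select_samples([cand], WORKED_LS, FilterConfig(minsup=3, theta=2))
    assert kept == [cand]
    assert report.n_kept == 1 and report.n_input == 1


def test_theta_at_ls_size_selects_nothing():
    cands = [_pair(("nsubj", "prep_of", "nn")), _pair(("nn",))]
    kept, _ = select_samples(cands, WORKED_LS, FilterConfig(theta=len(WORKED_LS)))
    assert kept == []


def test_theta_zero_minsup_one_selects_any_shared_label():
    db = [("nsubj", "dobj"), ("nn",), ("nsubj",)]
    ls = mine_frequent_patterns(db, minsup=1)
    cand = _pair(("prep_in", "nn"))  # shares the single label nn
    kept, _ = select_samples([cand], ls, FilterConfig(minsup=1, theta=0))
    assert kept == [cand]
    # oracle: count containment by hand
    assert match_count(cand.path, ls) == sum(
        1 for p, _ in ls.patterns if is_subsequence(p, cand.path)
    ) > 0


def test_pathless_candidates_discarded_before_filtering():
    kept, report = select_samples([_pair(None)], WORKED_LS, FilterConfig(theta=0))
    assert kept == [] and report.n_no_path == 1


def test_selection_monotone_in_theta_and_minsup(small_candidates):
    _, pairs, _ = small_candidates
    pos = [p for p in pairs if p.is_gold]
    neg = [p for p in pairs if not p.is_gold]
    db = build_sequence_db(pos)
    prev_by_theta = None
    for theta in (0, 1, 2, 3, 4):
        ls = mine_frequent_patterns(db, 3)
        kept, _ = select_samples(neg, ls, FilterConfig(minsup=3, theta=theta))
        ids = {id(p) for p in kept}
        if prev_by_theta is not None:
            assert ids <= prev_by_theta
        prev_by_theta = ids
    prev_by_minsup = None
    for minsup in (2, 3, 4, 6, 9):
        ls = mine_frequent_patterns(db, minsup)
        kept, _ = select_samples(neg, ls, FilterConfig(minsup=minsup, theta=2))
        ids = {id(p) for p in kept}
        if prev_by_minsup is not None:
            assert ids <= prev_by_minsup
        prev_by_minsup = ids


def _triplet(path1, path2):
    from bioevent.candidates import CandidateTriplet

    return CandidateTriplet(
        doc_id="d", sent_index=0, trigger_index=0, trigger_stem="t",
        arg1=Argument("protein", "T1", 1), arg2=Argument("protein", "T2", 2),
        path1=path1, path2=path2, ordered=True,
    )


def test_triplet_filter_composes_pair_criterion():
    good = ("nsubj", "prep_of", "nn")  # F = 3
    bad = ("amod",)  # F = 0
    cfg = FilterConfig(minsup=3, theta=2)
    kept, _ = filter_triplet_candidates([_triplet(good, good)], WORKED_LS, cfg)
    assert len(kept) == 1
    kept, _ = filter_triplet_candidates([_triplet(good, bad)], WORKED_LS, cfg)
    assert kept == []
    # oracle: applying the pair filter to each path twice
    for t in [_triplet(good, good), _triplet(good, bad), _triplet(bad, bad)]:
        both = all(
            bool(select_samples([_pair(p)], WORKED_LS, cfg)[0])
            for p in (t.path1, t.path2)
        )
        got, _ = filter_triplet_candidates([t], WORKED_LS, cfg)
        assert bool(got) == both


def test_triplet_sum_rule_variant():
    cfg = FilterConfig(minsup=3, theta=2, triplet_rule="sum")
    # F=3 and F=2 fails "both" but passes "sum" (5 > 4)
    t = _triplet(("nsubj", "prep_of", "nn"), ("prep_of", "nn"))
    kept, _ = filter_triplet_candidates([t], WORKED_LS, cfg)
    assert len(kept) == 1
    kept, _ = filter_triplet_candidates([t], WORKED_LS, FilterConfig(minsup=3, theta=2))
    assert kept == []


def test_filter_config_validation():
    with pytest.raises(ValueError):
        FilterConfig(minsup=0)
    with pytest.raises(ValueError):
        FilterConfig(theta=-1)
    with pytest.raises(ValueError):
        FilterConfig(triplet_rule="bogus")
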