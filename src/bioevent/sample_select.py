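"""Sequential-pattern sample selection for imbalanced candidate sets.

Annotated event corpora are heavily imbalanced: candidate trigger-argument
pairs that correspond to no event outnumber true pairs by an order of
magnitude (roughly 1:13 in GENIA-style data).  Rather than class weighting,
the filter keeps only those unlabelled candidates whose dependency path
resembles the paths of annotated positive pairs:

1. the dependency paths of all labelled positive pairs form a sequence
   database DS;
2. the frequent subsequences of DS at a minimum support ``minsup`` form the
   pattern set LS;
3. an unlabelled candidate is selected iff the number F of patterns in LS
   contained in its path is strictly greater than a threshold theta.

The default operating point is minsup=4, theta=2.  Labelled positives are
never filtered — they always enter training.  Triplet candidates carry two
trigger->argument paths; by default both must pass the pair criterion
(conservative AND), with a "sum" variant (F1 + F2 > 2*theta) available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .candidates import CandidatePair, CandidateTriplet
from .seqmine import FrequentPatternSet, is_subsequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabeledPairPath:
    """Minimal labelled pair: identifiers, path and gold label."""

    trigger: str
    argument: str
    path: Optional[tuple[str, ...]]
    label: str


@dataclass
class FilterConfig:
    minsup: int = 4
    theta: int = 2
    triplet_rule: str = "both"  # "both" | "sum"

    def __post_init__(self) -> None:
        if self.minsup < 1:
            raise ValueError("minsup must be >= 1")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.triplet_rule not in ("both", "sum"):
            raise ValueError(f"unknown triplet rule {self.triplet_rule!r}")


@dataclass
class SelectionReport:
    """Kept/discarded bookkeeping for one filtering run."""

    n_input: int = 0
    n_kept: int = 0
    n_no_path: int = 0

    @property
    def n_discarded(self) -> int:
        return self.n_input - self.n_kept

    @property
    def reduction(self) -> float:
        return self.n_discarded / self.n_input if self.n_input else 0.0


def build_sequence_db(labeled: Sequence) -> list[tuple[str, ...]]:
    """Dependency paths of labelled positive pairs -> sequence database DS.

    One database sequence per pair, in input order (multiset semantics:
    duplicated paths each contribute their own entry).  Pairs without a
    dependency path are skipped with a logged count.
    """
    db: list[tuple[str, ...]] = []
    skipped = 0
    for item in labeled:
        path = item.path
        if path is None or len(path) == 0:
            skipped += 1
            continue
        db.append(tuple(path))
    if skipped:
        logger.info("build_sequence_db: skipped %d pair(s) without a path", skipped)
    return db


def match_count(path: Sequence[str], ls: FrequentPatternSet) -> int:
    """Number of patterns in LS contained in ``path`` (the path itself
    counts when it is a member of LS)."""
    p = tuple(path)
    return sum(1 for pattern, _ in ls.patterns if is_subsequence(pattern, p))


def _pair_passes(path: Optional[Sequence[str]], ls: FrequentPatternSet,
                 theta: int) -> bool:
    if path is None:
        return False
    return match_count(path, ls) > theta


def select_samples(
    candidates: Sequence[CandidatePair],
    ls: FrequentPatternSet,
    cfg: FilterConfig,
) -> tuple[list[CandidatePair], SelectionReport]:
    """Keep exactly the candidates with F > theta (strict), in order.

    Candidates with no dependency path are discarded before filtering (the
    match count is undefined without a path, and such pairs are
    overwhelmingly negative).
    """
    report = SelectionReport(n_input=len(candidates))
    kept: list[CandidatePair] = []
    for cand in candidates:
        if cand.path is None:
            report.n_no_path += 1
            continue
        if _pair_passes(cand.path, ls, cfg.theta):
            kept.append(cand)
    report.n_kept = len(kept)
    logger.info(
        "select_samples: kept %d / %d (%.1f%% reduction, %d without path)",
        report.n_kept, report.n_input, 100 * report.reduction, report.n_no_path,
    )
    return kept, report


def filter_triplet_candidates(
    triplets: Sequence[CandidateTriplet],
    ls: FrequentPatternSet,
    cfg: FilterConfig,
) -> tuple[list[CandidateTriplet], SelectionReport]:
    """Apply the pair criterion to both trigger->argument paths.

    Default rule: both paths must individually pass (F > theta).  The "sum"
    variant requires F1 + F2 > 2*theta instead.
    """
    report = SelectionReport(n_input=len(triplets))
    kept: list[CandidateTriplet] = []
    for t in triplets:
        if t.path1 is None or t.path2 is None:
            report.n_no_path += 1
            continue
        if cfg.triplet_rule == "both":
            ok = _pair_passes(t.path1, ls, cfg.theta) and _pair_passes(
                t.path2, ls, cfg.theta
            )
        else:
            ok = match_count(t.path1, ls) + match_count(t.path2, ls) > 2 * cfg.theta
        if ok:
            kept.append(t)
    report.n_kept = len(kept)
    logger.info(
        "filter_triplet_candidates: kept %d / %d", report.n_kept, report.n_input
    )
    return kept, report
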