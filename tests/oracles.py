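"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's mining/selection code paths: the
miner oracle enumerates every subsequence of every database sequence and
counts containment directly.
"""

from __future__ import annotations

from itertools import combinations


def brute_subsequences(seq: tuple[str, ...]) -> set[tuple[str, ...]]:
    """All distinct non-empty subsequences of one sequence."""
    out: set[tuple[str, ...]] = set()
    for r in range(1, len(seq) + 1):
        for idxs in combinations(range(len(seq)), r):
            out.add(tuple(seq[i] for i in idxs))
    return out


def brute_contains(pattern: tuple[str, ...], seq: tuple[str, ...]) -> bool:
    """Order-preserving containment by explicit index search."""

    def rec(pi: int, si: int) -> bool:
        if pi == len(pattern):
            return True
        for j in range(si, len(seq)):
            if seq[j] == pattern[pi] and rec(pi + 1, j + 1):
                return True
        return False

    return rec(0, 0)


def brute_support(pattern: tuple[str, ...], db: list[tuple[str, ...]]) -> int:
    return sum(1 for s in db if brute_contains(pattern, s))


def brute_mine(db: list[tuple[str, ...]], minsup: int) -> dict[tuple[str, ...], int]:
    """Frequent patterns with supports, by full enumeration."""
    candidates: set[tuple[str, ...]] = set()
    for s in db:
        candidates |= brute_subsequences(s)
    return {
        p: brute_support(p, db)
        for p in candidates
        if brute_support(p, db) >= minsup
    }
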