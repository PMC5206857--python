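"""Sequential-pattern mining over dependency-label sequences.

A dependency path between a candidate trigger and argument is an ordered
list of typed-dependency labels, e.g. ``("nsubj", "prep_by", "nn")``.  The
paths of all labelled trigger-argument pairs form a sequence database; the
frequent order-preserving (not necessarily contiguous) subsequences of that
database are the patterns used to filter negative candidates.

Patterns are mined with PrefixSpan: the database is recursively projected
by frequent prefixes, so no candidate sequences are ever generated.  Items
are atomic labels (one label per position), which reduces PrefixSpan to
single-item extension.  Support is the number of database sequences that
contain the pattern; duplicate sequences each count once (multiset
semantics), and a sequence contains itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

Pattern = tuple[str, ...]


def is_subsequence(a: Sequence[str], b: Sequence[str]) -> bool:
    """True iff ``a`` embeds into ``b`` via strictly increasing indices.

    The empty sequence is a subsequence of everything.
    """
    it = iter(b)
    return all(item in it for item in a)


def support(s: Sequence[str], db: Iterable[Sequence[str]]) -> int:
    """Number of database sequences containing ``s``."""
    pat = tuple(s)
    return sum(1 for t in db if is_subsequence(pat, t))


@dataclass
class FrequentPatternSet:
    """Mined frequent patterns with their supports, at a given minsup.

    Patterns are stored in canonical order (length, then lexicographic) so
    that serialization is deterministic.
    """

    patterns: list[tuple[Pattern, int]]
    minsup: int
    _index: dict[Pattern, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.patterns = sorted(
            ((tuple(p), int(c)) for p, c in self.patterns),
            key=lambda pc: (len(pc[0]), pc[0]),
        )
        self._index = {p: c for p, c in self.patterns}
        if len(self._index) != len(self.patterns):
            raise ValueError("duplicate patterns in FrequentPatternSet")
        bad = [p for p, c in self.patterns if c < self.minsup]
        if bad:
            raise ValueError(f"patterns below minsup {self.minsup}: {bad}")

    def __len__(self) -> int:
        return len(self.patterns)

    def __contains__(self, pattern: Sequence[str]) -> bool:
        return tuple(pattern) in self._index

    def support_of(self, pattern: Sequence[str]) -> int:
        return self._index[tuple(pattern)]

    def as_dict(self) -> dict[Pattern, int]:
        return dict(self._index)

    def dumps(self) -> str:
        """Serialize as 'label1 label2 ...<TAB>support' lines."""
        lines = [f"# minsup={self.minsup}"]
        lines += [f"{' '.join(p)}\t{c}" for p, c in self.patterns]
        return "\n".join(lines) + "\n"

    @classmethod
    def loads(cls, text: str) -> "FrequentPatternSet":
        minsup = 1
        patterns: list[tuple[Pattern, int]] = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "minsup=" in line:
                    minsup = int(line.split("minsup=")[1])
                continue
            try:
                items, sup = line.rsplit("\t", 1)
            except ValueError:
                raise ValueError(f"malformed pattern line {lineno}: {line!r}") from None
            patterns.append((tuple(items.split()), int(sup)))
        return cls(patterns, minsup)


def mine_frequent_patterns(
    db: Sequence[Sequence[str]], minsup: int
) -> FrequentPatternSet:
    """Mine all non-empty frequent subsequences of ``db`` by PrefixSpan.

    Returns exactly {s : s non-empty, support(s, db) >= minsup}, each with
    its true support.  The empty pattern is excluded (vacuously frequent).
    """
    if minsup < 1:
        raise ValueError(f"minsup must be >= 1, got {minsup}")
    sequences = [tuple(s) for s in db]
    found: list[tuple[Pattern, int]] = []
    # A projected database is a list of (sequence index, start offset):
    # the suffix of sequences[i] beginning at the offset.
    initial = [(i, 0) for i in range(len(sequences))]
    _project((), initial, sequences, minsup, found)
    return FrequentPatternSet(found, minsup)


def _project(
    prefix: Pattern,
    proj: list[tuple[int, int]],
    sequences: list[Pattern],
    minsup: int,
    out: list[tuple[Pattern, int]],
) -> None:
    # Count each extension item once per distinct source sequence.
    counts: dict[str, int] = {}
    seen_in: dict[str, int] = {}
    for seq_i, start in proj:
        seq = sequences[seq_i]
        for item in dict.fromkeys(seq[start:]):
            if seen_in.get(item) != seq_i:
                counts[item] = counts.get(item, 0) + 1
                seen_in[item] = seq_i
    for item in sorted(c for c, n in counts.items() if n >= minsup):
        new_prefix = prefix + (item,)
        out.append((new_prefix, counts[item]))
        new_proj: list[tuple[int, int]] = []
        for seq_i, start in proj:
            seq = sequences[seq_i]
            try:
                pos = seq.index(item, start)
            except ValueError:
                continue
            new_proj.append((seq_i, pos + 1))
        _project(new_prefix, new_proj, sequences, minsup, out)
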