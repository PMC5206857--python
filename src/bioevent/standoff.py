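"""BioNLP-ST standoff annotation I/O, tokenization and dependency input.

A document is distributed across three plain-text files: ``.txt`` holds the
raw text, ``.a1`` the protein annotations (T lines), and ``.a2`` the event
annotations (trigger T lines plus E lines).  Offsets are 0-based, half-open
and document-level throughout.  Dependency parses are consumed as an input
file per document (they come from an external parser): one block per
sentence with ``govIdx depIdx label`` edge lines.

Tokenization is a contract-level whitespace/punctuation splitter with exact
offset tracking; hyphenated biomedical names like ``IRF-4`` stay single
tokens.  Stemming and POS tagging are deliberately lightweight heuristics —
they only feed classifier features and dictionary matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Union

from .schema import EVENT_TYPES, validate_event


class StandoffError(ValueError):
    """Base class for standoff format errors."""


class StandoffParseError(StandoffError):
    """Malformed line or dangling reference; message names the line."""


class IntegrityError(StandoffError):
    """Annotation disagrees with the document text or token indices."""


class ValidationError(StandoffError):
    """Event violates the nine-type argument schema."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Token:
    index: int
    text: str
    stem: str
    pos: str
    char_start: int
    char_end: int


@dataclass
class DependencyGraph:
    """Typed-dependency edges among the tokens of one sentence."""

    edges: set[tuple[int, int, str]] = field(default_factory=set)

    def add(self, gov: int, dep: int, label: str) -> None:
        if not label:
            raise ValueError("dependency label must be non-empty")
        self.edges.add((gov, dep, label))


@dataclass
class Sentence:
    index: int
    char_start: int
    char_end: int
    tokens: list[Token] = field(default_factory=list)
    deps: DependencyGraph = field(default_factory=DependencyGraph)


@dataclass(frozen=True)
class ProteinAnnotation:
    id: str
    char_start: int
    char_end: int
    text: str


@dataclass(frozen=True)
class TriggerAnnotation:
    id: str
    type: str
    char_start: int
    char_end: int
    text: str


@dataclass(frozen=True)
class EventAnnotation:
    """One event: typed trigger plus Theme (and optional Theme2/Cause).

    ``theme``/``theme2``/``cause`` are T references (proteins or triggers)
    or E references (nested events).
    """

    id: str
    type: str
    trigger_id: str
    theme: str
    theme2: Optional[str] = None
    cause: Optional[str] = None

    def validate(self) -> None:
        n_themes = 1 + (self.theme2 is not None)
        try:
            validate_event(self.type, n_themes, self.cause is not None)
        except ValueError as exc:
            raise ValidationError(f"{self.id}: {exc}") from None


@dataclass
class Document:
    doc_id: str
    text: str
    proteins: list[ProteinAnnotation] = field(default_factory=list)
    triggers: dict[str, TriggerAnnotation] = field(default_factory=dict)
    events: list[EventAnnotation] = field(default_factory=list)
    sentences: list[Sentence] = field(default_factory=list)

    def protein_by_id(self, tid: str) -> ProteinAnnotation:
        for p in self.proteins:
            if p.id == tid:
                return p
        raise KeyError(tid)


# ---------------------------------------------------------------------------
# tokenization

_SENT_BOUNDARY = re.compile(r"\n+|(?<=[.!?])[ \t]+")
_TOKEN = re.compile(r"[A-Za-z0-9](?:[A-Za-z0-9+_/\-]*[A-Za-z0-9])?|\S")

_SUFFIXES = (
    "ations", "ation", "ition", "sions", "sion", "tion",
    "ingly", "edly", "ness", "ing", "ies", "ed", "es", "ly", "s",
)
_CLOSED = {
    "the": "DT", "a": "DT", "an": "DT",
    "of": "IN", "in": "IN", "by": "IN", "with": "IN", "to": "IN",
    "on": "IN", "at": "IN", "for": "IN", "from": "IN",
    "and": "CC", "or": "CC", "but": "CC",
    "is": "VB", "are": "VB", "was": "VB", "were": "VB",
}


def stem(word: str) -> str:
    """Crude suffix-stripping stem; only used for matching and features."""
    w = word.lower()
    if len(w) > 4:
        for suf in _SUFFIXES:
            if w.endswith(suf) and len(w) - len(suf) >= 3:
                return w[: -len(suf)]
    return w


def pos_tag(word: str) -> str:
    """Heuristic POS tag (no parser is bundled; tags only feed features)."""
    lw = word.lower()
    if lw in _CLOSED:
        return _CLOSED[lw]
    if not any(c.isalnum() for c in word):
        return word[:1] or "SYM"
    if any(c.isdigit() for c in word) or "-" in word or word.isupper():
        return "NN"
    if lw.endswith(("tion", "sion", "ment", "ity", "ness")):
        return "NN"
    if lw.endswith(("ed", "ing", "ates", "izes", "es")):
        return "VB"
    return "NN"


def tokenize(doc: Document) -> Document:
    """Split ``doc.text`` into offset-tracked sentences and tokens."""
    sentences: list[Sentence] = []
    pos = 0
    pieces: list[tuple[int, str]] = []
    for m in _SENT_BOUNDARY.finditer(doc.text):
        pieces.append((pos, doc.text[pos : m.start()]))
        pos = m.end()
    pieces.append((pos, doc.text[pos:]))
    for start, chunk in pieces:
        if not chunk.strip():
            continue
        sent = Sentence(index=len(sentences), char_start=start, char_end=start + len(chunk))
        for tm in _TOKEN.finditer(chunk):
            text = tm.group(0)
            sent.tokens.append(
                Token(
                    index=len(sent.tokens),
                    text=text,
                    stem=stem(text),
                    pos=pos_tag(text),
                    char_start=start + tm.start(),
                    char_end=start + tm.end(),
                )
            )
        if sent.tokens:
            sentences.append(sent)
    for i, s in enumerate(sentences):
        s.index = i
    doc.sentences = sentences
    return doc


def find_token(doc: Document, char_start: int, char_end: int) -> tuple[int, int]:
    """Locate the (sentence index, token index) whose span overlaps most."""
    best: tuple[int, tuple[int, int]] | None = None
    for s in doc.sentences:
        if s.char_end <= char_start or s.char_start >= char_end:
            continue
        for t in s.tokens:
            overlap = min(t.char_end, char_end) - max(t.char_start, char_start)
            if overlap > 0 and (best is None or overlap > best[0]):
                best = (overlap, (s.index, t.index))
    if best is None:
        raise IntegrityError(
            f"{doc.doc_id}: no token overlaps span [{char_start}, {char_end})"
        )
    return best[1]


# ---------------------------------------------------------------------------
# standoff parsing

Streamish = Union[str, IO[str]]


def _as_text(stream: Optional[Streamish]) -> str:
    if stream is None:
        return ""
    if isinstance(stream, str):
        return stream
    return stream.read()


def _parse_t_line(line: str, lineno: int, which: str) -> tuple[str, str, int, int, str]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != 3 or not parts[0].startswith("T"):
        raise StandoffParseError(f"{which} line {lineno}: malformed T line: {line!r}")
    tid, mid, text = parts
    fields = mid.split()
    if len(fields) != 3:
        raise StandoffParseError(f"{which} line {lineno}: malformed span: {line!r}")
    ann_type, s, e = fields
    try:
        start, end = int(s), int(e)
    except ValueError:
        raise StandoffParseError(f"{which} line {lineno}: bad offsets: {line!r}") from None
    if start >= end:
        raise StandoffParseError(f"{which} line {lineno}: empty span: {line!r}")
    return tid, ann_type, start, end, text


def read_standoff(
    txt: Streamish,
    a1: Streamish,
    a2: Optional[Streamish] = None,
    doc_id: str = "doc",
) -> Document:
    """Parse .txt/.a1/.a2 streams into a Document (tokens not yet resolved).

    Raises StandoffParseError for malformed lines or dangling references
    (naming the line) and IntegrityError when an annotation's surface text
    disagrees with the document substring at its offsets.
    """
    text = _as_text(txt)
    doc = Document(doc_id=doc_id, text=text)
    known_t: set[str] = set()

    for lineno, line in enumerate(_as_text(a1).splitlines(), start=1):
        if not line.strip():
            continue
        tid, ann_type, start, end, surface = _parse_t_line(line, lineno, ".a1")
        if text[start:end] != surface:
            raise IntegrityError(
                f".a1 line {lineno}: text mismatch for {tid}: "
                f"{text[start:end]!r} != {surface!r}"
            )
        doc.proteins.append(ProteinAnnotation(tid, start, end, surface))
        known_t.add(tid)

    a2_text = _as_text(a2)
    event_lines: list[tuple[int, str]] = []
    for lineno, line in enumerate(a2_text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("T"):
            tid, ann_type, start, end, surface = _parse_t_line(line, lineno, ".a2")
            if ann_type not in EVENT_TYPES:
                raise StandoffParseError(
                    f".a2 line {lineno}: unknown event type {ann_type!r}"
                )
            if text[start:end] != surface:
                raise IntegrityError(
                    f".a2 line {lineno}: text mismatch for {tid}: "
                    f"{text[start:end]!r} != {surface!r}"
                )
            doc.triggers[tid] = TriggerAnnotation(tid, ann_type, start, end, surface)
            known_t.add(tid)
        elif line.startswith("E"):
            event_lines.append((lineno, line))
        else:
            raise StandoffParseError(f".a2 line {lineno}: unexpected line: {line!r}")

    known_e: set[str] = set()
    parsed: list[tuple[int, EventAnnotation]] = []
    for lineno, line in event_lines:
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise StandoffParseError(f".a2 line {lineno}: malformed E line: {line!r}")
        eid, body = parts
        fields = body.split()
        if not fields or ":" not in fields[0]:
            raise StandoffParseError(f".a2 line {lineno}: malformed E line: {line!r}")
        etype, trig = fields[0].split(":", 1)
        args: dict[str, str] = {}
        for f in fields[1:]:
            if ":" not in f:
                raise StandoffParseError(f".a2 line {lineno}: malformed argument {f!r}")
            role, ref = f.split(":", 1)
            if role not in ("Theme", "Theme2", "Cause"):
                raise StandoffParseError(f".a2 line {lineno}: unsupported role {role!r}")
            if role in args:
                raise StandoffParseError(f".a2 line {lineno}: duplicate role {role!r}")
            args[role] = ref
        if "Theme" not in args:
            raise StandoffParseError(f".a2 line {lineno}: event {eid} has no Theme")
        ev = EventAnnotation(
            id=eid,
            type=etype,
            trigger_id=trig,
            theme=args["Theme"],
            theme2=args.get("Theme2"),
            cause=args.get("Cause"),
        )
        parsed.append((lineno, ev))
        known_e.add(eid)

    for lineno, ev in parsed:
        if ev.trigger_id not in doc.triggers:
            raise StandoffParseError(
                f".a2 line {lineno}: event {ev.id} references undeclared "
                f"trigger {ev.trigger_id}"
            )
        if doc.triggers[ev.trigger_id].type != ev.type:
            raise IntegrityError(
                f".a2 line {lineno}: event {ev.id} type {ev.type} disagrees with "
                f"trigger {ev.trigger_id}"
            )
        for ref in (ev.theme, ev.theme2, ev.cause):
            if ref is None:
                continue
            if ref.startswith("E"):
                if ref not in known_e:
                    raise StandoffParseError(
                        f".a2 line {lineno}: event {ev.id} references undeclared {ref}"
                    )
            elif ref not in known_t:
                raise StandoffParseError(
                    f".a2 line {lineno}: event {ev.id} references undeclared {ref}"
                )
        ev.validate()
        doc.events.append(ev)
    return doc


def write_a2(
    events: Iterable[EventAnnotation],
    triggers: dict[str, TriggerAnnotation],
) -> str:
    """Serialize events (and their trigger T lines) to .a2 format.

    ``read_standoff`` of the output reproduces the event set exactly.
    """
    events = list(events)
    used: set[str] = set()
    for ev in events:
        ev.validate()
        if ev.trigger_id not in triggers:
            raise ValidationError(f"{ev.id}: unknown trigger {ev.trigger_id}")
        used.add(ev.trigger_id)
    lines: list[str] = []

    def _tnum(tid: str) -> int:
        return int(re.sub(r"\D", "", tid) or 0)

    for tid in sorted(used, key=_tnum):
        t = triggers[tid]
        lines.append(f"{t.id}\t{t.type} {t.char_start} {t.char_end}\t{t.text}")
    for ev in events:
        body = f"{ev.type}:{ev.trigger_id} Theme:{ev.theme}"
        if ev.theme2 is not None:
            body += f" Theme2:{ev.theme2}"
        if ev.cause is not None:
            body += f" Cause:{ev.cause}"
        lines.append(f"{ev.id}\t{body}")
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# dependency input

def read_dependencies(dep_text: Streamish, doc: Document) -> Document:
    """Attach per-sentence dependency edges from a ``.dep`` file.

    Format: one block per sentence introduced by ``#sent <index>``, followed
    by ``govIdx depIdx label`` lines (token indices within that sentence).
    """
    if not doc.sentences:
        raise ValueError("tokenize the document before attaching dependencies")
    current: Optional[Sentence] = None
    for lineno, line in enumerate(_as_text(dep_text).splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#sent"):
            try:
                idx = int(line.split()[1])
                current = doc.sentences[idx]
            except (IndexError, ValueError):
                raise StandoffParseError(f".dep line {lineno}: bad sentence header") from None
            continue
        if current is None:
            raise StandoffParseError(f".dep line {lineno}: edge before sentence header")
        parts = line.split()
        if len(parts) != 3:
            raise StandoffParseError(f".dep line {lineno}: malformed edge: {line!r}")
        gov, dep, label = int(parts[0]), int(parts[1]), parts[2]
        n = len(current.tokens)
        if not (0 <= gov < n and 0 <= dep < n):
            raise IntegrityError(
                f".dep line {lineno}: token index out of range for sentence "
                f"{current.index} ({n} tokens)"
            )
        current.deps.add(gov, dep, label)
    return doc


def write_dependencies(doc: Document) -> str:
    lines: list[str] = []
    for s in doc.sentences:
        lines.append(f"#sent {s.index}")
        for gov, dep, label in sorted(s.deps.edges):
            lines.append(f"{gov} {dep} {label}")
    return "\n".join(lines) + ("\n" if lines else "")


def load_document(
    txt_path: str,
    a1_path: str,
    a2_path: Optional[str] = None,
    dep_path: Optional[str] = None,
    doc_id: Optional[str] = None,
) -> Document:
    """Read, tokenize and wire a document from its standoff files."""
    import os

    did = doc_id or os.path.splitext(os.path.basename(txt_path))[0]
    with open(txt_path, encoding="utf-8") as ftxt, open(a1_path, encoding="utf-8") as fa1:
        a2_stream: Optional[IO[str]] = None
        if a2_path is not None and os.path.exists(a2_path):
            a2_stream = open(a2_path, encoding="utf-8")
        try:
            doc = read_standoff(ftxt, fa1, a2_stream, doc_id=did)
        finally:
            if a2_stream is not None:
                a2_stream.close()
    tokenize(doc)
    if dep_path is not None and os.path.exists(dep_path):
        with open(dep_path, encoding="utf-8") as fdep:
            read_dependencies(fdep, doc)
    return doc
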