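"""Candidate trigger-argument pairs and triplets, and their labelling.

Candidate triggers are single tokens whose stem appears in a trigger
dictionary built from the training annotations.  Candidate arguments are
the annotated proteins of the sentence plus the other dictionary-matched
trigger tokens (candidate entities, needed so a regulation event can take
another event as its Theme).  Pairs are every (trigger, argument) with
trigger != argument; triplets (trigger, argument, argument2) are generated
only for triggers whose dictionary types include a Binding or regulation
type — unordered protein pairs for Binding, ordered (Theme, Cause) pairs
for regulation.

Each candidate carries the typed-dependency label sequence of the shortest
path from trigger to argument over the undirected view of the sentence's
dependency graph (None when disconnected).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional

import networkx as nx

from .schema import BIND_TYPES, NEGATIVE_LABEL, REG_TYPES, event_class
from .standoff import Document, Sentence, find_token


@dataclass
class TriggerDictionary:
    """Stem -> event-type occurrence counts, from training .a2 triggers."""

    entries: dict[str, Counter] = field(default_factory=dict)

    @classmethod
    def from_documents(cls, docs: Iterable[Document]) -> "TriggerDictionary":
        from .standoff import stem as _stem

        d = cls()
        for doc in docs:
            for ev in doc.events:
                trig = doc.triggers[ev.trigger_id]
                d.entries.setdefault(_stem(trig.text), Counter())[ev.type] += 1
        return d

    def __contains__(self, stem: str) -> bool:
        return stem in self.entries

    def types_for(self, stem: str) -> set[str]:
        return set(self.entries.get(stem, ()))

    def majority_type(self, stem: str) -> str:
        counts = self.entries[stem]
        return min(counts, key=lambda t: (-counts[t], t))


@dataclass(frozen=True)
class Argument:
    """A candidate argument: an annotated protein or a trigger token."""

    kind: str  # "protein" | "entity"
    ref: str  # protein T id, or "tok:<sent>:<idx>" for entities
    token_index: int

    @property
    def is_protein(self) -> bool:
        return self.kind == "protein"


@dataclass
class CandidatePair:
    doc_id: str
    sent_index: int
    trigger_index: int
    trigger_stem: str
    argument: Argument
    path: Optional[tuple[str, ...]]
    label: str = NEGATIVE_LABEL
    is_gold: bool = False


@dataclass
class CandidateTriplet:
    doc_id: str
    sent_index: int
    trigger_index: int
    trigger_stem: str
    arg1: Argument  # Theme (first Theme for Binding)
    arg2: Argument  # second Theme for Binding, Cause for REG
    path1: Optional[tuple[str, ...]]
    path2: Optional[tuple[str, ...]]
    ordered: bool  # True for REG (Theme, Cause); False for Binding
    label: str = NEGATIVE_LABEL
    is_gold: bool = False


# --------------------------------------------------------------------------
# dependency paths


def _sentence_graph(sent: Sentence) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(sent.tokens)))
    for gov, dep, lab in sorted(sent.deps.edges):
        g.add_edge(gov, dep, label=lab)
    return g


def dep_path(sent: Sentence, src: int, dst: int,
             graph: Optional[nx.Graph] = None) -> Optional[tuple[str, ...]]:
    """Label sequence along the shortest undirected path src -> dst."""
    g = graph if graph is not None else _sentence_graph(sent)
    try:
        nodes = nx.shortest_path(g, src, dst)
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        return None
    return tuple(g.edges[a, b]["label"] for a, b in zip(nodes, nodes[1:]))


# --------------------------------------------------------------------------
# candidate generation


def _sentence_proteins(doc: Document, sent: Sentence) -> list[Argument]:
    args = []
    for p in doc.proteins:
        if p.char_start >= sent.char_start and p.char_end <= sent.char_end:
            _, tok = find_token(doc, p.char_start, p.char_end)
            args.append(Argument("protein", p.id, tok))
    return args


def _trigger_tokens(doc: Document, sent: Sentence, tdict: TriggerDictionary) -> list[int]:
    covered = set()
    for p in doc.proteins:
        for t in sent.tokens:
            if t.char_start < p.char_end and t.char_end > p.char_start:
                covered.add(t.index)
    return [
        t.index
        for t in sent.tokens
        if t.index not in covered and t.stem in tdict
    ]


def generate_pairs(doc: Document, sent: Sentence,
                   tdict: TriggerDictionary) -> list[CandidatePair]:
    """All (trigger, argument) candidates of one sentence."""
    graph = _sentence_graph(sent)
    proteins = _sentence_proteins(doc, sent)
    trig_idxs = _trigger_tokens(doc, sent, tdict)
    entities = [
        Argument("entity", f"tok:{sent.index}:{i}", i) for i in trig_idxs
    ]
    pairs: list[CandidatePair] = []
    for c in trig_idxs:
        for a in proteins + entities:
            if a.kind == "entity" and a.token_index == c:
                continue
            pairs.append(
                CandidatePair(
                    doc_id=doc.doc_id,
                    sent_index=sent.index,
                    trigger_index=c,
                    trigger_stem=sent.tokens[c].stem,
                    argument=a,
                    path=dep_path(sent, c, a.token_index, graph),
                )
            )
    return pairs


def generate_triplets(doc: Document, sent: Sentence,
                      tdict: TriggerDictionary) -> list[CandidateTriplet]:
    """Binding (unordered) and REG (ordered Theme/Cause) triplet candidates."""
    graph = _sentence_graph(sent)
    proteins = _sentence_proteins(doc, sent)
    trig_idxs = _trigger_tokens(doc, sent, tdict)
    entities = [Argument("entity", f"tok:{sent.index}:{i}", i) for i in trig_idxs]
    triplets: list[CandidateTriplet] = []
    for c in trig_idxs:
        types = tdict.types_for(sent.tokens[c].stem)
        args = [a for a in proteins + entities if not (a.kind == "entity" and a.token_index == c)]
        paths = {a.token_index: dep_path(sent, c, a.token_index, graph) for a in args}

        def mk(a1: Argument, a2: Argument, ordered: bool) -> CandidateTriplet:
            return CandidateTriplet(
                doc_id=doc.doc_id,
                sent_index=sent.index,
                trigger_index=c,
                trigger_stem=sent.tokens[c].stem,
                arg1=a1,
                arg2=a2,
                path1=paths[a1.token_index],
                path2=paths[a2.token_index],
                ordered=ordered,
            )

        if any(t in BIND_TYPES for t in types):
            prot_args = [a for a in args if a.is_protein]
            for a1, a2 in combinations(prot_args, 2):
                triplets.append(mk(a1, a2, ordered=False))
        if any(t in REG_TYPES for t in types):
            for a1 in args:
                for a2 in args:
                    if a1 is a2:
                        continue
                    triplets.append(mk(a1, a2, ordered=True))
    return triplets


# --------------------------------------------------------------------------
# gold labelling


def _gold_index(doc: Document):
    """Resolve gold events to (trigger token, theme refs, cause ref) keys."""
    ev_by_id = {ev.id: ev for ev in doc.events}

    def trig_token(eid_or_tid: str) -> tuple[int, int]:
        if eid_or_tid.startswith("E"):
            ev = ev_by_id[eid_or_tid]
            t = doc.triggers[ev.trigger_id]
        else:
            t = doc.triggers[eid_or_tid]
        return find_token(doc, t.char_start, t.char_end)

    resolved = []
    for ev in doc.events:
        trig = doc.triggers[ev.trigger_id]
        t_sent, t_idx = find_token(doc, trig.char_start, trig.char_end)

        def arg_key(ref: Optional[str]):
            if ref is None:
                return None
            if ref.startswith("E"):
                s, i = trig_token(ref)
                return ("entity", s, i)
            return ("protein", ref)

        resolved.append(
            {
                "type": ev.type,
                "sent": t_sent,
                "trig": t_idx,
                "themes": [k for k in (arg_key(ev.theme), arg_key(ev.theme2)) if k],
                "cause": arg_key(ev.cause),
            }
        )
    return resolved


def _argkey(sent_index: int, a: Argument):
    if a.is_protein:
        return ("protein", a.ref)
    return ("entity", sent_index, a.token_index)


def label_candidates(doc: Document, pairs: list[CandidatePair],
                     triplets: list[CandidateTriplet]) -> None:
    """Assign gold event-type labels in place (others stay negative)."""
    gold = _gold_index(doc)
    pair_labels: dict[tuple, str] = {}
    for g in gold:
        for theme in g["themes"]:
            pair_labels[(g["sent"], g["trig"], theme)] = g["type"]
    for p in pairs:
        key = (p.sent_index, p.trigger_index, _argkey(p.sent_index, p.argument))
        if key in pair_labels:
            p.label = pair_labels[key]
            p.is_gold = True

    bind_keys: dict[tuple, str] = {}
    reg_keys: dict[tuple, str] = {}
    for g in gold:
        if event_class(g["type"]) == "BIND" and len(g["themes"]) == 2:
            key = (g["sent"], g["trig"], frozenset(g["themes"]))
            bind_keys[key] = g["type"]
        elif event_class(g["type"]) == "REG" and g["cause"] is not None:
            key = (g["sent"], g["trig"], g["themes"][0], g["cause"])
            reg_keys[key] = g["type"]
    for t in triplets:
        k1 = _argkey(t.sent_index, t.arg1)
        k2 = _argkey(t.sent_index, t.arg2)
        if t.ordered:
            key = (t.sent_index, t.trigger_index, k1, k2)
            if key in reg_keys:
                t.label = reg_keys[key]
                t.is_gold = True
        else:
            key = (t.sent_index, t.trigger_index, frozenset((k1, k2)))
            if key in bind_keys:
                t.label = bind_keys[key]
                t.is_gold = True
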