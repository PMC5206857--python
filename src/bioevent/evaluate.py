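"""Internal evaluator: approximate-span, recursive event matching.

Used only on synthetic fixture corpora.  A predicted event matches a gold
event when the types are equal, the trigger tokens are at most one token
apart in the same sentence (approximate span), and the arguments match:
protein arguments must overlap the same protein annotation, event
arguments must reference events that themselves match (approximate
recursion); Binding Themes are compared as an unordered set, and Cause
must be absent on both sides or match.  Matching is greedy per event type
with each gold event consumed at most once.

The official shared-task scorer implements additional normalisations
(e.g. duplicate-event equivalences); this evaluator is documented, not
claimed identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .schema import EVENT_CLASSES, EVENT_TYPES, event_class
from .standoff import Document, find_token


@dataclass
class Metrics:
    tp: int = 0
    n_gold: int = 0
    n_pred: int = 0

    @property
    def recall(self) -> float:
        return 100.0 * self.tp / self.n_gold if self.n_gold else 0.0

    @property
    def precision(self) -> float:
        return 100.0 * self.tp / self.n_pred if self.n_pred else 0.0

    @property
    def fscore(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0

    def add(self, other: "Metrics") -> None:
        self.tp += other.tp
        self.n_gold += other.n_gold
        self.n_pred += other.n_pred


@dataclass
class EvalResult:
    per_type: dict[str, Metrics] = field(default_factory=dict)
    per_class: dict[str, Metrics] = field(default_factory=dict)
    total: Metrics = field(default_factory=Metrics)

    def summary(self) -> str:
        lines = [f"{'type':<22}{'R':>8}{'P':>8}{'F':>8}"]
        for typ in list(EVENT_TYPES) + list(EVENT_CLASSES) + ["ALL"]:
            m = (
                self.per_type.get(typ)
                or self.per_class.get(typ)
                or (self.total if typ == "ALL" else None)
            )
            if m is None or (m.n_gold == 0 and m.n_pred == 0):
                continue
            lines.append(
                f"{typ:<22}{m.recall:>8.2f}{m.precision:>8.2f}{m.fscore:>8.2f}"
            )
        return "\n".join(lines)


def _event_view(doc: Document):
    """Resolve a document's events to comparable keys."""
    views = {}
    for ev in doc.events:
        trig = doc.triggers[ev.trigger_id]
        sent, tok = find_token(doc, trig.char_start, trig.char_end)
        views[ev.id] = {
            "type": ev.type,
            "sent": sent,
            "tok": tok,
            "themes": [r for r in (ev.theme, ev.theme2) if r],
            "cause": ev.cause,
            "spans": {
                p.id: (p.char_start, p.char_end) for p in doc.proteins
            },
        }
    return views


def _protein_span(doc: Document, tid: str) -> Optional[tuple[int, int]]:
    for p in doc.proteins:
        if p.id == tid:
            return (p.char_start, p.char_end)
    return None


def _args_match(gref: str, pref: str, gdoc: Document, pdoc: Document,
                gviews, pviews, memo) -> bool:
    g_is_event = gref.startswith("E")
    p_is_event = pref.startswith("E")
    if g_is_event != p_is_event:
        return False
    if g_is_event:
        return _events_match(gviews[gref], pviews[pref], gref, pref,
                             gdoc, pdoc, gviews, pviews, memo)
    gs = _protein_span(gdoc, gref)
    ps = _protein_span(pdoc, pref)
    if gs is None or ps is None:
        return False
    return gs[0] < ps[1] and ps[0] < gs[1]  # overlapping protein spans


def _events_match(g, p, gid, pid, gdoc, pdoc, gviews, pviews, memo) -> bool:
    key = (gid, pid)
    if key in memo:
        return memo[key]
    memo[key] = False  # break reference cycles conservatively
    ok = (
        g["type"] == p["type"]
        and g["sent"] == p["sent"]
        and abs(g["tok"] - p["tok"]) <= 1
    )
    if ok:
        gt, pt = g["themes"], p["themes"]
        if len(gt) != len(pt):
            ok = False
        elif len(gt) == 1:
            ok = _args_match(gt[0], pt[0], gdoc, pdoc, gviews, pviews, memo)
        else:  # Binding: unordered Theme set
            ok = (
                _args_match(gt[0], pt[0], gdoc, pdoc, gviews, pviews, memo)
                and _args_match(gt[1], pt[1], gdoc, pdoc, gviews, pviews, memo)
            ) or (
                _args_match(gt[0], pt[1], gdoc, pdoc, gviews, pviews, memo)
                and _args_match(gt[1], pt[0], gdoc, pdoc, gviews, pviews, memo)
            )
    if ok:
        gc, pc = g["cause"], p["cause"]
        if (gc is None) != (pc is None):
            ok = False
        elif gc is not None:
            ok = _args_match(gc, pc, gdoc, pdoc, gviews, pviews, memo)
    memo[key] = ok
    return ok


def evaluate_corpus(gold: list[Document], predicted: list[Document]) -> EvalResult:
    """Recall/precision/F per type, per class and overall (percentages)."""
    gold_by_id = {d.doc_id: d for d in gold}
    pred_by_id = {d.doc_id: d for d in predicted}
    if set(gold_by_id) != set(pred_by_id):
        raise ValueError(
            "gold and predicted corpora cover different documents: "
            f"{sorted(set(gold_by_id) ^ set(pred_by_id))}"
        )
    result = EvalResult(
        per_type={t: Metrics() for t in EVENT_TYPES},
        per_class={c: Metrics() for c in EVENT_CLASSES},
    )
    for doc_id in sorted(gold_by_id):
        gdoc, pdoc = gold_by_id[doc_id], pred_by_id[doc_id]
        gviews, pviews = _event_view(gdoc), _event_view(pdoc)
        memo: dict = {}
        matched_gold: set[str] = set()
        matched_pred: set[str] = set()
        for pid in sorted(pviews):
            for gid in sorted(gviews):
                if gid in matched_gold:
                    continue
                if gviews[gid]["type"] != pviews[pid]["type"]:
                    continue
                if _events_match(gviews[gid], pviews[pid], gid, pid,
                                 gdoc, pdoc, gviews, pviews, memo):
                    matched_gold.add(gid)
                    matched_pred.add(pid)
                    break
        for gid, g in gviews.items():
            m = result.per_type[g["type"]]
            m.n_gold += 1
            if gid in matched_gold:
                m.tp += 1
        for pid, p in pviews.items():
            result.per_type[p["type"]].n_pred += 1
    for typ, m in result.per_type.items():
        result.per_class[event_class(typ)].add(m)
        result.total.add(m)
    return result
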