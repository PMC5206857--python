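"""End-to-end orchestration: corpus loading, training, prediction, rescoring.

Training: load the annotated corpus, build the trigger dictionary and
candidate pairs/triplets, construct the sequence database from labelled
positive pairs, mine frequent patterns, filter the unlabelled (negative)
candidates, extract features and fit the linear models.  A manifest records
the before/after sample counts and the realized positive:negative ratios.

Prediction: generate candidates over an unannotated corpus, filter, apply
the models, integrate pair/triplet predictions, compute the joint score
against the training context, drop predictions below delta, and write one
``.a2`` per document (plus a delimited score report).  The whole pipeline
is deterministic under a fixed seed.
"""

from __future__ import annotations

import glob
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib

from . import classify
from .candidates import (
    Argument,
    CandidatePair,
    CandidateTriplet,
    TriggerDictionary,
    generate_pairs,
    generate_triplets,
    label_candidates,
)
from .classify import EventPrediction, ModelBundle, PredictionSet, integrate
from .evaluate import EvalResult, evaluate_corpus
from .features import extract_pair_features, extract_triplet_features
from .jointscore import Rescorer, ScoreConfig, TriggerStats, filter_by_score
from .sample_select import (
    FilterConfig,
    build_sequence_db,
    filter_triplet_candidates,
    select_samples,
)
from .schema import NEGATIVE_LABEL, event_class
from .seqmine import FrequentPatternSet, mine_frequent_patterns
from .standoff import (
    Document,
    EventAnnotation,
    TriggerAnnotation,
    load_document,
    write_a2,
)

logger = logging.getLogger(__name__)

BUNDLE_FILENAME = "model_bundle.joblib"
PATTERNS_FILENAME = "patterns.tsv"
MANIFEST_FILENAME = "manifest.json"


@dataclass
class RunConfig:
    corpus_dir: str
    out_dir: str = "."
    filter: FilterConfig = field(default_factory=FilterConfig)
    score: ScoreConfig = field(default_factory=ScoreConfig)
    seed: int = 0
    hypernyms: Optional[dict] = None


@dataclass
class TrainArtifacts:
    bundle: ModelBundle
    patterns: FrequentPatternSet
    tdict: TriggerDictionary
    stats: TriggerStats
    # (tokens, trigger stems, event types) per training sentence
    sentences: list[tuple[list[str], set[str], set[str]]]
    manifest: dict

    def save(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        joblib.dump(self, os.path.join(out_dir, BUNDLE_FILENAME))
        with open(os.path.join(out_dir, PATTERNS_FILENAME), "w", encoding="utf-8") as fh:
            fh.write(self.patterns.dumps())
        with open(os.path.join(out_dir, MANIFEST_FILENAME), "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, out_dir: str) -> "TrainArtifacts":
        art = joblib.load(os.path.join(out_dir, BUNDLE_FILENAME))
        if art.bundle.version != classify.BUNDLE_VERSION:
            raise ValueError(
                f"model bundle version {art.bundle.version} is incompatible "
                f"with {classify.BUNDLE_VERSION}"
            )
        return art


def load_corpus(corpus_dir: str, with_events: bool = True) -> list[Document]:
    """Load every ``<id>.txt`` (+ .a1/.a2/.dep) document under a directory."""
    docs = []
    for txt in sorted(glob.glob(os.path.join(corpus_dir, "*.txt"))):
        base = txt[:-4]
        docs.append(
            load_document(
                txt,
                base + ".a1",
                base + ".a2" if with_events else None,
                base + ".dep",
            )
        )
    return docs


def _doc_candidates(doc: Document, tdict: TriggerDictionary):
    pairs: list[CandidatePair] = []
    triplets: list[CandidateTriplet] = []
    for sent in doc.sentences:
        pairs.extend(generate_pairs(doc, sent, tdict))
        triplets.extend(generate_triplets(doc, sent, tdict))
    return pairs, triplets


def _n_entities(doc: Document, sent_index: int) -> int:
    sent = doc.sentences[sent_index]
    return sum(
        1
        for p in doc.proteins
        if p.char_start >= sent.char_start and p.char_end <= sent.char_end
    )


def _pair_feats(doc: Document, pairs: Sequence[CandidatePair], hypernyms):
    return [
        extract_pair_features(
            p, doc.sentences[p.sent_index], _n_entities(doc, p.sent_index), hypernyms
        )
        for p in pairs
    ]


def _triplet_feats(doc: Document, triplets: Sequence[CandidateTriplet], hypernyms):
    return [
        extract_triplet_features(
            t, doc.sentences[t.sent_index], _n_entities(doc, t.sent_index), hypernyms
        )
        for t in triplets
    ]


def _training_sentences(docs: Sequence[Document]):
    """Sentence context index for the rescorer."""
    out = []
    for doc in docs:
        by_sent: dict[int, tuple[set, set]] = {}
        from .standoff import find_token

        for ev in doc.events:
            trig = doc.triggers[ev.trigger_id]
            s, _ = find_token(doc, trig.char_start, trig.char_end)
            stems, types = by_sent.setdefault(s, (set(), set()))
            from .standoff import stem as _stem

            stems.add(_stem(trig.text))
            types.add(ev.type)
        for sent in doc.sentences:
            stems, types = by_sent.get(sent.index, (set(), set()))
            out.append(([t.text for t in sent.tokens], stems, types))
    return out


def run_train(cfg: RunConfig) -> TrainArtifacts:
    """Full training pass; see the module docstring for the stage order."""
    docs = load_corpus(cfg.corpus_dir, with_events=True)
    if not docs:
        raise ValueError(f"empty corpus: {cfg.corpus_dir!r}")
    if not any(doc.events for doc in docs):
        raise ValueError("training corpus has no events")

    tdict = TriggerDictionary.from_documents(docs)
    all_pairs: list[tuple[Document, CandidatePair]] = []
    all_triplets: list[tuple[Document, CandidateTriplet]] = []
    for doc in docs:
        pairs, triplets = _doc_candidates(doc, tdict)
        label_candidates(doc, pairs, triplets)
        all_pairs.extend((doc, p) for p in pairs)
        all_triplets.extend((doc, t) for t in triplets)

    pos_pairs = [(d, p) for d, p in all_pairs if p.is_gold]
    neg_pairs = [(d, p) for d, p in all_pairs if not p.is_gold]
    pos_triplets = [(d, t) for d, t in all_triplets if t.is_gold]
    neg_triplets = [(d, t) for d, t in all_triplets if not t.is_gold]

    ds = build_sequence_db([p for _, p in pos_pairs])
    ls = mine_frequent_patterns(ds, cfg.filter.minsup)

    kept_neg_pairs, pair_report = select_samples(
        [p for _, p in neg_pairs], ls, cfg.filter
    )
    kept_ids = {id(p) for p in kept_neg_pairs}
    kept_neg = [(d, p) for d, p in neg_pairs if id(p) in kept_ids]
    kept_neg_triplets, trip_report = filter_triplet_candidates(
        [t for _, t in neg_triplets], ls, cfg.filter
    )
    kept_tids = {id(t) for t in kept_neg_triplets}
    kept_negt = [(d, t) for d, t in neg_triplets if id(t) in kept_tids]

    train_pairs = pos_pairs + kept_neg
    train_triplets = pos_triplets + kept_negt
    pair_X = [
        _pair_feats(d, [p], cfg.hypernyms)[0] for d, p in train_pairs
    ]
    pair_y = [p.label if p.is_gold else NEGATIVE_LABEL for _, p in train_pairs]
    trip_X = [
        _triplet_feats(d, [t], cfg.hypernyms)[0] for d, t in train_triplets
    ]
    trip_y = [t.label if t.is_gold else NEGATIVE_LABEL for _, t in train_triplets]

    bundle = classify.train(pair_X, pair_y, trip_X, trip_y, seed=cfg.seed)
    stats = TriggerStats.from_documents(docs)

    manifest = {
        "seed": cfg.seed,
        "minsup": cfg.filter.minsup,
        "theta": cfg.filter.theta,
        "sigma": cfg.score.sigma,
        "delta": cfg.score.delta,
        "n_documents": len(docs),
        "n_patterns": len(ls),
        "pairs": {
            "positive": len(pos_pairs),
            "negative_before": len(neg_pairs),
            "negative_after": len(kept_neg),
            "ratio_before": round(len(neg_pairs) / max(1, len(pos_pairs)), 3),
            "ratio_after": round(len(kept_neg) / max(1, len(pos_pairs)), 3),
            "no_path": pair_report.n_no_path,
        },
        "triplets": {
            "positive": len(pos_triplets),
            "negative_before": len(neg_triplets),
            "negative_after": len(kept_negt),
        },
    }
    logger.info("run_train manifest: %s", manifest)
    return TrainArtifacts(
        bundle=bundle,
        patterns=ls,
        tdict=tdict,
        stats=stats,
        sentences=_training_sentences(docs),
        manifest=manifest,
    )


# --------------------------------------------------------------------------
# prediction


def predict_documents(
    cfg: RunConfig,
    art: TrainArtifacts,
    docs: Sequence[Document],
    apply_delta: bool = True,
) -> tuple[list[EventPrediction], list[EventPrediction]]:
    """Candidates -> filter -> classify -> integrate -> joint score -> delta.

    Returns (kept, removed) predictions, each with score components filled.
    """
    all_events: list[EventPrediction] = []
    feats_by_id: dict[int, Document] = {}
    for doc in docs:
        pairs, triplets = _doc_candidates(doc, art.tdict)
        pairs, _ = select_samples(pairs, art.patterns, cfg.filter)
        triplets, _ = filter_triplet_candidates(triplets, art.patterns, cfg.filter)
        preds = classify.predict(
            art.bundle,
            pairs,
            _pair_feats(doc, pairs, cfg.hypernyms),
            triplets,
            _triplet_feats(doc, triplets, cfg.hypernyms),
        )
        events = integrate(preds)
        # schema sanity: only REG events may take an event (entity) Theme
        events = [
            e
            for e in events
            if e.theme.is_protein or event_class(e.type) == "REG"
        ]
        all_events.extend(events)
        feats_by_id[id(doc)] = doc

    doc_by_id = {doc.doc_id: doc for doc in docs}
    rescorer = Rescorer(art.stats, art.sentences, cfg.score)
    rescorer.score(
        all_events,
        sentence_tokens=lambda p: [
            t.text for t in doc_by_id[p.doc_id].sentences[p.sent_index].tokens
        ],
    )
    if not apply_delta:
        return all_events, []
    kept, removed = filter_by_score(all_events, cfg.score)
    return kept, removed


def predictions_to_document(doc: Document, preds: Sequence[EventPrediction]) -> Document:
    """Materialize predictions as a Document carrying .a2-style events.

    Event Themes referencing another prediction's trigger are resolved
    bottom-up (events with protein Themes first); predictions whose Theme
    event was not emitted are dropped with a log message.
    """
    out = Document(doc_id=doc.doc_id, text=doc.text, proteins=list(doc.proteins))
    out.sentences = doc.sentences
    next_t = (
        max((int(p.id[1:]) for p in doc.proteins), default=0)
    )
    trig_tid: dict[tuple[int, int], str] = {}
    events: list[EventAnnotation] = []
    eid_by_trigger: dict[tuple[int, int], str] = {}

    def trigger_id(pred: EventPrediction) -> str:
        nonlocal next_t
        key = (pred.sent_index, pred.trigger_index)
        tkey = key + (pred.type,)
        if tkey not in trig_tid:
            next_t += 1
            tok = doc.sentences[pred.sent_index].tokens[pred.trigger_index]
            tid = f"T{next_t}"
            out.triggers[tid] = TriggerAnnotation(
                tid, pred.type, tok.char_start, tok.char_end, tok.text
            )
            trig_tid[tkey] = tid
        return trig_tid[tkey]

    def arg_ref(a: Argument, sent_index: int) -> Optional[str]:
        if a.is_protein:
            return a.ref
        return eid_by_trigger.get((sent_index, a.token_index))

    first = [p for p in preds if p.theme.is_protein]
    second = [p for p in preds if not p.theme.is_protein]
    n_e = 0
    dropped = 0
    for wave in (first, second):
        for pred in wave:
            theme_ref = arg_ref(pred.theme, pred.sent_index)
            cause_ref = theme2_ref = None
            if pred.arg2 is not None:
                ref2 = arg_ref(pred.arg2, pred.sent_index)
                if ref2 is None:
                    dropped += 1
                    continue
                if pred.arg2_role == "Cause":
                    cause_ref = ref2
                else:
                    theme2_ref = ref2
            if theme_ref is None:
                dropped += 1
                continue
            n_e += 1
            eid = f"E{n_e}"
            ev = EventAnnotation(
                id=eid,
                type=pred.type,
                trigger_id=trigger_id(pred),
                theme=theme_ref,
                theme2=theme2_ref,
                cause=cause_ref,
            )
            events.append(ev)
            eid_by_trigger.setdefault((pred.sent_index, pred.trigger_index), eid)
    if dropped:
        logger.info(
            "%s: dropped %d prediction(s) with unresolved event Theme",
            doc.doc_id, dropped,
        )
    out.events = events
    return out


def run_predict(
    cfg: RunConfig, art: TrainArtifacts, corpus_dir: Optional[str] = None
) -> dict[str, Document]:
    """Predict over a corpus and write ``.a2`` files plus a score report."""
    docs = load_corpus(corpus_dir or cfg.corpus_dir, with_events=False)
    kept, removed = predict_documents(cfg, art, docs)
    os.makedirs(cfg.out_dir, exist_ok=True)
    result: dict[str, Document] = {}
    for doc in docs:
        doc_preds = [p for p in kept if p.doc_id == doc.doc_id]
        pdoc = predictions_to_document(doc, doc_preds)
        result[doc.doc_id] = pdoc
        with open(
            os.path.join(cfg.out_dir, f"{doc.doc_id}.a2"), "w", encoding="utf-8"
        ) as fh:
            fh.write(write_a2(pdoc.events, pdoc.triggers))
    report_lines = ["id\tP1\tP2\tP\tSim\tScore\tstatus"]
    for status, group in (("kept", kept), ("removed", removed)):
        for p in group:
            c = p.components
            report_lines.append(
                f"{p}\t{c['P1']:.4f}\t{c['P2']:.4f}\t{c['P']:.4f}"
                f"\t{c['Sim']:.4f}\t{c['Score']:.4f}\t{status}"
            )
    with open(
        os.path.join(cfg.out_dir, "score_report.tsv"), "w", encoding="utf-8"
    ) as fh:
        fh.write("\n".join(report_lines) + "\n")
    return result


# --------------------------------------------------------------------------
# baseline and evaluation helpers


def majority_baseline(docs: Sequence[Document], tdict: TriggerDictionary) -> list[EventPrediction]:
    """Naive baseline: every dictionary-matched token triggers one event of
    its majority type, with the nearest protein as Theme."""
    from .candidates import _sentence_proteins, _trigger_tokens

    preds: list[EventPrediction] = []
    for doc in docs:
        for sent in doc.sentences:
            proteins = _sentence_proteins(doc, sent)
            if not proteins:
                continue
            for c in _trigger_tokens(doc, sent, tdict):
                theme = min(
                    proteins, key=lambda a: (abs(a.token_index - c), a.token_index)
                )
                preds.append(
                    EventPrediction(
                        type=tdict.majority_type(sent.tokens[c].stem),
                        doc_id=doc.doc_id,
                        sent_index=sent.index,
                        trigger_index=c,
                        trigger_stem=sent.tokens[c].stem,
                        theme=theme,
                    )
                )
    return preds


def evaluate_predictions(
    gold_docs: Sequence[Document],
    preds: Sequence[EventPrediction],
) -> EvalResult:
    """Score raw predictions against gold documents (fixture corpora)."""
    pred_docs = []
    for doc in gold_docs:
        doc_preds = [p for p in preds if p.doc_id == doc.doc_id]
        pred_docs.append(predictions_to_document(doc, doc_preds))
    return evaluate_corpus(list(gold_docs), pred_docs)
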