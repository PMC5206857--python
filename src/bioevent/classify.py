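"""One-vs-rest linear classification of pairs/triplets and event integration.

Two multiclass linear SVMs are trained on the filtered samples: a pair
model over all nine event types plus an explicit negative class, and a
triplet model over the Binding/regulation types plus negative.  Prediction
assigns the argmax class with its decision margin.

Integration merges the two views into final events:

* a predicted Binding triplet (c, a_j, a_k) becomes one two-Theme Binding
  event, and the single-argument Binding pairs (c, a_j) and (c, a_k) are
  removed;
* a predicted REG triplet becomes an event with a_j as Theme and a_k as
  Cause (and covers the corresponding Theme pair);
* pairs untouched by any triplet of the same trigger are emitted directly;
  SVT pairs always are;
* when two pair predictions disagree on the type of the identical
  (trigger, argument), the higher-margin one wins (logged).

Regulation Themes may reference another predicted event's trigger
(nesting); references are resolved in one bottom-up pass when the events
are serialized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.svm import LinearSVC

from .candidates import Argument, CandidatePair, CandidateTriplet
from .schema import NEGATIVE_LABEL, event_class

logger = logging.getLogger(__name__)

BUNDLE_VERSION = 1


@dataclass
class PredictionSet:
    """Typed pair/triplet assignments with decision margins."""

    pairs: list[tuple[str, CandidatePair, float]] = field(default_factory=list)
    triplets: list[tuple[str, CandidateTriplet, float]] = field(default_factory=list)


@dataclass
class EventPrediction:
    """A final (possibly multi-argument) event with score components."""

    type: str
    doc_id: str
    sent_index: int
    trigger_index: int
    trigger_stem: str
    theme: Argument
    arg2: Optional[Argument] = None  # second Theme (Binding) or Cause (REG)
    arg2_role: Optional[str] = None  # "Theme2" | "Cause"
    margin: float = 0.0
    components: dict = field(default_factory=dict)

    def __str__(self) -> str:  # used in filter logs
        return (
            f"{self.type}@{self.doc_id}:s{self.sent_index}:t{self.trigger_index}"
        )


@dataclass
class _Model:
    vectorizer: DictVectorizer
    clf: Optional[LinearSVC]
    constant_label: Optional[str] = None  # when training had a single class


@dataclass
class ModelBundle:
    pair_model: _Model
    triplet_model: _Model
    seed: int
    version: int = BUNDLE_VERSION


def _as_int32(X):
    X = X.tocsr()
    X.indices = X.indices.astype(np.int32)
    X.indptr = X.indptr.astype(np.int32)
    return X


def _fit(features: Sequence[Mapping[str, float]], labels: Sequence[str],
         seed: int, class_weight) -> _Model:
    vec = DictVectorizer(sparse=True)
    if not features:
        return _Model(vec, None, constant_label=NEGATIVE_LABEL)
    X = _as_int32(vec.fit_transform(features))
    classes = sorted(set(labels))
    if len(classes) == 1:
        logger.warning("single-class training set (%s); model is constant", classes[0])
        return _Model(vec, None, constant_label=classes[0])
    clf = LinearSVC(C=1.0, class_weight=class_weight, random_state=seed, max_iter=5000)
    clf.fit(X, labels)
    return _Model(vec, clf)


def _decide(model: _Model, features: Sequence[Mapping[str, float]]):
    """(label, margin) per sample; constant models yield margin 0."""
    if not features:
        return []
    if model.clf is None:
        return [(model.constant_label, 0.0)] * len(features)
    X = _as_int32(model.vectorizer.transform(features))
    scores = model.clf.decision_function(X)
    classes = list(model.clf.classes_)
    out = []
    if scores.ndim == 1:  # binary: positive score -> classes_[1]
        for s in scores:
            label = classes[1] if s > 0 else classes[0]
            out.append((label, abs(float(s))))
    else:
        for row in scores:
            i = int(np.argmax(row))
            out.append((classes[i], float(row[i])))
    return out


def train(
    pair_features: Sequence[Mapping[str, float]],
    pair_labels: Sequence[str],
    triplet_features: Sequence[Mapping[str, float]],
    triplet_labels: Sequence[str],
    seed: int = 0,
    class_weight: Optional[str] = "balanced",
) -> ModelBundle:
    """Fit the pair and triplet one-vs-rest linear models.

    Training sets are the selected (filtered) candidates; a class absent
    from the data is simply never predicted.  Deterministic given ``seed``.
    """
    pair_model = _fit(pair_features, pair_labels, seed, class_weight)
    triplet_model = _fit(triplet_features, triplet_labels, seed, class_weight)
    return ModelBundle(pair_model, triplet_model, seed=seed)


def predict(
    bundle: ModelBundle,
    pairs: Sequence[CandidatePair],
    pair_features: Sequence[Mapping[str, float]],
    triplets: Sequence[CandidateTriplet],
    triplet_features: Sequence[Mapping[str, float]],
) -> PredictionSet:
    """Assign types/margins; only positive (non-neg) assignments are kept."""
    preds = PredictionSet()
    for cand, (label, margin) in zip(pairs, _decide(bundle.pair_model, pair_features)):
        if label != NEGATIVE_LABEL:
            preds.pairs.append((label, cand, margin))
    for cand, (label, margin) in zip(
        triplets, _decide(bundle.triplet_model, triplet_features)
    ):
        if label != NEGATIVE_LABEL:
            # the triplet model only covers multi-argument classes
            if event_class(label) == "SVT":
                continue
            preds.triplets.append((label, cand, margin))
    return preds


def _argkey(a: Argument):
    return (a.kind, a.ref, a.token_index)


def integrate(preds: PredictionSet) -> list[EventPrediction]:
    """Merge pair and triplet predictions into final events."""
    # resolve pair conflicts: identical (trigger, argument), different types
    best_pairs: dict[tuple, tuple[str, CandidatePair, float]] = {}
    for label, cand, margin in preds.pairs:
        key = (cand.doc_id, cand.sent_index, cand.trigger_index, _argkey(cand.argument))
        cur = best_pairs.get(key)
        if cur is not None and cur[0] != label:
            logger.info(
                "integrate: type conflict at %s: %s vs %s", key, cur[0], label
            )
        if cur is None or margin > cur[2]:
            best_pairs[key] = (label, cand, margin)

    events: list[EventPrediction] = []
    covered: set[tuple] = set()
    seen_triplets: set[tuple] = set()
    for label, cand, margin in sorted(
        preds.triplets, key=lambda t: -t[2]
    ):
        cls = event_class(label)
        k1, k2 = _argkey(cand.arg1), _argkey(cand.arg2)
        tkey = (
            cand.doc_id, cand.sent_index, cand.trigger_index, label,
            frozenset((k1, k2)) if cls == "BIND" else (k1, k2),
        )
        if tkey in seen_triplets:
            continue
        seen_triplets.add(tkey)
        trig_key = (cand.doc_id, cand.sent_index, cand.trigger_index)
        if cls == "BIND":
            covered.add(trig_key + (label, k1))
            covered.add(trig_key + (label, k2))
            events.append(
                EventPrediction(
                    type=label,
                    doc_id=cand.doc_id,
                    sent_index=cand.sent_index,
                    trigger_index=cand.trigger_index,
                    trigger_stem=cand.trigger_stem,
                    theme=cand.arg1,
                    arg2=cand.arg2,
                    arg2_role="Theme2",
                    margin=margin,
                )
            )
        else:  # REG: arg2 is emitted as the Cause argument
            covered.add(trig_key + (label, k1))
            events.append(
                EventPrediction(
                    type=label,
                    doc_id=cand.doc_id,
                    sent_index=cand.sent_index,
                    trigger_index=cand.trigger_index,
                    trigger_stem=cand.trigger_stem,
                    theme=cand.arg1,
                    arg2=cand.arg2,
                    arg2_role="Cause",
                    margin=margin,
                )
            )

    for key, (label, cand, margin) in sorted(best_pairs.items(), key=lambda kv: kv[0]):
        trig_key = (cand.doc_id, cand.sent_index, cand.trigger_index)
        if trig_key + (label, _argkey(cand.argument)) in covered:
            continue  # subsumed by a triplet of the same trigger
        events.append(
            EventPrediction(
                type=label,
                doc_id=cand.doc_id,
                sent_index=cand.sent_index,
                trigger_index=cand.trigger_index,
                trigger_stem=cand.trigger_stem,
                theme=cand.argument,
                margin=margin,
            )
        )
    events.sort(
        key=lambda e: (e.doc_id, e.sent_index, e.trigger_index, e.type,
                       _argkey(e.theme), _argkey(e.arg2) if e.arg2 else ())
    )
    return events
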