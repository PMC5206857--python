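"""Joint rescoring of predicted events: sentence similarity x trigger importance.

Sample selection raises recall at the expense of precision, so predictions
are post-processed with a joint score combining two signals:

* Sim(s', d) — the maximum semantic relevance between the sentence s' of a
  prediction and the training sentences d that contain the same trigger
  (0 when d is empty).  Relevance is the cosine of fixed-length sentence
  embeddings.  The default backend is a deterministic letter-trigram
  bag-of-words embedding; a convolutional deep-structured semantic model
  (C-DSSM) style backend with loadable or seeded-random weights is also
  provided (its training on web-scale clickthrough data is out of scope).

* P_ti — the importance of the trigger t_i for type typ in training data:
  P1 = f(t_i^typ) / sum_typ f(t_i^typ) (type-conditional fraction),
  P2 = sum_typ f(t_i^typ) / sum_{t in D} f(t) (share of all triggers),
  P_ti = (w1*P1 + w2*P2) / (w1 + w2), with w1 the number of (t_i, typ)
  predictions and w2 the number of t_i predictions in the predicted set.

The joint score is Score = (1 - sigma) * P_ti + sigma * Sim with sigma in
[0, 1] (default 0.7: similarity is the stronger corrector); predictions
with Score below delta (default 0.5) are discarded as false positives.
Negative cosines are clamped to 0 first so that Score stays in [0, 1] and
delta has a meaningful [0, 1] range.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .standoff import Document, stem as _stem

logger = logging.getLogger(__name__)

Vector = Union[np.ndarray, dict]


# --------------------------------------------------------------------------
# word hashing and similarity backends


def word_hash(term: str, n: int = 3) -> dict[str, int]:
    """Letter n-gram counts of '#term#' (word-boundary marks)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not term:
        return {}
    marked = f"#{term}#"
    counts: Counter = Counter(
        marked[i : i + n] for i in range(max(0, len(marked) - n + 1))
    )
    return dict(counts)


def _gram_index(gram: str, dim: int) -> int:
    digest = hashlib.md5(gram.encode("utf-8")).hexdigest()
    return int(digest, 16) % dim


def hashed_word_vector(term: str, dim: int, n: int = 3) -> np.ndarray:
    v = np.zeros(dim)
    for gram, count in word_hash(term, n).items():
        v[_gram_index(gram, dim)] += count
    return v


class TrigramBackend:
    """Deterministic letter-trigram bag-of-words sentence embedding.

    The sentence vector is the sum of the (hashed) trigram count vectors of
    its tokens.  No learned weights: all runs produce identical embeddings.
    """

    name = "trigram"

    def __init__(self, dim: int = 2048, n: int = 3) -> None:
        self.dim = dim
        self.n = n

    def embed(self, tokens: Sequence[str]) -> np.ndarray:
        v = np.zeros(self.dim)
        for tok in tokens:
            v += hashed_word_vector(tok.lower(), self.dim, self.n)
        return v


class CDSSMBackend:
    """C-DSSM-style sentence embedding: word hashing, a convolution over a
    sliding token window, element-wise max pooling, and a non-linear
    semantic layer (tanh by convention; configurable).

    Weights are loadable (``weights`` mapping of arrays) or drawn from a
    seeded RNG; the model is applied, never trained, here.
    """

    name = "cdssm"

    def __init__(
        self,
        dim: int = 2048,
        latent_dim: int = 128,
        conv_dim: int = 64,
        semantic_dim: int = 32,
        window: int = 3,
        pooling: str = "max",
        activation: str = "tanh",
        seed: int = 0,
        weights: Optional[dict] = None,
    ) -> None:
        if pooling not in ("max", "sum"):
            raise ValueError(f"unknown pooling {pooling!r}")
        if activation not in ("tanh", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        self.dim, self.window = dim, window
        self.pooling, self.activation = pooling, activation
        if weights is not None:
            self.W1 = np.asarray(weights["W1"])
            self.Wc = np.asarray(weights["Wc"])
            self.bc = np.asarray(weights["bc"])
            self.Ws = np.asarray(weights["Ws"])
            self.bs = np.asarray(weights["bs"])
        else:
            rng = np.random.default_rng(seed)
            self.W1 = rng.normal(0, 0.1, (latent_dim, dim))
            self.Wc = rng.normal(0, 0.1, (conv_dim, window * latent_dim))
            self.bc = np.zeros(conv_dim)
            self.Ws = rng.normal(0, 0.1, (semantic_dim, conv_dim))
            self.bs = np.zeros(semantic_dim)
        lat = self.W1.shape[0]
        if self.Wc.shape[1] != self.window * lat:
            raise ValueError(
                f"convolution weights expect window*latent = {self.Wc.shape[1]}, "
                f"got {self.window}*{lat}"
            )
        if self.Ws.shape[1] != self.Wc.shape[0]:
            raise ValueError("semantic weights do not match convolution output")

    @classmethod
    def identity(cls, dim: int) -> "CDSSMBackend":
        """Degenerate configuration reproducing the trigram-bag embedding:
        window 1, identity weights, linear activation, sum pooling."""
        eye = np.eye(dim)
        return cls(
            dim=dim,
            window=1,
            pooling="sum",
            activation="linear",
            weights={"W1": eye, "Wc": eye, "bc": np.zeros(dim),
                     "Ws": eye, "bs": np.zeros(dim)},
        )

    def _f(self, x: np.ndarray) -> np.ndarray:
        return np.tanh(x) if self.activation == "tanh" else x

    def embed(self, tokens: Sequence[str]) -> np.ndarray:
        if not tokens:
            return np.zeros(self.Ws.shape[0])
        hashed = [hashed_word_vector(t.lower(), self.dim) for t in tokens]
        latent = [self.W1 @ h for h in hashed]  # l1 = W1 x, linear
        pad = self.window // 2
        zeros = [np.zeros_like(latent[0])] * pad
        padded = zeros + latent + zeros
        convs = []
        for i in range(len(latent)):
            win = np.concatenate(padded[i : i + self.window])
            convs.append(self._f(self.Wc @ win + self.bc))
        stack = np.stack(convs)
        pooled = stack.max(axis=0) if self.pooling == "max" else stack.sum(axis=0)
        return self._f(self.Ws @ pooled + self.bs)


def cdssm_forward(tokens: Sequence[str], model: CDSSMBackend) -> np.ndarray:
    """Forward pass of the C-DSSM backend for one sentence."""
    return model.embed(tokens)


def make_backend(name: str, **kwargs):
    if name == "trigram":
        return TrigramBackend(**{k: v for k, v in kwargs.items() if k in ("dim", "n")})
    if name == "cdssm":
        return CDSSMBackend(**kwargs)
    raise ValueError(f"unknown similarity backend {name!r}")


def relevance(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two semantic vectors, in [-1, 1]; 0 for a zero
    vector (with a warning)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = float(np.linalg.norm(a)), float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        warnings.warn("relevance of a zero vector is defined as 0", stacklevel=2)
        return 0.0
    return float(a @ b / (na * nb))


def sentence_similarity(
    s_prime: Sequence[str],
    d: Iterable[Sequence[str]],
    backend=None,
) -> float:
    """max_i relevance(embed(s'), embed(s_i)) over s_i in d; 0 if d is empty."""
    backend = backend or TrigramBackend()
    d = list(d)
    if not d:
        return 0.0
    e = backend.embed(list(s_prime))
    return max(relevance(e, backend.embed(list(s))) for s in d)


# --------------------------------------------------------------------------
# trigger importance


@dataclass
class TriggerStats:
    """Per-trigger, per-type event counts from training annotations.

    Counts are event instances (how often a stem triggers each type in the
    gold .a2 files), not raw token frequencies.
    """

    type_counts: dict[str, Counter] = field(default_factory=dict)

    @classmethod
    def from_documents(cls, docs: Iterable[Document]) -> "TriggerStats":
        stats = cls()
        for doc in docs:
            for ev in doc.events:
                trig = doc.triggers[ev.trigger_id]
                stats.type_counts.setdefault(_stem(trig.text), Counter())[ev.type] += 1
        return stats

    def trigger_total(self, stem: str) -> int:
        return sum(self.type_counts.get(stem, {}).values())

    @property
    def grand_total(self) -> int:
        return sum(sum(c.values()) for c in self.type_counts.values())

    def p1(self, stem: str, typ: str) -> float:
        total = self.trigger_total(stem)
        if total == 0:
            return 0.0
        return self.type_counts[stem].get(typ, 0) / total

    def p2(self, stem: str) -> float:
        grand = self.grand_total
        if grand == 0:
            return 0.0
        return self.trigger_total(stem) / grand


def trigger_importance(
    stem: str,
    typ: str,
    stats: TriggerStats,
    w1: int,
    w2: int,
) -> tuple[float, float, float]:
    """(P1, P2, P_ti) for trigger ``stem`` and event type ``typ``.

    ``w1`` is the number of (stem, typ) predictions and ``w2`` the number of
    stem predictions in the predicted result set.  Unseen triggers yield
    P1 = P2 = 0 (logged); w1 + w2 = 0 is an error (the weighted mean is
    undefined).
    """
    if w1 + w2 <= 0:
        raise ValueError("w1 + w2 must be positive")
    if stats.trigger_total(stem) == 0:
        logger.info("trigger_importance: unseen trigger %r", stem)
        return 0.0, 0.0, 0.0
    p1 = stats.p1(stem, typ)
    p2 = stats.p2(stem)
    p = (w1 * p1 + w2 * p2) / (w1 + w2)
    return p1, p2, p


# --------------------------------------------------------------------------
# joint score and filtering


@dataclass
class ScoreConfig:
    sigma: float = 0.7
    delta: float = 0.5
    backend: str = "trigram"
    backend_kwargs: dict = field(default_factory=dict)
    same_type_context: bool = False  # restrict d to sentences of same event type

    def __post_init__(self) -> None:
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError("sigma must be in [0, 1]")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [0, 1]")


def joint_score(p_ti: float, sim: float, cfg: ScoreConfig) -> float:
    """(1 - sigma) * P_ti + sigma * Sim, with negative Sim clamped to 0."""
    sim = max(0.0, sim)
    return (1.0 - cfg.sigma) * p_ti + cfg.sigma * sim


def filter_by_score(preds: Sequence, cfg: ScoreConfig) -> tuple[list, list]:
    """Partition predictions into (kept, removed) by Score >= delta.

    Each prediction must expose ``components["Score"]``; removed ones are
    logged with their score components.
    """
    kept, removed = [], []
    for p in preds:
        (kept if p.components["Score"] >= cfg.delta else removed).append(p)
    for p in removed:
        logger.info("filter_by_score: removed %s (%s)", p, p.components)
    return kept, removed


class Rescorer:
    """Scores a predicted result set against training-corpus context.

    Holds the trigger statistics and a stem -> training-sentence index; for
    each prediction computes Sim, P1/P2/P_ti and the joint Score, storing
    them in ``prediction.components``.
    """

    def __init__(
        self,
        stats: TriggerStats,
        sentences: Sequence[tuple[list[str], set[str], set[str]]],
        cfg: Optional[ScoreConfig] = None,
    ) -> None:
        """``sentences``: (tokens, trigger stems, event types) per training
        sentence."""
        self.stats = stats
        self.cfg = cfg or ScoreConfig()
        self.backend = make_backend(self.cfg.backend, **self.cfg.backend_kwargs)
        self._sentences = list(sentences)
        self._emb = [self.backend.embed(toks) for toks, _, _ in self._sentences]
        self._norms = np.array([float(np.linalg.norm(e)) for e in self._emb])
        self._matrix = np.stack(self._emb) if self._emb else np.zeros((0, 1))

    def _similarity(self, tokens: Sequence[str], stem: str, typ: str) -> float:
        idxs = [
            i
            for i, (_, stems, types) in enumerate(self._sentences)
            if stem in stems and (not self.cfg.same_type_context or typ in types)
        ]
        if not idxs:
            return 0.0
        e = self.backend.embed(list(tokens))
        ne = float(np.linalg.norm(e))
        if ne == 0.0:
            return 0.0
        sub = self._matrix[idxs]
        norms = self._norms[idxs]
        ok = norms > 0
        if not ok.any():
            return 0.0
        sims = (sub[ok] @ e) / (norms[ok] * ne)
        return float(sims.max())

    def score(self, preds: Sequence, sentence_tokens) -> None:
        """Fill ``components`` for every prediction in place.

        ``sentence_tokens``: callable mapping a prediction to the token
        texts of its sentence s'.
        """
        w2_counts: Counter = Counter(p.trigger_stem for p in preds)
        w1_counts: Counter = Counter((p.trigger_stem, p.type) for p in preds)
        sim_cache: dict[tuple, float] = {}
        for p in preds:
            p1, p2, p_ti = trigger_importance(
                p.trigger_stem, p.type, self.stats,
                w1=w1_counts[(p.trigger_stem, p.type)],
                w2=w2_counts[p.trigger_stem],
            )
            key = (p.doc_id, p.sent_index, p.trigger_stem, p.type)
            if key not in sim_cache:
                sim_cache[key] = self._similarity(
                    sentence_tokens(p), p.trigger_stem, p.type
                )
            sim = sim_cache[key]
            p.components = {
                "P1": p1,
                "P2": p2,
                "P": p_ti,
                "Sim": sim,
                "Score": joint_score(p_ti, sim, self.cfg),
            }
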