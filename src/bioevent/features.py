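"""Sparse feature extraction for candidate pairs and triplets.

Four feature groups, following the usual design of feature-based event
extraction systems:

* token features — base stem, character n-grams (n = 1..3), POS tag and
  spelling shape of the trigger and argument head tokens;
* sentence features — candidate-entity count and bag of stems;
* dependency features — label chains up to a configurable depth from the
  trigger, plus the label sequence (and its bigrams and token stems) along
  the shortest trigger->argument path;
* external-resource features — optional stem -> hypernym-list lookup,
  off by default so no download is required.

A relative-position feature (argument before/after the trigger) is
included: Cause arguments typically precede regulation triggers while
Themes follow them.  Extraction is pure: the same candidate always yields
the identical map.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from .candidates import Argument, CandidatePair, CandidateTriplet
from .standoff import Sentence, Token

CHAIN_DEPTH = 3


def token_shape(text: str) -> str:
    """Collapsed capitalisation/digit shape, e.g. 'IRF-4' -> 'X-d'."""
    out: list[str] = []
    for ch in text:
        if ch.isupper():
            c = "X"
        elif ch.islower():
            c = "x"
        elif ch.isdigit():
            c = "d"
        else:
            c = ch
        if not out or out[-1] != c:
            out.append(c)
    return "".join(out)


def char_ngrams(text: str, n: int) -> list[str]:
    if n < 1:
        raise ValueError("n must be >= 1")
    return [text[i : i + n] for i in range(max(0, len(text) - n + 1))]


def _token_features(tok: Token, prefix: str, out: dict[str, float]) -> None:
    out[f"{prefix}stem={tok.stem}"] = 1.0
    out[f"{prefix}pos={tok.pos}"] = 1.0
    out[f"{prefix}shape={token_shape(tok.text)}"] = 1.0
    if any(c.isdigit() for c in tok.text):
        out[f"{prefix}has_digit"] = 1.0
    if "-" in tok.text:
        out[f"{prefix}has_hyphen"] = 1.0
    if tok.text[:1].isupper():
        out[f"{prefix}init_cap"] = 1.0
    low = tok.text.lower()
    for n in (1, 2, 3):
        for g in char_ngrams(low, n):
            out[f"{prefix}ng{n}={g}"] = out.get(f"{prefix}ng{n}={g}", 0.0) + 1.0


def _sentence_features(sent: Sentence, n_entities: int, out: dict[str, float]) -> None:
    out["n_entities"] = float(n_entities)
    for tok in sent.tokens:
        out[f"bow={tok.stem}"] = 1.0


def _chain_features(sent: Sentence, trigger_index: int, out: dict[str, float]) -> None:
    """Dependency label chains up to CHAIN_DEPTH from the trigger token."""
    adj: dict[int, list[tuple[int, str]]] = {}
    for gov, dep, lab in sorted(sent.deps.edges):
        adj.setdefault(gov, []).append((dep, lab))
        adj.setdefault(dep, []).append((gov, lab))
    frontier = [(trigger_index, ())]
    visited = {trigger_index}
    for _ in range(CHAIN_DEPTH):
        nxt = []
        for node, chain in frontier:
            for other, lab in adj.get(node, ()):
                if other in visited:
                    continue
                visited.add(other)
                new_chain = chain + (lab,)
                out[f"chain={'.'.join(new_chain)}"] = 1.0
                nxt.append((other, new_chain))
        frontier = nxt


def _path_features(sent: Sentence, path: Optional[Sequence[str]],
                   trigger_index: int, arg: Argument, prefix: str,
                   out: dict[str, float]) -> None:
    if path is None:
        out[f"{prefix}no_path"] = 1.0
        return
    labels = tuple(path)
    out[f"{prefix}path={'.'.join(labels)}"] = 1.0
    out[f"{prefix}path_len"] = float(len(labels))
    for lab in labels:
        out[f"{prefix}pathlab={lab}"] = 1.0
    for a, b in zip(labels, labels[1:]):
        out[f"{prefix}pathbi={a}.{b}"] = 1.0
    out[f"{prefix}arg_{'before' if arg.token_index < trigger_index else 'after'}"] = 1.0


def _external_features(stem: str, prefix: str,
                       hypernyms: Optional[Mapping[str, Sequence[str]]],
                       out: dict[str, float]) -> None:
    if not hypernyms:
        return
    for h in hypernyms.get(stem, ()):
        out[f"{prefix}hyper={h}"] = 1.0


def extract_pair_features(
    cand: CandidatePair,
    sent: Sentence,
    n_entities: int,
    hypernyms: Optional[Mapping[str, Sequence[str]]] = None,
) -> dict[str, float]:
    out: dict[str, float] = {}
    trig = sent.tokens[cand.trigger_index]
    arg_tok = sent.tokens[cand.argument.token_index]
    _token_features(trig, "trg_", out)
    _token_features(arg_tok, "arg_", out)
    out[f"arg_kind={cand.argument.kind}"] = 1.0
    _sentence_features(sent, n_entities, out)
    _chain_features(sent, cand.trigger_index, out)
    _path_features(sent, cand.path, cand.trigger_index, cand.argument, "", out)
    if cand.path:
        for i in _path_token_indices(sent, cand.trigger_index, cand.argument.token_index):
            out[f"pathtok={sent.tokens[i].stem}"] = 1.0
    _external_features(trig.stem, "trg_", hypernyms, out)
    _external_features(arg_tok.stem, "arg_", hypernyms, out)
    return out


def extract_triplet_features(
    cand: CandidateTriplet,
    sent: Sentence,
    n_entities: int,
    hypernyms: Optional[Mapping[str, Sequence[str]]] = None,
) -> dict[str, float]:
    out: dict[str, float] = {}
    trig = sent.tokens[cand.trigger_index]
    _token_features(trig, "trg_", out)
    _token_features(sent.tokens[cand.arg1.token_index], "arg1_", out)
    _token_features(sent.tokens[cand.arg2.token_index], "arg2_", out)
    out[f"ordered={cand.ordered}"] = 1.0
    _sentence_features(sent, n_entities, out)
    _chain_features(sent, cand.trigger_index, out)
    _path_features(sent, cand.path1, cand.trigger_index, cand.arg1, "p1_", out)
    _path_features(sent, cand.path2, cand.trigger_index, cand.arg2, "p2_", out)
    _external_features(trig.stem, "trg_", hypernyms, out)
    return out


def _path_token_indices(sent: Sentence, src: int, dst: int) -> list[int]:
    """Interior token indices of the shortest path (BFS over the edges)."""
    adj: dict[int, list[int]] = {}
    for gov, dep, _ in sorted(sent.deps.edges):
        adj.setdefault(gov, []).append(dep)
        adj.setdefault(dep, []).append(gov)
    prev: dict[int, int] = {src: src}
    frontier = [src]
    while frontier and dst not in prev:
        nxt = []
        for node in frontier:
            for other in adj.get(node, ()):
                if other not in prev:
                    prev[other] = node
                    nxt.append(other)
        frontier = nxt
    if dst not in prev:
        return []
    chain = []
    node = prev[dst]
    while node != src:
        chain.append(node)
        node = prev[node]
    return chain[::-1]


def serialize_features(feats: Mapping[str, float]) -> str:
    """Sparse 'name:value' line for classifier interchange."""
    return " ".join(
        f"{name.replace(' ', '_')}:{feats[name]:g}" for name in sorted(feats)
    )
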