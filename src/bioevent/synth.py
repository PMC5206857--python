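"""Synthetic standoff corpora for exercising the extraction pipeline.

Real GENIA-style corpora cannot ship with the package, so this module
generates small, fully-annotated stand-ins: ``.txt``/``.a1``/``.a2`` files
plus a typed-dependency edge file per document.  The corpora are synthetic
and deliberately simple, but emulate the properties the pipeline's design
responds to:

* a trigger lexicon with type-skewed frequencies (some surface forms are
  ambiguous between event types);
* all nine event types with correct argument arity, including REG events
  nested over SVT events (depth 2);
* dependency-label paths whose distributions differ between positive and
  negative trigger-argument pairs: positive Theme/Cause paths are drawn
  from a small pool, negative paths from a broader, stratified pool — so
  the sequential-pattern filter has signal;
* a configurable candidate-pair positive:negative imbalance (default
  1:13.163, matching the class skew of annotated event corpora).

The negative-path strata are sized by their match count F against the
subsequence closure of the positive pool (F = 0/1/2/3/high with weights
0.20/0.15/0.15/0.25/0.25), so that at a selection threshold of 2 roughly
half of the negatives fall below the threshold.  Role direction follows
the usual linear order of regulation statements ("IFN-alpha induced ...
expression"): Cause arguments precede the trigger, Themes follow it.

Everything is deterministic given the seed: running the generator twice
with the same arguments produces byte-identical corpora.
"""

from __future__ import annotations

import json
import os
import random
from dataclasses import dataclass, field

from .schema import BIND_TYPES, EVENT_TYPES, REG_TYPES, SVT_TYPES, event_class
from .standoff import stem

# --------------------------------------------------------------------------
# lexicons and path pools

# surface -> {event type: relative frequency}; "regulation" is deliberately
# ambiguous so that trigger-importance P1 is strictly below 1 for it.
TRIGGER_LEXICON: dict[str, dict[str, int]] = {
    "expression": {"Gene_expression": 8},
    "production": {"Gene_expression": 2},
    "transcription": {"Transcription": 4},
    "degradation": {"Protein_catabolism": 2},
    "secretion": {"Localization": 2},
    "localization": {"Localization": 1},
    "phosphorylation": {"Phosphorylation": 3},
    "binding": {"Binding": 4},
    "interaction": {"Binding": 1},
    "regulation": {"Regulation": 4, "Positive_regulation": 1},
    "induced": {"Positive_regulation": 4},
    "activation": {"Positive_regulation": 3},
    "upregulation": {"Positive_regulation": 1},
    "inhibition": {"Negative_regulation": 3},
    "suppressed": {"Negative_regulation": 1},
}

# corpus-level skew over event types (simple and positive regulation
# dominate, as in annotated event corpora)
TYPE_WEIGHTS: dict[str, float] = {
    "Gene_expression": 0.24,
    "Transcription": 0.07,
    "Protein_catabolism": 0.03,
    "Localization": 0.05,
    "Phosphorylation": 0.06,
    "Binding": 0.13,
    "Regulation": 0.09,
    "Positive_regulation": 0.23,
    "Negative_regulation": 0.10,
}

PROTEIN_NAMES = [
    "IRF-4", "IFN-alpha", "IL-2", "IL-4", "TNF-alpha", "NF-kappaB",
    "STAT1", "STAT3", "p53", "p65", "CD28", "CD40", "TRAF2", "GATA3",
    "FOXP3", "JAK2", "SOCS1", "TLR4", "MYC", "BCL-2", "CREB1", "ERK2",
    "RELA", "SPI1", "TBX21", "CTLA-4", "ICAM-1", "VCAM-1", "CXCR4",
    "IL-10", "IL-6", "TGF-beta", "NFAT1", "IKK-beta", "MAPK1",
]

FILLERS = [
    "of", "in", "by", "with", "to", "the", "cells", "levels",
    "protein", "gene", "activity", "pathway", "response", "signal",
]

# Positive Theme paths: the small pool whose subsequence closure is what
# the miner recovers (12 patterns over {nsubj, dobj, prep_of, nn, amod}).
THEME_PATHS: list[tuple[str, ...]] = [
    ("nsubj", "dobj"),
    ("nsubj", "prep_of", "nn"),
    ("amod", "nn"),
    ("dobj", "prep_of"),
    ("nsubj", "nn"),
    ("prep_of", "nn"),
]
# Cause chains reuse positive-pool subsequences with match count >= 3, so
# predicted REG triplets can pass the both-path pattern filter.
CAUSE_PATHS: list[tuple[str, ...]] = [
    ("nsubj", "dobj"),
    ("nsubj", "prep_of", "nn"),
    ("nsubj", "nn"),
]
# Chains linking a REG trigger to a nested event's trigger.
EVENT_THEME_PATHS: list[tuple[str, ...]] = [
    ("nsubj", "prep_of", "nn"),
    ("dobj", "prep_of"),
]

# Negative paths, stratified by match count F against the closure of
# THEME_PATHS.  (path, stratum weight).
NEGATIVE_PATHS: list[tuple[tuple[str, ...], float]] = [
    # F = 0 (disjoint labels), total weight 0.20
    (("prep_in", "pobj"), 0.05),
    (("advmod", "prep_to"), 0.04),
    (("conj_and", "appos"), 0.03),
    (("det", "mark"), 0.03),
    (("prep_to", "pobj", "advmod"), 0.03),
    (("aux", "xcomp"), 0.02),
    # F = 1, total weight 0.15
    (("prep_in", "nn"), 0.05),
    (("advmod", "dobj"), 0.04),
    (("nsubj", "prep_to"), 0.03),
    (("prep_to", "amod"), 0.03),
    # F = 2, total weight 0.15
    (("prep_in", "nn", "dobj"), 0.05),
    (("dobj", "prep_in", "nsubj"), 0.05),
    (("nn", "conj_and", "amod"), 0.05),
    # F = 3, total weight 0.25
    (("amod", "prep_to", "nn"), 0.13),
    (("nsubj", "advmod", "dobj"), 0.12),
    # F high (5 and 9), total weight 0.25
    (("nsubj", "amod", "prep_of", "nn"), 0.13),
    (("dobj", "prep_of", "nn"), 0.12),
]


# --------------------------------------------------------------------------
# sentence assembly


@dataclass
class _Block:
    labels: tuple[str, ...]
    terminal: str
    tag: str  # "theme" | "theme2" | "cause" | "evtheme" | "neg"


@dataclass
class _SentencePlan:
    tokens: list[str] = field(default_factory=list)
    edges: list[tuple[int, int, str]] = field(default_factory=list)
    # (token idx, surface, event type or None for decoy use)
    triggers: list[tuple[int, str, str | None]] = field(default_factory=list)
    proteins: list[tuple[int, str]] = field(default_factory=list)
    # event descriptors: (type, trigger tok idx, theme ref, theme2 ref, cause ref)
    # refs are ("prot", tok idx) or ("event", local event number)
    events: list[tuple] = field(default_factory=list)
    n_positive_pairs: int = 0

    def n_candidate_pairs(self) -> int:
        nt, np_ = len(self.triggers), len(self.proteins)
        return nt * (np_ + nt - 1)


def _append_block(plan: _SentencePlan, rng: random.Random, root_idx: int,
                  block: _Block) -> int:
    """Append a dependency chain root -> ... -> terminal; returns terminal idx."""
    fillers = [rng.choice(FILLERS) for _ in range(len(block.labels) - 1)]
    prev = root_idx
    terminal_idx = -1
    for lab, word in zip(block.labels, fillers + [block.terminal]):
        idx = len(plan.tokens)
        plan.tokens.append(word)
        plan.edges.append((prev, idx, lab))
        prev = idx
        terminal_idx = idx
    return terminal_idx


def _build_sentence(plan: _SentencePlan, rng: random.Random, trigger_word: str,
                    trigger_type: str | None, before: list[_Block],
                    after: list[_Block]) -> tuple[int, dict[str, list[int]]]:
    """Lay out one trigger with argument chains before/after it."""
    terminals: dict[str, list[int]] = {}
    deferred: list[tuple[_Block, int]] = []
    for block in before:
        idx = _append_block(plan, rng, -1, block)  # root patched below
        deferred.append((block, idx))
    trig_idx = len(plan.tokens)
    plan.tokens.append(trigger_word)
    plan.triggers.append((trig_idx, trigger_word, trigger_type))
    # patch the before-block roots now that the trigger index is known
    fixed = []
    for gov, dep, lab in plan.edges:
        fixed.append((trig_idx if gov == -1 else gov, dep, lab))
    plan.edges = fixed
    for block, idx in deferred:
        terminals.setdefault(block.tag, []).append(idx)
        if block.tag != "evtheme":
            plan.proteins.append((idx, plan.tokens[idx]))
    for block in after:
        idx = _append_block(plan, rng, trig_idx, block)
        terminals.setdefault(block.tag, []).append(idx)
        if block.tag != "evtheme":
            plan.proteins.append((idx, plan.tokens[idx]))
    return trig_idx, terminals


def _finish_sentence(plan: _SentencePlan) -> None:
    idx = len(plan.tokens)
    plan.tokens.append(".")
    if plan.triggers:
        plan.edges.append((plan.triggers[0][0], idx, "punct"))


def _pick_trigger(rng: random.Random, typ: str) -> str:
    choices = [(w, wt[typ]) for w, wt in TRIGGER_LEXICON.items() if typ in wt]
    words, weights = zip(*choices)
    return rng.choices(words, weights=weights, k=1)[0]


def _pick_negative_path(rng: random.Random) -> tuple[str, ...]:
    paths, weights = zip(*NEGATIVE_PATHS)
    return rng.choices(paths, weights=weights, k=1)[0]


# --------------------------------------------------------------------------
# corpus generation


def _plan_event_sentence(rng: random.Random, typ: str, nested: bool,
                         n_extra_neg: int) -> _SentencePlan:
    plan = _SentencePlan()
    names = iter(rng.sample(PROTEIN_NAMES, 8))
    trig_word = _pick_trigger(rng, typ)
    cls = event_class(typ)
    neg_blocks = [
        _Block(_pick_negative_path(rng), next(names), "neg")
        for _ in range(n_extra_neg)
    ]
    if cls == "SVT":
        after = [_Block(rng.choice(THEME_PATHS), next(names), "theme")] + neg_blocks
        trig_idx, term = _build_sentence(plan, rng, trig_word, typ, [], after)
        plan.events.append((typ, trig_idx, ("prot", term["theme"][0]), None, None))
        plan.n_positive_pairs = 1
    elif cls == "BIND":
        after = [
            _Block(rng.choice(THEME_PATHS), next(names), "theme"),
            _Block(rng.choice(THEME_PATHS), next(names), "theme2"),
        ] + neg_blocks
        trig_idx, term = _build_sentence(plan, rng, trig_word, typ, [], after)
        plan.events.append(
            (typ, trig_idx, ("prot", term["theme"][0]), ("prot", term["theme2"][0]), None)
        )
        plan.n_positive_pairs = 2
    elif not nested:
        before = [_Block(rng.choice(CAUSE_PATHS), next(names), "cause")]
        after = [_Block(rng.choice(THEME_PATHS), next(names), "theme")] + neg_blocks
        trig_idx, term = _build_sentence(plan, rng, trig_word, typ, before, after)
        plan.events.append(
            (typ, trig_idx, ("prot", term["theme"][0]), None, ("prot", term["cause"][0]))
        )
        plan.n_positive_pairs = 1
    else:
        # REG nested over an SVT event: cause protein, REG trigger, chain to
        # an SVT trigger which carries its own Theme chain.
        inner_typ = rng.choice(SVT_TYPES)
        inner_word = _pick_trigger(rng, inner_typ)
        before = [_Block(rng.choice(CAUSE_PATHS), next(names), "cause")]
        after = [_Block(rng.choice(EVENT_THEME_PATHS), inner_word, "evtheme")]
        trig_idx, term = _build_sentence(plan, rng, trig_word, typ, before, after)
        inner_idx = term["evtheme"][0]
        plan.triggers.append((inner_idx, inner_word, inner_typ))
        theme_idx = _append_block(
            plan, rng, inner_idx,
            _Block(rng.choice(THEME_PATHS), next(names), "theme"),
        )
        plan.proteins.append((theme_idx, plan.tokens[theme_idx]))
        if n_extra_neg:
            neg_idx = _append_block(
                plan, rng, trig_idx,
                _Block(_pick_negative_path(rng), next(names), "neg"),
            )
            plan.proteins.append((neg_idx, plan.tokens[neg_idx]))
        plan.events.append((inner_typ, inner_idx, ("prot", theme_idx), None, None))
        plan.events.append((typ, trig_idx, ("event", 0), None, ("prot", term["cause"][0])))
        plan.n_positive_pairs = 2  # inner theme pair + REG event-theme pair
    _finish_sentence(plan)
    return plan


def _plan_decoy_sentence(rng: random.Random, used_surfaces: list[str],
                         n_proteins: int) -> _SentencePlan:
    plan = _SentencePlan()
    trig_word = rng.choice(used_surfaces)
    names = iter(rng.sample(PROTEIN_NAMES, max(n_proteins, 1)))
    blocks = [
        _Block(_pick_negative_path(rng), next(names), "neg")
        for _ in range(n_proteins)
    ]
    n_before = rng.randint(0, min(1, len(blocks)))
    _build_sentence(plan, rng, trig_word, None, blocks[:n_before], blocks[n_before:])
    _finish_sentence(plan)
    return plan


def _render_document(doc_id: str, plans: list[_SentencePlan]):
    """Lay out sentences (one per line) and emit standoff + dependency text."""
    lines: list[str] = []
    a1_lines: list[str] = []
    a2_lines: list[str] = []
    dep_lines: list[str] = []
    t_counter = 0
    offset = 0
    trig_tid: dict[tuple[int, int], str] = {}
    prot_tid: dict[tuple[int, int], str] = {}

    # proteins first so trigger T ids continue after the .a1 numbering
    token_offsets: list[list[tuple[int, int]]] = []
    for s_i, plan in enumerate(plans):
        offs = []
        pos = offset
        for tok in plan.tokens:
            offs.append((pos, pos + len(tok)))
            pos += len(tok) + 1
        token_offsets.append(offs)
        offset = pos - 1 + 1  # trailing newline replaces the last space
        lines.append(" ".join(plan.tokens))
    text = "\n".join(lines) + "\n"

    for s_i, plan in enumerate(plans):
        for tok_i, name in sorted(plan.proteins):
            t_counter += 1
            tid = f"T{t_counter}"
            start, end = token_offsets[s_i][tok_i]
            a1_lines.append(f"{tid}\tProtein {start} {end}\t{name}")
            prot_tid[(s_i, tok_i)] = tid

    e_counter = 0
    for s_i, plan in enumerate(plans):
        local_eids: list[str] = []
        for typ, trig_i, *_ in plan.events:
            if (s_i, trig_i) not in trig_tid:
                t_counter += 1
                tid = f"T{t_counter}"
                start, end = token_offsets[s_i][trig_i]
                a2_lines.append(f"{tid}\t{typ} {start} {end}\t{plan.tokens[trig_i]}")
                trig_tid[(s_i, trig_i)] = tid

        def ref(r) -> str:
            kind, v = r
            if kind == "prot":
                return prot_tid[(s_i, v)]
            return local_eids[v]

        for typ, trig_i, theme, theme2, cause in plan.events:
            e_counter += 1
            eid = f"E{e_counter}"
            local_eids.append(eid)
            body = f"{typ}:{trig_tid[(s_i, trig_i)]} Theme:{ref(theme)}"
            if theme2 is not None:
                body += f" Theme2:{ref(theme2)}"
            if cause is not None:
                body += f" Cause:{ref(cause)}"
            a2_lines.append(f"{eid}\t{body}")

    for s_i, plan in enumerate(plans):
        dep_lines.append(f"#sent {s_i}")
        for gov, dep, lab in sorted(plan.edges):
            dep_lines.append(f"{gov} {dep} {lab}")

    def _join(ls: list[str]) -> str:
        return "\n".join(ls) + ("\n" if ls else "")

    return text, _join(a1_lines), _join(a2_lines), _join(dep_lines)


def generate_fixture_corpus(
    out_dir: str,
    n_docs: int,
    imbalance: float = 13.163,
    seed: int = 0,
    event_sentences_per_doc: int = 3,
) -> dict:
    """Generate a synthetic annotated corpus under ``out_dir``.

    Returns a summary dict (also written as ``corpus_manifest.json``) with
    the realized candidate-pair positive:negative ratio and the path pools.
    Deterministic given ``seed``; the realized ratio tracks ``imbalance``
    by appending all-negative decoy sentences until the corpus-level ratio
    reaches the target.
    """
    if n_docs < 1:
        raise ValueError("n_docs must be >= 1")
    if imbalance < 1:
        raise ValueError("imbalance must be >= 1")
    rng = random.Random(seed)
    os.makedirs(out_dir, exist_ok=True)

    n_extra_neg = 2 if imbalance >= 6 else (1 if imbalance >= 3 else 0)
    type_cycle = list(EVENT_TYPES)
    weighted_types = list(TYPE_WEIGHTS)
    weights = [TYPE_WEIGHTS[t] for t in weighted_types]

    total_pos = 0
    total_pairs = 0
    used_surfaces: list[str] = []
    reg_counter = 0
    event_counter = 0
    doc_ids: list[str] = []

    for d in range(n_docs):
        doc_id = f"synth{d:04d}"
        doc_ids.append(doc_id)
        plans: list[_SentencePlan] = []
        for _ in range(event_sentences_per_doc):
            if event_counter < len(type_cycle):
                typ = type_cycle[event_counter]
            else:
                typ = rng.choices(weighted_types, weights=weights, k=1)[0]
            event_counter += 1
            nested = False
            if event_class(typ) == "REG":
                reg_counter += 1
                nested = reg_counter % 3 == 0
            plan = _plan_event_sentence(rng, typ, nested, n_extra_neg)
            for _, word, t in plan.triggers:
                if t is not None and word not in used_surfaces:
                    used_surfaces.append(word)
            plans.append(plan)
            total_pos += plan.n_positive_pairs
            total_pairs += plan.n_candidate_pairs()
        # top up negatives with decoy sentences to track the target ratio
        while total_pairs - total_pos < imbalance * total_pos:
            deficit = imbalance * total_pos - (total_pairs - total_pos)
            m = max(1, min(5, round(deficit / max(1, n_docs - d))))
            if d < n_docs - 1 and deficit / (n_docs - d) < 1:
                break
            plan = _plan_decoy_sentence(rng, used_surfaces, int(m))
            plans.append(plan)
            total_pairs += plan.n_candidate_pairs()
        rng.shuffle(plans)
        text, a1, a2, dep = _render_document(doc_id, plans)
        base = os.path.join(out_dir, doc_id)
        for ext, content in ((".txt", text), (".a1", a1), (".a2", a2), (".dep", dep)):
            with open(base + ext, "w", encoding="utf-8") as fh:
                fh.write(content)

    realized = (total_pairs - total_pos) / total_pos if total_pos else 0.0
    summary = {
        "n_docs": n_docs,
        "seed": seed,
        "imbalance_target": imbalance,
        "realized_neg_per_pos": round(realized, 4),
        "positive_pairs": total_pos,
        "candidate_pairs": total_pairs,
        "event_sentences_per_doc": event_sentences_per_doc,
        "theme_path_pool": [list(p) for p in THEME_PATHS],
        "cause_path_pool": [list(p) for p in CAUSE_PATHS],
        "event_theme_path_pool": [list(p) for p in EVENT_THEME_PATHS],
        "negative_path_pool": [
            {"path": list(p), "weight": w} for p, w in NEGATIVE_PATHS
        ],
        "doc_ids": doc_ids,
    }
    with open(os.path.join(out_dir, "corpus_manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
    return summary
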