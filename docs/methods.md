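# Methods

## Task and data model

The package extracts nine GENIA event types, grouped into simple events
(SVT: `Gene_expression`, `Transcription`, `Protein_catabolism`,
`Localization`, `Phosphorylation`; exactly one protein Theme), Binding
(up to two protein Themes) and regulation (REG: `Regulation`,
`Positive_regulation`, `Negative_regulation`; a Theme plus optional Cause,
either of which may be another event).  Only these primary arguments are
modelled; secondary arguments (Site, AtLoc, ToLoc, CSite) are out of
scope, as are the five additional types of the 2013 task revision.

Inputs are BioNLP-ST standoff documents: raw text, protein T annotations
(`.a1`), and — for training — trigger/event annotations (`.a2`).  Offsets
are 0-based, half-open and document-level.  Dependency parses are consumed
as an input file per document (`.dep`: one `govIdx depIdx label` block per
sentence); producing them is a parser's job and deliberately outside the
package.  Tokenization is a regex splitter with exact offset tracking that
keeps hyphenated biomedical names (`IRF-4`, `NF-kappaB`) as single tokens;
stemming is a light suffix stripper and POS tags are heuristic — both only
feed dictionary matching and classifier features, so a full morphological
analyser would add little here.

## Sequential-pattern sample selection

Candidate (trigger, argument) pairs are generated from a trigger
dictionary (stems of training-annotation triggers, with per-type counts)
crossed with the sentence's proteins and other trigger tokens.  The typed
dependency path between trigger and argument is the label sequence along
the shortest path in the undirected dependency graph; labels carry no
direction markers by default.

The paths of labelled positive pairs form the sequence database *DS*
(multiset: duplicate paths count separately).  `mine_frequent_patterns`
implements PrefixSpan with single-item extension: the database is
recursively projected by each frequent item, so patterns are grown without
candidate generation, and each reported support is exact (a sequence
contains itself; containment is order-preserving with gaps).  Output is
exactly the set of non-empty subsequences with support ≥ *minsup*, in
canonical (length, lexicographic) order; the empty pattern is excluded as
vacuously frequent.  *minsup* is an absolute count.

An unlabelled candidate whose path contains F patterns of the mined set is
selected iff F > Θ (strict).  Defaults are *minsup* = 4 and Θ = 2, the
operating point at which roughly half of the negative candidates are
removed on corpora with the canonical ≈1:13.2 imbalance; both are
configurable.  Candidates with no dependency path are discarded before
filtering (F is undefined without a path and such pairs are almost never
events).  Labelled positives are never filtered.  Selection is monotone:
raising Θ, or raising *minsup* (which can only shrink the pattern set),
can only shrink the kept set.

Triplet candidates carry two paths.  How to filter them is a genuinely
open design point; the package requires **both** paths to pass the pair
criterion (conservative AND), with a `sum` variant (F₁ + F₂ > 2Θ) exposed
on `FilterConfig` for looser selection.

## Classification and integration

Features are sparse name→value maps in four groups: token features (stem,
character 1–3-grams, POS, spelling shape, digit/hyphen/capitalisation) for
trigger and argument heads; sentence features (entity count,
bag-of-stems); dependency features (label chains to depth 3 from the
trigger — the depth is configurable via `features.CHAIN_DEPTH`; the
shortest-path label sequence, its bigrams and interior token stems); and
optional external hypernym features accepted as any stem→hypernyms
mapping (off by default so the build needs no lexical-resource download).
A relative-position feature (argument before/after the trigger) is
included, since Cause arguments typically precede regulation triggers
while Themes follow them.

Two one-vs-rest linear SVMs (scikit-learn `LinearSVC`, L2, C = 1,
`class_weight="balanced"` as mild residual weighting after filtering,
fixed `random_state`) are trained: a pair model over the nine types plus
an explicit negative class, and a triplet model over the Binding/REG types
plus negative.  Prediction takes the argmax class with its decision
margin; a single-class training set yields a constant model that predicts
nothing positive.

Integration rules: a Binding triplet (c, a₁, a₂) becomes one two-Theme
event and subsumes the Binding pairs (c, a₁) and (c, a₂); a REG triplet
emits a₂ as Cause and covers the corresponding Theme pair; pairs untouched
by any triplet of the same trigger are emitted directly, and SVT pairs
always are.  When pair predictions disagree on the type of an identical
(trigger, argument), the higher margin wins (logged) — the resolution
policy is a documented choice, as is single-pass bottom-up resolution of
nested REG Themes (events with protein Themes are materialized first;
a REG prediction whose Theme event was not emitted is dropped and
counted).  Integration is idempotent on its own output.

## Joint rescoring

For each prediction, `Sim(s′, d)` is the maximum cosine relevance between
the embedding of its sentence s′ and the embeddings of the training
sentences d sharing the trigger stem; `Sim = 0` when d is empty.  "Same
trigger" means same stem across the whole training corpus; restricting d
to sentences of the same event type is a config switch
(`same_type_context`).

The default similarity backend embeds a sentence as the summed
letter-trigram count vectors of its tokens (word-boundary-marked trigrams
hashed to 2048 dimensions with a stable digest), making the whole pipeline
deterministic with no model artifacts.  The C-DSSM-style backend applies a
word-hash layer, a linear projection, a tanh convolution over a 3-token
window, element-wise max pooling and a tanh semantic layer; the activation
is configurable (tanh is the convention of convolutional semantic models,
whose original training data — web-search clickthrough logs — is not
reproducible here, so weights are loadable or seeded-random).  In the
degenerate configuration (window 1, identity weights, linear activation,
sum pooling) it reproduces the trigram backend exactly.  Cosine against a
zero vector is defined as 0 with a warning.

Trigger importance uses training event counts f(tᵢ^typ): P1 is the
fraction of tᵢ's events with type typ, P2 is tᵢ's share of all training
trigger occurrences, and P_ti their weighted mean with w1 = #(tᵢ, typ) and
w2 = #tᵢ in the predicted result set (w1 + w2 = 0 is an error; unseen
triggers score 0 and are flagged).  For every known trigger, Σ_typ P1 = 1.

`Score = (1 − σ)·P_ti + σ·Sim` with σ = 0.7 by default (similarity is the
stronger false-positive signal and gets the higher weight); negative
cosines are clamped to 0 first so Score ∈ [0, 1] and the removal threshold
δ ∈ [0, 1] (default 0.5) is meaningful.  Predictions below δ are removed
and logged with all components (P1, P2, P, Sim, Score).

## Synthetic corpora

The generator emits fully-annotated standoff documents whose sentences are
built from a type-skewed trigger lexicon (including a deliberately
ambiguous surface, so P1 < 1 occurs), realistic protein names, and
dependency trees wired so that each trigger→argument path is an explicitly
chosen label sequence.  Positive Theme paths come from a 6-sequence pool
whose subsequence closure is 12 patterns; Cause and nested-event chains
reuse closure members with match count ≥ 3 so predicted triplets can pass
the both-path filter; negative paths come from a 17-sequence pool
stratified by match count F against that closure (weights 0.20 / 0.15 /
0.15 / 0.25 / 0.25 for F = 0 / 1 / 2 / 3 / ≥5).  The strata arithmetic
fixes the expected negative removal at ≈50% for Θ = 2 (≈33% at Θ = 1,
≈75% at Θ = 3), mirroring the intended operating point.  Role direction
follows natural linear order: Causes precede the trigger, Themes follow.
About a third of REG event sentences nest a REG event over an SVT event
(depth 2, matching the common regulation-over-expression structure).

The candidate-pair imbalance is controlled corpus-wide: after each
document's event sentences, all-negative decoy sentences (a known trigger
surface used in a non-event sense plus proteins with negative-pool paths)
are appended until the cumulative negative:positive ratio reaches the
target (default 13.163).  The realized ratio is reported in the corpus
manifest and tracked by construction to well within 20% of the target.
Generation is byte-deterministic given the seed.

What the corpora do **not** emulate: real lexical variety and parse noise,
multi-token triggers, secondary arguments, inter-sentence context, and the
annotation idiosyncrasies of curated corpora.  Tests passing on these
fixtures therefore demonstrate that the machinery is correct and that the
method behaves as designed under its intended signal, not that any
particular F-score carries over to real shared-task data — which would
also require the external biomedical parser and the official scorer.

## Evaluation

The internal evaluator implements approximate-span, recursive matching:
trigger tokens may differ by at most one token position within the same
sentence; protein arguments match by span overlap; event arguments match
recursively; Binding Themes are compared as an unordered set; Cause must
be absent on both sides or match.  Greedy per-type assignment consumes
each gold event at most once; recall/precision/F are reported per type,
per class and overall, as percentages.  The official shared-task scorer
applies further normalisations, so the internal evaluator is used on
fixture corpora only and is documented rather than claimed identical.
The naive comparison baseline emits, for every dictionary-matched token,
one event of the trigger's majority type with the nearest protein as
Theme.

## Problem sizes and numerical choices

Default demonstration and test sizes: 30-document corpora for filter
behaviour (≈1 560 candidate pairs), 60/20 train/test for the worked
end-to-end example, and 150/50 for the acceptance-level recovery run —
sizes at which every reported behaviour (imbalance realization, reduction
band, recovery margin) is stable across seeds while the whole suite stays
fast.  All randomness flows from explicit integer seeds (corpus
generation via `random.Random`, SVM tie-breaking via `random_state`,
C-DSSM initialisation via `numpy` generators); reruns are bit-identical.
Ties in pattern order are broken canonically (length, then lexicographic);
prediction output ordering is fully sorted before serialization so `.a2`
files are byte-stable.

## Known limitations

Single-token triggers only; nesting depth 2 (one bottom-up resolution
pass); no Equiv/modification annotations; no probability calibration; the
pattern filter presumes dependency paths exist (disconnected parses fall
back to a flag feature and exclusion from selection); C-DSSM weights are
applied, never trained.
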