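"""Score a prediction by trigger importance and sentence similarity.

The joint score Score = (1 - sigma) * P_ti + sigma * Sim combines how
consistently a trigger word signals the predicted type in training
(P_ti, from P1 and P2) with how similar the sentence is to training
sentences containing the same trigger (Sim, a max cosine of letter-trigram
embeddings).  Predictions scoring below delta are discarded.
"""

from collections import Counter

from bioevent import (
    ScoreConfig,
    TriggerStats,
    joint_score,
    sentence_similarity,
    trigger_importance,
)

# training statistics: "expr" triggered Gene_expression 4x and
# Positive_regulation 1x; all other triggers account for 5 more events
stats = TriggerStats()
stats.type_counts["expr"] = Counter(
    {"Gene_expression": 4, "Positive_regulation": 1}
)
stats.type_counts["other"] = Counter({"Binding": 5})

p1, p2, p_ti = trigger_importance("expr", "Gene_expression", stats, w1=2, w2=3)
print(f"P1 = {p1:.2f}  (fraction of 'expr' events that are Gene_expression)")
print(f"P2 = {p2:.2f}  ('expr' share of all training trigger occurrences)")
print(f"P_ti = {p_ti:.2f}  (weighted by the prediction-set counts w1=2, w2=3)")

s_prime = ["IRF-4", "expression", "was", "increased"]
context = [
    ["expression", "of", "IRF-4", "in", "cells"],
    ["binding", "of", "IL-2"],
]
sim = sentence_similarity(s_prime, context)
print(f"Sim = {sim:.3f}  (max cosine against same-trigger training sentences)")

cfg = ScoreConfig(sigma=0.7, delta=0.5)
score = joint_score(p_ti, sim, cfg)
print(f"Score = {score:.3f}  -> {'kept' if score >= cfg.delta else 'removed'}"
      f" at delta={cfg.delta}")
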