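"""Integrate pair and triplet predictions into final events.

A Binding event may take two Themes.  When the triplet classifier accepts
(trigger, a1, a2), the single-argument Binding pairs (trigger, a1) and
(trigger, a2) are subsumed by one two-Theme event, while pairs untouched
by any triplet are emitted directly.
"""

from bioevent import Argument, CandidatePair, PredictionSet, integrate
from bioevent.candidates import CandidateTriplet


def pair(ref, tok):
    return CandidatePair(
        doc_id="doc", sent_index=0, trigger_index=0, trigger_stem="bind",
        argument=Argument("protein", ref, tok), path=("nsubj",),
    )


triplet = CandidateTriplet(
    doc_id="doc", sent_index=0, trigger_index=0, trigger_stem="bind",
    arg1=Argument("protein", "T1", 1), arg2=Argument("protein", "T2", 2),
    path1=("nsubj",), path2=("dobj",), ordered=False,
)

preds = PredictionSet(
    pairs=[
        ("Binding", pair("T1", 1), 1.2),
        ("Binding", pair("T2", 2), 1.1),
        ("Binding", pair("T3", 3), 0.9),
    ],
    triplets=[("Binding", triplet, 2.0)],
)

for event in integrate(preds):
    args = event.theme.ref + (f" + {event.arg2.ref} ({event.arg2_role})"
                              if event.arg2 else "")
    print(f"{event.type}: trigger token {event.trigger_index}, {args}")

# Two events result: Binding{T1, T2} (the triplet, covering both pairs)
# and Binding{T3} (the untouched pair, output directly).
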