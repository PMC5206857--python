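"""Mine frequent dependency-path patterns from a small sequence database.

The database holds the typed-dependency label paths of six annotated
trigger-argument pairs; mining returns every subsequence occurring in at
least `minsup` of them, with its support.
"""

from bioevent import mine_frequent_patterns, support

db = [
    ("amod", "prep_to", "prep_in", "nn"),
    ("prep_to", "nn", "prep_in"),
    ("amod", "nn"),
    ("prep_to", "dobj", "prep_in", "nn"),
    ("dobj", "amod", "prep_to", "nn"),
    ("prep_to", "nn"),
]

print(f"support of <amod nn> in the {len(db)}-sequence database:",
      support(("amod", "nn"), db))

ls = mine_frequent_patterns(db, minsup=3)
print(f"frequent patterns at minsup=3 ({len(ls)} total):")
for pattern, sup in ls.patterns:
    print(f"  <{' '.join(pattern)}>  support={sup}")

# Each line is a label sequence contained (order-preserving, gaps allowed)
# in at least 3 of the 6 paths; these patterns characterise how annotated
# trigger-argument pairs are syntactically connected.
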