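"""Induce normalization rules from a synonym cluster and map new variants.

Builds the six-variant UniProt Q8K4R9 cluster (hepatoma up-regulated
protein / Dlg7), induces rewrite rules from its internal variation, and
maps unseen surface forms through the inverse index.
"""

from lexiforge import (
    CandidateTerm,
    ClusteredDictionary,
    build_inverse_index,
    compute_metrics,
    induce_ruleset,
    map_term,
    RuleSet,
)

TERMS = [
    "Hepatoma up-regulated protein",
    "Hurp",
    "hepatoma up-regulated protein",
    "discs large homolog 7",
    "discs, large homolog 7",
    "Dlg7",
]

dictionary = ClusteredDictionary.from_pairs([("Q8K4R9", t) for t in TERMS])

before = compute_metrics(dictionary, RuleSet())
rules = induce_ruleset(dictionary)
after = compute_metrics(dictionary, rules)
print(f"induced {len(rules)} rules: "
      + ", ".join(f"{r.kind}({r.pattern}->{r.replacement})" if r.pattern else r.kind
                  for r in rules))
print(f"variability {before.variability:.2f} -> {after.variability:.2f}  "
      f"(forms per cluster; 1.0 = fully collapsed)")
print(f"ambiguity   {before.ambiguity:.2f} -> {after.ambiguity:.2f}  "
      f"(clusters per form; 1.0 = no cross-cluster sharing)")

index = build_inverse_index(dictionary, rules)
for surface, prob in [("HURP", 0.995), ("dlg7", 0.999), ("HURP", 0.99),
                      ("zzz999", 0.999)]:
    r = map_term(CandidateTerm(surface, prob), index, rules, dictionary)
    accs = ",".join(sorted(r.accessions)) or "-"
    print(f"{surface!r:28s} p={prob:<6} -> {r.status:18s} {accs} "
          f"(confidence {r.confidence_score:.3f})")
# A mined variant maps to its accession only when its recognition
# probability is strictly above 0.99 and its normalized form hits a cluster.
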