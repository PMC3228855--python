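# lexiforge

Tools for building, representing and applying a biomedical computational
lexicon — the kind of resource that lets text-mining systems resolve the
many written variants of gene and protein names to database accessions,
and interpret the verbs that describe biomedical events.

It is aimed at biomedical NLP practitioners who have (i) synonym
dictionaries clustered by accession number (UniProt, ChEBI, NCBI
taxonomy), (ii) term candidates mined by a named-entity recognizer, (iii)
predicate–argument output from a deep parser, and (iv) role-annotated
event corpora — and who want to turn those into a single lexicon usable
for tagging and fact extraction.

## What it computes

**Term normalization and mapping.** A normalization rule is a
deterministic, idempotent string rewrite (case folding, character-class
deletion, bounded substring rewrites such as `our`→`or`). Rule sets are
scored on an accession-clustered dictionary by two metrics —

- *variability*: mean number of distinct normalized forms per cluster,
- *ambiguity*: mean number of clusters sharing a normalized form —

and induced greedily to maximize `Δvariability − λ·Δambiguity`. The
induced rules define an inverse index `normalized form → accessions`, so
mapping a mined candidate is one normalization plus one lookup instead of
an all-pairs similarity computation. Candidates need recognition
probability strictly above 0.99; forms hitting more than 10 accessions
are discarded as hopelessly ambiguous. Soft string similarity (mean of
character-bigram Dice and token Jaccard) sub-clusters dictionary terms
and scores mapping confidence.

**Grammatical frames.** From parsed verb instances with logical argument
slots (ARG1 = logical subject, so actives and passives share a frame),
the toolkit estimates `P(pattern | verb)`, keeps patterns with
probability ≥ 0.03, and records passive-voice percentages, support, NE
filler distributions, and per-slot association via the likelihood-ratio
statistic G² = 2·Σ O·ln(O/E).

**Semantic frames and linking.** Role-annotated events (13-role
inventory: AGENT, THEME, LOCATION, SOURCE, DESTINATION, ...) aggregate
into verb-specific frames like `activate(Agent=>Protein,Theme=>DNA)`,
which are aligned to grammatical frames argument-by-argument through
prototypic realizations (AGENT→ARG1, SOURCE→PP-from, ...) plus
left-to-right hierarchy alignment; unmatched sides link to `0`, e.g.
`0 > ARG1#THEME > ARG2#DESTINATION > PP-into`.

**Application.** Leftmost-longest dictionary tagging (`NN-BIOMED` spans),
and three-filter fact extraction: keep a parsed instance iff its verb is
a lexicon verb, at least one argument carries a named entity, and its
slot pattern matches a stored frame; surviving instances become facts
with roles assigned through the frame links.

**Fixtures.** All inputs can be generated synthetically with planted
ground truth (seeded, pure functions of the spec), so every stage is
testable end-to-end without downloads.

## Worked example

```python
from lexiforge import (CandidateTerm, ClusteredDictionary,
                       build_inverse_index, induce_ruleset, map_term)

terms = ["Hepatoma up-regulated protein", "Hurp",
         "hepatoma up-regulated protein", "discs large homolog 7",
         "discs, large homolog 7", "Dlg7"]
d = ClusteredDictionary.from_pairs([("Q8K4R9", t) for t in terms])
rules = induce_ruleset(d)
index = build_inverse_index(d, rules)
print(map_term(CandidateTerm("HURP", 0.995), index, rules, d))
```

Running `python examples/normalize_and_map.py` prints:

```
induced 2 rules: case_fold, delete_class(punctuation->)
variability 6.00 -> 4.00  (forms per cluster; 1.0 = fully collapsed)
ambiguity   1.00 -> 1.00  (clusters per form; 1.0 = no cross-cluster sharing)
'HURP'                       p=0.995  -> mapped             Q8K4R9 (confidence 0.999)
'dlg7'                       p=0.999  -> mapped             Q8K4R9 (confidence 0.999)
'HURP'                       p=0.99   -> rejected_low_prob  - (confidence 0.000)
'zzz999'                     p=0.999  -> unmapped           - (confidence 0.000)
```

The induced rules collapse case and punctuation variation, so the unseen
surface forms `HURP` and `dlg7` resolve to the cluster's accession; a
candidate at exactly the 0.99 probability cutoff is rejected (the filter
is strict), and an unknown string stays unmapped. The acronym `Hurp` and
the short synonym `Dlg7` are not rewrite-recoverable from the long forms,
which is why variability stops at 4.0 rather than 1.0.

The other scripts in `examples/` walk through grammatical frame induction
(`induce_syn_frames.py`), semantic frames and the three canonical linking
cases (`link_sem_frames.py`), tagging and filtered fact extraction
(`tag_and_extract_facts.py`), and XIF serialization with staged,
all-or-nothing loading (`xif_round_trip.py`).

A thin CLI wraps the same library:

```bash
lexiforge gen-fixtures --seed 1 --out scratch/fx
lexiforge induce-rules --dict scratch/fx/dictionary.tsv --out scratch/rules.tsv
lexiforge build-index --dict scratch/fx/dictionary.tsv --rules scratch/rules.tsv --out scratch/index.tsv
lexiforge map-terms --index scratch/index.tsv --rules scratch/rules.tsv \
    --dict scratch/fx/dictionary.tsv --candidates scratch/fx/candidates.tsv --out scratch/mapped.tsv
```

## Layout

```
src/lexiforge/
  model.py          lexicon data model, XIF round-tripping, staged loading
  normalization.py  rules, metrics, greedy induction, inverse index
  mapping.py        candidate filtering, soft similarity, accession mapping
  synframes.py      grammatical frame induction, passive rates, G2 association
  semframes.py      role frames, NE taxonomy, syntax-semantics linking
  application.py    dictionary tagging, three-filter fact extraction
  fixtures.py       seeded synthetic-data generators with planted truth
  cli.py            thin click CLI (`lexiforge ...`)
docs/methods.md     models, parameters, numerical choices, limitations
docs/xif.md         the XML interchange format
examples/           one narrative script per capability
```
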