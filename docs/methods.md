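# Methods

`lexiforge` implements the computational core of a biomedical lexicon
pipeline: normalizing and mapping term variants onto database accessions,
inducing grammatical and semantic frames for domain verbs from annotated
corpora, linking the two frame inventories, and applying the resulting
lexicon for tagging and fact extraction.  This note records the models,
the parameters that matter, the numerical choices, and what the synthetic
fixtures do and do not show.

## Term normalization and the two metrics

A normalization rule is a total, deterministic, idempotent string rewrite.
Four kinds are supported: `case_fold`; `delete_class` over a named
character class (`hyphens` ⊂ `punctuation`, and `whitespace`);
`substring_rewrite` (a bounded literal rewrite such as `our`→`or`, applied
to a fixpoint so it stays idempotent; a replacement containing its own
pattern is applied in a single pass); and `token_sort` (alphabetical token
reordering for structural variants such as *discs, large homolog 7*; off
by default because it merges aggressively).  Rules apply in rank order to
NFC-normalized strings.

A rule set is scored against an accession-clustered dictionary by two
macro-averages:

* **variability** — mean over clusters of the number of distinct
  normalized forms in the cluster.  1.0 means every cluster collapses to a
  single canonical form.
* **ambiguity** — mean over distinct normalized forms of the number of
  clusters containing a term with that form.  1.0 means no normalized form
  is shared across clusters.

A known artifact of the mean-over-forms ambiguity: collapsing unique
variants removes unambiguous forms from the denominator, so the mean can
rise even when a rule creates no new cross-cluster sharing.  On
dictionaries dominated by one highly shared form this can make every
candidate look ambiguity-increasing.  In practice rules are induced from
the synonym dictionary itself, where sharing is rare; the metric remains
configurable at the `compute_metrics` level.

### Candidate generation and greedy induction

Candidates are proposed from intra-cluster variant pairs: a case-only
difference votes for `case_fold`; a difference explained by deleting a
character class votes for the most specific sufficient class (classes are
tried cumulatively — hyphens, then punctuation, then whitespace — and
every class in the minimal sufficient prefix whose characters occur in the
pair is proposed, so a hyphen/space alternation proposes both `hyphens`
and `whitespace`); a single-block diff of at most four characters per side
becomes a `substring_rewrite` with one character of context, oriented
longer→shorter (ties: the lexicographically greater side becomes the
pattern), which yields `our`→`or` deterministically.

Induction is greedy: repeatedly add the candidate maximizing

    Δvariability_reduction − λ · Δambiguity_increase

stopping at `k_max` rules (default 1000, far more than desk-scale
dictionaries ever select) or when no candidate scores above zero.
λ defaults to 1.0; larger values veto any ambiguity increase.  Ties break
on higher supporting-pair count, then on the lexicographic rule
representation, so induction is deterministic.

The **inverse index** maps each dictionary term's normalized form to the
accessions of the clusters containing it, and carries the inducing rule
set's digest; mapping refuses an index whose provenance does not match the
rules supplied, since lookups are only meaningful when candidate terms are
normalized with the same rules that built the index.  The index replaces
the quadratic all-pairs similarity computation with one normalization and
one lookup per candidate.

## Term mapping

Candidates from a named-entity recognizer carry a recognition probability;
only candidates **strictly above** 0.99 (configurable) are considered.  A
candidate is normalized, looked up, and classified: `unmapped` (no
cluster), `discarded_ambiguous` (more than 10 accessions, configurable),
else `mapped` with a polysemy flag when it hits two or more accessions.

Soft string similarity is the mean of character-bigram Dice and token-set
Jaccard, computed on casefolded NFC text.  Exact NFC equality scores 1.0;
any other pair is capped at 0.999, so identity is exactly recoverable
while case variants still score near 1.  Dictionary clusters are
sub-clustered by single-linkage over pairs with similarity at or above the
threshold (default 0.8), which separates e.g. long-form families from
unrelated short synonyms within one accession cluster; a mapped
candidate's confidence is its best similarity to the members of the
sub-cluster(s) its normalized form matched.  Acronym-like forms whose
similarity to every long form is low become singleton sub-clusters; this
is expected and does not affect their index-based mapping.

## Grammatical frame induction

Input instances are predicate-argument records with *logical* slots: ARG1
is the logical subject and ARG2 the logical object, so actives and
passives of one event share a frame.  Canonical slot order is ARG1, ARG2,
ARG3, THAT-CL, TO-INF, prepositional slots alphabetically by preposition,
ADV last; repeated prepositions collapse with multiplicity recorded.  This
makes the `#`-joined serialization injective and input-order independent.

P(pattern | verb) is the relative frequency among the verb's instances;
patterns with probability **at or above** 0.03 are retained (the threshold
is inclusive), each with support, passive-voice percentage, and the
observed named-entity-type distribution per slot.  A `min_support` floor
(default 1) exists solely to guard very small corpora.

Slot association uses the likelihood-ratio statistic
G² = 2·Σ O·ln(O/E) on the 2×2 verb × slot contingency table with
expecteds from the marginals; zero cells contribute zero, and degenerate
margins (a slot absent or universal corpus-wide) return 0 with a warning.
G² is computed per (verb, slot); a per-filler variant would need filler
annotations dense enough to fill the table and is left to the caller via
pre-filtering.

## Semantic frames and frame linking

Events carry a verb (or nominalized-verb) trigger and arguments labelled
with one of 13 roles; nominalized triggers contribute to their base verb's
frames by default.  Annotated NE types resolve to one of five top-level
classes (DNA, PROTEIN, EXPERIMENTAL, ORGANISMS, PROCESSES) through an
extensible subtype map (e.g. PROMOTER → DNA).  Frames aggregate by (verb,
role pattern, filler pattern) with support counts, roles ordered by the
role hierarchy.

Linking aligns a semantic frame to a grammatical frame in three stages:

1. **Forced prototypic matches.**  Each role has admissible realizations
   (AGENT → ARG1; THEME → ARG2; INSTRUMENT → PP-with/through/using/via/by;
   SOURCE → PP-from; DESTINATION → PP-to/into/onto/towards; LOCATION →
   PP-in/on/at/within; MANNER → PP-by/through/via/in; PURPOSE → TO-INF or
   PP-for; descriptive roles → ARG3 or PP-as; the full table is
   configurable).  Roles whose admissible slots intersect the frame's
   unclaimed slots in exactly one label claim it; prepositional
   realizations are resolved first, iterating to a fixpoint so that one
   role's claim can make another's unique.
2. **Hierarchy alignment.**  Remaining roles (in role-hierarchy order:
   AGENT > THEME > INSTRUMENT > SOURCE > DESTINATION > LOCATION > TEMPORAL
   > CONDITION > RATE > MANNER > PURPOSE > descriptives) pair
   left-to-right with remaining slots in canonical slot order.  This is
   what lets the THEME of an agentless intransitive take the subject slot.
3. **Leftovers link to 0** on either side.

A role whose prototypic slots exist in the frame but were all claimed by
other roles is a genuine contention; `link_frames` raises and `link_all`
reports the pair instead of guessing.  Serialization lists slot-bearing
pairs in canonical slot order, then role>0 leftovers in hierarchy order.

## Applying the lexicon

**Tagging** matches token windows greedily, leftmost-longest, against the
lexicon's written-form index (exact match first, casefolded fallback);
matched spans are tagged `NN-BIOMED` and never overlap.

**Fact extraction** applies three filters in order: (1) the verb must be a
lexicon verb (auxiliaries are excluded from the denominator by a
configurable stoplist); (2) at least one argument must carry an NE; (3)
the instance's canonical pattern must match a stored frame by
*subsumption* — the frame's slots must be a subset of the instance's — so
extra adjuncts never block extraction while a missing licensed slot does.
When several frames subsume an instance the most specific (largest) wins,
ties broken by probability.  Roles are assigned through the chosen frame's
link; a prepositional argument licensed by the frame can thereby receive a
core role (the *codes for* pattern).  The filter report partitions
lexicon-verb instances exactly into facts, frame mismatches, and NE-free
instances, mirroring how such pipelines report their filtering yield.

## Synthetic fixtures

Generators are pure functions of a `FixtureSpec` (seed included).  The
dictionary generator builds gene-like lowercase names (syllable stems,
optional Greek-letter token, trailing digit, and stems seeded with
`our`/`ise` substrings so spelling rules have material), then derives
variants by case change, hyphen toggling at the letter-digit boundary,
spelling swaps, and optionally whitespace jitter, acronym formation and
token permutation (the last two are flagged irrecoverable by rewrite
rules).  Defaults: 200 concepts, 3 variants per concept, case/hyphen/
spelling at 0.4/0.3/0.3, no cross-cluster ambiguity injection.

The corpus generator plants, per verb, a pattern distribution
({ARG1#ARG2: 0.60, ARG1#ARG2#PP-in: 0.35, ARG1: 0.05} by default, chosen
to bracket the retention threshold), a passive-voice probability (0.30), and
per-slot NE distributions; optional noise patterns are planted below the
threshold.  Distractors for fact extraction (NE-free, off-frame,
non-lexicon-verb instances) are allocated as exact counts, so report
ratios are exact by construction.  Event generation plants role patterns
paired with those grammatical patterns, with a nominalization rate of 0.1.

Problem sizes used by the test suite and the acceptance script (2000
instances per verb for distribution recovery, 200-concept dictionaries,
1000 random contingency tables) are desk-scale choices: large enough that
three binomial standard errors sit inside the stated tolerances, small
enough to run in seconds.

What passing on fixtures does **not** show: real dictionaries contain
acronyms, structural and semantic variants that no rewrite rule recovers;
real parses carry attachment errors and slot noise far richer than the
planted off-frame patterns; and real role annotation disagrees with
syntax in ways the paired generator never does.  Fixture results certify
the machinery — estimators, filters, alignments, serialization — not
performance on MEDLINE-scale data.

## Known limitations

* Ambiguity is a macro-average over forms (artifact discussed above).
* The similarity measure is character/token based; it cannot see acronym
  ↔ expansion relations (these map through the index only when a rule
  collapses them).
* Frame linking automates stated constraints; genuinely ambiguous
  preposition competition is reported, not resolved.
* Polysemous mapped candidates are flagged, never disambiguated.
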