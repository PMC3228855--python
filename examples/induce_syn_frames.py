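"""Induce grammatical frames from a seeded parsed corpus.

Generates 2000 predicate-argument instances of *activate* with a planted
pattern distribution ({ARG1#ARG2: 0.60, ARG1#ARG2#PP-in: 0.35, ARG1:
0.05}) plus two noise patterns at 0.01, then estimates the frame
inventory; frames below probability 0.03 are filtered.
"""

from lexiforge import FixtureSpec, estimate_frames, gen_parsed_corpus, passive_rate, slot_loglik

spec = FixtureSpec(
    seed=42,
    verbs=("activate", "regulate"),
    instances_per_verb=2000,
    noise_patterns={"ARG1#PP-under": 0.01, "ARG1#ADV": 0.01},
    passive_prob=0.3,
)
instances, truth = gen_parsed_corpus(spec)

print("verb        pattern              P(pat|verb)  passive%  support")
for frame, stats in estimate_frames(instances):
    print(f"{frame.verb_lemma:10s}  {frame.pattern:20s} {stats.probability:10.3f}"
          f"  {stats.passive_pct:7.1f}  {stats.support:6d}")
# The noise patterns (planted at 0.01 < 0.03) never appear; retained
# probabilities estimate the planted {0.60, 0.35, 0.05} within sampling error.

print(f"\npassive rate of activate: {passive_rate(instances, 'activate'):.1f}% "
      f"(planted {100 * spec.passive_prob:.0f}%)")

assoc = slot_loglik(instances, "activate", "PP-in")
print(f"association of activate with PP-in: G2 = {assoc.ll:.1f} "
      f"(2x2 counts {assoc.counts}; larger = more verb-specific)")
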