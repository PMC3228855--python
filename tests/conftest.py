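"""Shared fixtures: printed worked-example data and small generated inputs."""

from __future__ import annotations

import numpy as np
import pytest

from lexiforge.fixtures import FixtureSpec, gen_dictionary
from lexiforge.model import (
    AccessionLink,
    FrameRecord,
    LexicalEntry,
    Lexicon,
    Variant,
    WordForm,
)
from lexiforge.normalization import ClusteredDictionary

#: The six synonym-cluster variants recorded under UniProt accession Q8K4R9.
Q8K4R9_TERMS = (
    "Hepatoma up-regulated protein",
    "Hurp",
    "hepatoma up-regulated protein",
    "discs large homolog 7",
    "discs, large homolog 7",
    "Dlg7",
)


@pytest.fixture
def q8k4r9_dict() -> ClusteredDictionary:
    return ClusteredDictionary.from_pairs(
        [("Q8K4R9", t) for t in Q8K4R9_TERMS]
    )


@pytest.fixture
def small_spec() -> FixtureSpec:
    return FixtureSpec(seed=11, n_concepts=30, variants_per_concept=2)


def make_random_lexicon(seed: int, n_entries: int = 25) -> Lexicon:
    """Small lexicon with nouns (accessions + variants), verbs (frames,
    inflections, relations) and assorted data categories."""
    rng = np.random.default_rng(seed)
    spec = FixtureSpec(seed=seed, n_concepts=max(n_entries - 5, 1),
                       variants_per_concept=2)
    d, _ = gen_dictionary(spec)
    lex = Lexicon()
    noun_ids = []
    for acc in sorted(d.clusters):
        terms = sorted(d.clusters[acc])
        lemma = terms[0]
        entry = LexicalEntry(f"N-{acc}", lemma, "noun", semantic_type="Protein")
        entry.accession_links.append(AccessionLink("UniProt", acc, True))
        for t in terms[1:]:
            entry.variants.append(Variant(t, "orthographic", "curated"))
        if rng.random() < 0.5:
            entry.variants.append(
                Variant(lemma + " var", "text-mined", "corpus",
                        round(float(rng.uniform(0.5, 0.99)), 3))
            )
        entry.frequency.append(("MEDLINE", int(rng.integers(1, 10000))))
        lex.add(entry)
        noun_ids.append(entry.entry_id)
    for i, verb in enumerate(("activate", "regulate", "transcribe", "bind",
                              "accumulate")):
        entry = LexicalEntry(f"V-{i:02d}", verb, "verb")
        entry.inflected_forms.append(
            WordForm(verb + "s", (("tense", "present"), ("person", "3sg")))
        )
        entry.inflected_forms.append(WordForm(verb + "d", (("tense", "past"),)))
        entry.frames.append(
            FrameRecord("syn", "ARG1#ARG2",
                        (("probability", "0.60"), ("passive_pct", "28.0")))
        )
        entry.frames.append(
            FrameRecord("sem", f"{verb}(Agent=>Protein,Theme=>DNA)")
        )
        entry.related_entries.append((noun_ids[i], "nominalization"))
        lex.add(entry)
    return lex
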