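"""Seeded synthetic-data generators for every input the toolkit consumes.

The generators emulate, at desk scale, the data a lexicon-construction
pipeline would see: an accession-clustered synonym dictionary whose
variants are produced by known processes (case change, hyphen toggling,
Anglo-American spelling swaps, whitespace jitter, acronym formation, token
permutation), mined candidate terms with recognition probabilities, a
parsed predicate-argument corpus with planted per-verb pattern/voice/NE
distributions plus sub-threshold noise, and role-annotated events paired
with the grammatical patterns so frame linking is exercised end to end.

Every generator is a pure function of its spec (including the seed), and
each returns the planted ground truth alongside the data so recovery tests
can score against it.  Synthetic gene names mimic real morphology (letters
plus digits, Greek-letter tokens, hyphens) so normalization rules face
realistic character classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .mapping import CandidateTerm
from .normalization import ClusteredDictionary
from .semframes import EventAnnotation, EventArgument, Trigger
from .synframes import ParsedInstance, Slot

__all__ = [
    "RECOVERABLE_PROCESSES",
    "IRRECOVERABLE_PROCESSES",
    "FixtureSpec",
    "gen_dictionary",
    "gen_parsed_corpus",
    "gen_events",
    "gen_candidates",
]

RECOVERABLE_PROCESSES = ("case_change", "hyphen_toggle", "spelling_swap",
                         "whitespace_jitter")
IRRECOVERABLE_PROCESSES = ("acronym", "token_permutation")

_GREEK = ("alpha", "beta", "gamma", "delta", "kappa", "sigma")
_SYLLABLES = ("ba", "co", "dar", "fen", "gly", "hem", "lin", "mor", "nuc",
              "pro", "reg", "sor", "tam", "vex", "zym")

_DEFAULT_PATTERNS: dict[str, float] = {
    "ARG1#ARG2": 0.60,
    "ARG1#ARG2#PP-in": 0.35,
    "ARG1": 0.05,
}

_DEFAULT_NE_FILLERS: dict[str, dict[str, float]] = {
    "ARG1": {"PROTEIN": 0.8, "DNA": 0.2},
    "ARG2": {"DNA": 0.7, "PROTEIN": 0.3},
    "PP-in": {"ORGANISMS": 1.0},
}

_DEFAULT_ROLE_PATTERNS: dict[str, list[tuple[tuple[tuple[str, str | None], ...], float]]] = {
    "activate": [
        ((("AGENT", "PROTEIN"), ("THEME", "DNA")), 0.7),
        ((("AGENT", "PROTEIN"), ("THEME", "DNA"), ("LOCATION", "ORGANISMS")), 0.3),
    ],
    "regulate": [
        ((("AGENT", "PROTEIN"), ("THEME", "DNA")), 1.0),
    ],
    "transcribe": [
        ((("AGENT", "PROTEIN"), ("THEME", "DNA"), ("SOURCE", "DNA")), 1.0),
    ],
    "accumulate": [
        ((("THEME", "PROTEIN"),), 1.0),
    ],
}

_NOMINALIZATIONS = {
    "activate": "activation",
    "regulate": "regulation",
    "transcribe": "transcription",
    "accumulate": "accumulation",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for all generators; seeded and fully reproducible."""

    seed: int = 0
    # dictionary
    n_concepts: int = 200
    variants_per_concept: int = 3
    ambiguity_injection_rate: float = 0.0
    process_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "case_change": 0.4, "hyphen_toggle": 0.3, "spelling_swap": 0.3,
        }
    )
    # parsed corpus
    verbs: tuple[str, ...] = ("activate", "regulate", "transcribe", "accumulate")
    instances_per_verb: int = 2000
    pattern_dist: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PATTERNS)
    )
    noise_patterns: Mapping[str, float] = field(default_factory=dict)
    passive_prob: float = 0.3
    ne_filler_dist: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_NE_FILLERS.items()}
    )
    # distractors for fact extraction (exact fractions of each verb's block)
    no_ne_rate: float = 0.0
    off_frame_rate: float = 0.0
    nonlexicon_rate: float = 0.0
    # events
    events_per_verb: int = 50
    nominalized_rate: float = 0.1
    role_patterns: Mapping[str, Sequence[tuple[tuple[tuple[str, str | None], ...], float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_ROLE_PATTERNS.items()}
    )
    # candidates
    n_true_candidates: int = 100
    n_lowprob_candidates: int = 20
    n_junk_candidates: int = 20

    def validate(self) -> None:
        for name in ("ambiguity_injection_rate", "passive_prob", "no_ne_rate",
                     "off_frame_rate", "nonlexicon_rate", "nominalized_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.pattern_dist.values()) - 1.0) > 1e-9:
            raise ValueError("pattern_dist must sum to 1")
        if self.n_concepts < 1:
            raise ValueError("n_concepts must be >= 1")


def _base_name(rng: np.random.Generator, i: int) -> str:
    """Gene-like lowercase base name, e.g. "sorlin1", "hemour kappa2"."""
    stem = "".join(rng.choice(_SYLLABLES, size=int(rng.integers(2, 4))))
    r = rng.random()
    if r < 0.25:
        stem += "our"
    elif r < 0.5:
        stem += "ise"
    name = stem
    if rng.random() < 0.4:
        name += " " + str(rng.choice(_GREEK))
    name += str(int(rng.integers(1, 10)))
    return name


def _apply_process(rng: np.random.Generator, term: str, kind: str) -> str | None:
    """Apply one variant process; None when not applicable to this term."""
    if kind == "case_change":
        out = term.upper() if rng.random() < 0.5 else term.title()
        return out if out != term else term.upper()
    if kind == "hyphen_toggle":
        if "-" in term:
            return term.replace("-", "", 1)
        # insert before the trailing digit run
        i = len(term)
        while i > 0 and term[i - 1].isdigit():
            i -= 1
        if 0 < i < len(term) and term[i - 1] not in "- ":
            return term[:i] + "-" + term[i:]
        return None
    if kind == "spelling_swap":
        if "our" in term:
            return term.replace("our", "or")
        if "ise" in term:
            return term.replace("ise", "ize")
        return None
    if kind == "whitespace_jitter":
        if " " in term:
            return term.replace(" ", "", 1)
        return None
    if kind == "acronym":
        tokens = term.split()
        if len(tokens) < 2:
            return None
        return "".join(t[0] for t in tokens).upper()
    if kind == "token_permutation":
        tokens = term.split()
        if len(tokens) < 2:
            return None
        perm = list(tokens)
        rng.shuffle(perm)
        return " ".join(perm) if perm != tokens else " ".join(reversed(tokens))
    raise ValueError(f"unknown variant process {kind!r}")


def gen_dictionary(
    spec: FixtureSpec,
) -> tuple[ClusteredDictionary, dict[tuple[str, str], str]]:
    """Generate an accession-clustered dictionary with process-tagged
    variants; returns the dictionary and the process per (accession, term)
    ground truth ("base" for the seed name, "shared" for injected
    ambiguity)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    d = ClusteredDictionary()
    truth: dict[tuple[str, str], str] = {}
    kinds = list(spec.process_probs)
    probs = np.array([spec.process_probs[k] for k in kinds], dtype=float)
    if probs.sum() > 0:
        probs = probs / probs.sum()
    bases: list[tuple[str, str]] = []
    for i in range(spec.n_concepts):
        acc = f"ACC{i:05d}"
        base = _base_name(rng, i)
        while any(b == base for _, b in bases):
            base = _base_name(rng, i)
        d.add(acc, base, source="curated")
        truth[(acc, base)] = "base"
        for _ in range(spec.variants_per_concept):
            variant = None
            kind = None
            for _attempt in range(8):
                if not kinds:
                    break
                kind = kinds[int(rng.choice(len(kinds), p=probs))]
                variant = _apply_process(rng, base, kind)
                if variant and variant != base:
                    break
                variant = None
            if variant is None:
                variant, kind = base.upper(), "case_change"
            d.add(acc, variant, source="curated")
            truth.setdefault((acc, variant), kind)
        if bases and rng.random() < spec.ambiguity_injection_rate:
            other_acc, other_base = bases[int(rng.integers(len(bases)))]
            d.add(acc, other_base, source="curated")
            truth[(acc, other_base)] = "shared"
        bases.append((acc, base))
    return d, truth


_NE_TEXTS = {
    "PROTEIN": "the {} protein",
    "DNA": "the {} promoter",
    "ORGANISMS": "Escherichia coli",
    "EXPERIMENTAL": "the {} assay",
    "PROCESSES": "{} transcription",
}

_OFF_FRAME_PATTERN = "ARG3#PP-under"
_NONLEXICON_VERBS = ("seem", "remain", "happen")


def _instance_from_pattern(
    rng: np.random.Generator,
    verb: str,
    pattern: str,
    sentence_id: str,
    voice: str,
    ne_dist: Mapping[str, Mapping[str, float]],
    with_ne: bool,
) -> ParsedInstance:
    labels = pattern.split("#")
    order = rng.permutation(len(labels))  # input order should not matter
    slots = []
    for k in order:
        label = labels[int(k)]
        category = "clause" if label in ("THAT-CL", "TO-INF") else (
            "adverb" if label == "ADV" else "NP"
        )
        ne = None
        if with_ne and label in ne_dist:
            types = list(ne_dist[label])
            p = np.array([ne_dist[label][t] for t in types], dtype=float)
            ne = types[int(rng.choice(len(types), p=p / p.sum()))]
        text = None
        if ne is not None:
            text = _NE_TEXTS.get(ne, "the {} factor").format(
                "".join(rng.choice(list("abcdefgh"), size=3)) + str(int(rng.integers(1, 9)))
            )
        slots.append(Slot(label, category, ne, text))
    return ParsedInstance(verb, sentence_id, voice, tuple(slots))


def gen_parsed_corpus(
    spec: FixtureSpec,
) -> tuple[list[ParsedInstance], dict]:
    """Generate a parsed predicate-argument corpus.

    Per verb: ``instances_per_verb`` instances drawn from the planted
    pattern distribution (rescaled around any sub-threshold noise
    patterns), Bernoulli passive voice, NE fillers per slot.  Distractor
    fractions (NE-free, off-frame, non-lexicon verbs) are allocated as
    exact counts so filter-report ratios are exact by construction.

    Returns (instances, truth) where truth records the effective pattern
    distribution, the passive probability, and the sentence ids of planted
    facts (instances that should survive all extraction filters).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    noise_mass = sum(spec.noise_patterns.values())
    if noise_mass >= 1.0:
        raise ValueError("noise pattern mass must be < 1")
    effective: dict[str, float] = {
        p: w * (1.0 - noise_mass) for p, w in spec.pattern_dist.items()
    }
    for p, w in spec.noise_patterns.items():
        effective[p] = effective.get(p, 0.0) + w

    instances: list[ParsedInstance] = []
    planted_ids: list[str] = []
    n = spec.instances_per_verb
    n_off = int(round(spec.off_frame_rate * n))
    n_none = int(round(spec.no_ne_rate * n))
    patterns = list(effective)
    pw = np.array([effective[p] for p in patterns], dtype=float)
    pw = pw / pw.sum()
    sid = 0
    for verb in spec.verbs:
        kinds = ["off"] * n_off + ["none"] * n_none + ["planted"] * (n - n_off - n_none)
        rng.shuffle(kinds)
        for kind in kinds:
            sid += 1
            sentence_id = f"s{sid:07d}"
            voice = "passive" if rng.random() < spec.passive_prob else "active"
            if kind == "off":
                inst = _instance_from_pattern(
                    rng, verb, _OFF_FRAME_PATTERN, sentence_id, voice,
                    {"ARG3": {"PROTEIN": 1.0}}, True,
                )
            else:
                pattern = patterns[int(rng.choice(len(patterns), p=pw))]
                inst = _instance_from_pattern(
                    rng, verb, pattern, sentence_id, voice,
                    spec.ne_filler_dist, with_ne=kind == "planted",
                )
                if kind == "planted" and not any(s.ne_type for s in inst.slots):
                    # guarantee the NE filter is satisfiable for planted facts
                    slots = list(inst.slots)
                    slots[0] = Slot(slots[0].label, slots[0].category,
                                    "PROTEIN", "the fixture protein")
                    inst = ParsedInstance(verb, sentence_id, voice, tuple(slots))
                if kind == "planted" and pattern not in spec.noise_patterns:
                    planted_ids.append(sentence_id)
            instances.append(inst)
    n_extra = int(round(spec.nonlexicon_rate * len(instances)))
    for _ in range(n_extra):
        sid += 1
        verb = _NONLEXICON_VERBS[int(rng.integers(len(_NONLEXICON_VERBS)))]
        pattern = patterns[int(rng.choice(len(patterns), p=pw))]
        instances.append(
            _instance_from_pattern(
                rng, verb, pattern, f"s{sid:07d}", "active",
                spec.ne_filler_dist, True,
            )
        )
    rng.shuffle(instances)
    truth = {
        "pattern_dist": effective,
        "passive_prob": spec.passive_prob,
        "planted_fact_ids": set(planted_ids),
        "n_off_frame_per_verb": n_off,
        "n_no_ne_per_verb": n_none,
    }
    return instances, truth


def gen_events(spec: FixtureSpec) -> list[EventAnnotation]:
    """Generate role-annotated events per verb from the planted role
    patterns; a fraction of triggers are nominalized forms pointing back at
    the base verb.  Role patterns pair with the grammatical patterns of
    :func:`gen_parsed_corpus` so frame linking succeeds end to end."""
    spec.validate()
    rng = np.random.default_rng(spec.seed + 2)
    events: list[EventAnnotation] = []
    for verb in spec.verbs:
        patterns = spec.role_patterns.get(verb)
        if not patterns:
            continue
        weights = np.array([w for _, w in patterns], dtype=float)
        weights = weights / weights.sum()
        for _ in range(spec.events_per_verb):
            roles = patterns[int(rng.choice(len(patterns), p=weights))][0]
            nominal = rng.random() < spec.nominalized_rate
            trigger = Trigger(
                _NOMINALIZATIONS.get(verb, verb + "ion") if nominal else verb,
                is_nominalized=nominal,
                base_lemma=verb if nominal else None,
            )
            args = tuple(
                EventArgument(role, ne, (0, 0),
                              _NE_TEXTS.get(ne or "", "the {} entity").format("x1"))
                for role, ne in roles
            )
            events.append(EventAnnotation(trigger, args))
    return events


def gen_candidates(
    dictionary: ClusteredDictionary, spec: FixtureSpec
) -> tuple[list[CandidateTerm], dict[str, set[str] | None]]:
    """Generate mined-candidate fixtures against a dictionary.

    Mix of true variants (corruptions of dictionary terms by the spec's own
    recoverable processes, probability above the 0.99 cutoff),
    sub-threshold candidates, and junk strings; returns the candidates and
    surface-form -> expected accession set truth (None marks junk)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed + 3)
    terms = list(dictionary.terms())
    truth: dict[str, set[str] | None] = {}
    out: list[CandidateTerm] = []
    processes = [k for k in spec.process_probs if k in RECOVERABLE_PROCESSES]
    if not processes:
        processes = ["case_change"]

    def true_accessions(term: str) -> set[str]:
        return {a for a, ts in dictionary.clusters.items() if term in ts}

    for i in range(spec.n_true_candidates):
        acc, term = terms[int(rng.integers(len(terms)))]
        corrupted = None
        for kind in rng.permutation(processes):
            corrupted = _apply_process(rng, term, str(kind))
            if corrupted and corrupted != term:
                break
            corrupted = None
        if corrupted is None:
            corrupted = term.upper() if term.upper() != term else term.title()
        p = float(rng.uniform(0.991, 1.0))
        out.append(CandidateTerm(corrupted, p, doc_id=f"d{i}"))
        truth.setdefault(corrupted, true_accessions(term))
    for i in range(spec.n_lowprob_candidates):
        _, term = terms[int(rng.integers(len(terms)))]
        out.append(
            CandidateTerm(term, float(rng.uniform(0.5, 0.99)), doc_id=f"low{i}")
        )
    for i in range(spec.n_junk_candidates):
        junk = "zz" + "".join(rng.choice(list("qxvwkj"), size=6)) + "999"
        out.append(CandidateTerm(junk, float(rng.uniform(0.995, 1.0)), doc_id=f"junk{i}"))
        truth[junk] = None
    return out, truth
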