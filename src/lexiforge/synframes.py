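"""Subcategorization (grammatical) frame induction for verbs.

Input is a parsed corpus of predicate-argument records: one record per verb
instance, with logical (passive-normalized) argument slots — ARG1 is the
logical subject, ARG2 the logical object — plus prepositional, clausal and
adverbial slots.  Actives and passives of the same event therefore share a
frame: "CysB controls the repression ... in E. coli" and "The repression
... is controlled by CysB in E. coli" both canonicalize to ARG1#ARG2#PP-in.

For each verb we estimate P(pattern | verb) by relative frequency, keep
patterns at or above a probability threshold (default 0.03, inclusive),
record the passive-voice percentage and support per frame, and score each
argument slot's association with the verb by the log-likelihood-ratio
statistic G2 on the verb x slot contingency table.
"""

from __future__ import annotations

import json
import math
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "CORE_SLOTS",
    "Slot",
    "ParsedInstance",
    "SynFrame",
    "FrameStats",
    "SlotAssociation",
    "InductionConfig",
    "canonicalize",
    "estimate_frames",
    "passive_rate",
    "slot_loglik",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
]

CORE_SLOTS = ("ARG1", "ARG2", "ARG3")
CLAUSAL_SLOTS = ("THAT-CL", "TO-INF")
FILLER_CATEGORIES = ("NP", "clause", "adverb")


def _slot_sort_key(label: str) -> tuple[int, str]:
    """Canonical slot order: core arguments, clausal complements,
    prepositional slots alphabetically by preposition, adverbs last."""
    if label in CORE_SLOTS:
        return (CORE_SLOTS.index(label), "")
    if label in CLAUSAL_SLOTS:
        return (3 + CLAUSAL_SLOTS.index(label), "")
    if label.startswith("PP-"):
        return (5, label[3:])
    if label == "ADV":
        return (6, "")
    raise ValueError(f"unknown slot label: {label!r}")


def slot_order(labels: Iterable[str]) -> list[str]:
    return sorted(labels, key=_slot_sort_key)


@dataclass(frozen=True)
class Slot:
    label: str
    category: str = "NP"
    ne_type: str | None = None
    text: str | None = None

    def __post_init__(self) -> None:
        _slot_sort_key(self.label)  # validates
        if self.category not in FILLER_CATEGORIES:
            raise ValueError(f"unknown filler category: {self.category!r}")


@dataclass(frozen=True)
class ParsedInstance:
    verb_lemma: str
    sentence_id: str
    voice: str  # active | passive
    slots: tuple[Slot, ...]

    def __post_init__(self) -> None:
        if self.voice not in ("active", "passive"):
            raise ValueError(f"voice must be active or passive, got {self.voice!r}")
        for core in ("ARG1", "ARG2"):
            if sum(1 for s in self.slots if s.label == core) > 1:
                raise ValueError(f"more than one {core} slot")

    def slot_labels(self) -> set[str]:
        return {s.label for s in self.slots}


def canonicalize(instance: ParsedInstance) -> str:
    """Canonical "#"-joined pattern for an instance; repeated prepositions
    collapse to one slot (multiplicity is tracked separately in frames)."""
    labels = sorted(set(s.label for s in instance.slots), key=_slot_sort_key)
    return "#".join(labels)


@dataclass
class SynFrame:
    """A verb's canonical grammatical argument pattern.

    ``ne_fillers`` records the observed named-entity-type distribution per
    slot; ``pp_multiplicity`` the maximum observed repetition of each
    prepositional slot (patterns collapse repeats).
    """

    verb_lemma: str
    pattern: str
    ne_fillers: dict[str, Counter] = field(default_factory=dict)
    pp_multiplicity: dict[str, int] = field(default_factory=dict)

    @property
    def slots(self) -> tuple[str, ...]:
        return tuple(self.pattern.split("#")) if self.pattern else ()


@dataclass(frozen=True)
class FrameStats:
    probability: float
    passive_pct: float
    support: int


@dataclass(frozen=True)
class SlotAssociation:
    verb_lemma: str
    slot_label: str
    ll: float
    counts: tuple[int, int, int, int]  # (v&slot, v&~slot, ~v&slot, ~v&~slot)


@dataclass(frozen=True)
class InductionConfig:
    prob_threshold: float = 0.03
    min_support: int = 1
    verb_list: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.prob_threshold <= 1.0):
            raise ValueError("prob_threshold must be in (0, 1]")


def estimate_frames(
    instances: Sequence[ParsedInstance],
    cfg: InductionConfig = InductionConfig(),
) -> list[tuple[SynFrame, FrameStats]]:
    """Estimate per-verb frame inventories.

    P(pattern | verb) is the relative frequency among the verb's instances;
    frames with probability >= threshold (inclusive) and support >=
    min_support are retained, each with its passive percentage and observed
    NE-filler distribution.
    """
    by_verb: dict[str, list[ParsedInstance]] = defaultdict(list)
    for inst in instances:
        if cfg.verb_list is not None and inst.verb_lemma not in cfg.verb_list:
            continue
        by_verb[inst.verb_lemma].append(inst)

    out: list[tuple[SynFrame, FrameStats]] = []
    for verb in sorted(by_verb):
        verb_insts = by_verb[verb]
        n = len(verb_insts)
        groups: dict[str, list[ParsedInstance]] = defaultdict(list)
        for inst in verb_insts:
            groups[canonicalize(inst)].append(inst)
        for pattern in sorted(groups):
            members = groups[pattern]
            prob = len(members) / n
            if prob < cfg.prob_threshold or len(members) < cfg.min_support:
                continue
            frame = SynFrame(verb, pattern)
            for inst in members:
                per_label: Counter = Counter(s.label for s in inst.slots)
                for lbl, k in per_label.items():
                    if lbl.startswith("PP-"):
                        frame.pp_multiplicity[lbl] = max(
                            frame.pp_multiplicity.get(lbl, 1), k
                        )
                for s in inst.slots:
                    if s.ne_type:
                        frame.ne_fillers.setdefault(s.label, Counter())[s.ne_type] += 1
            passive = sum(1 for i in members if i.voice == "passive")
            out.append(
                (
                    frame,
                    FrameStats(
                        probability=prob,
                        passive_pct=100.0 * passive / len(members),
                        support=len(members),
                    ),
                )
            )
    return out


def passive_rate(instances: Sequence[ParsedInstance], verb: str) -> float:
    """Percentage of a verb's instances in the passive voice (0-100)."""
    verb_insts = [i for i in instances if i.verb_lemma == verb]
    if not verb_insts:
        raise ValueError(f"no instances for verb {verb!r}")
    return 100.0 * sum(1 for i in verb_insts if i.voice == "passive") / len(verb_insts)


def loglik_2x2(a: int, b: int, c: int, d: int) -> float:
    """Likelihood-ratio statistic G2 = 2 * sum O ln(O/E) for a 2x2 table
    with expecteds from the marginals; zero cells contribute zero."""
    n = a + b + c + d
    if n == 0:
        return 0.0
    rows = (a + b, c + d)
    cols = (a + c, b + d)
    obs = ((a, b), (c, d))
    g2 = 0.0
    for i in range(2):
        for j in range(2):
            o = obs[i][j]
            if o == 0:
                continue
            e = rows[i] * cols[j] / n
            g2 += o * math.log(o / e)
    return max(2.0 * g2, 0.0)


def slot_loglik(
    instances: Sequence[ParsedInstance], verb: str, slot: str
) -> SlotAssociation:
    """Association between a verb and an argument slot across the corpus.

    The 2x2 table counts instances of the verb with/without the slot against
    instances of all other verbs with/without it.  Degenerate margins (the
    slot occurs never, or always, corpus-wide) give ll = 0 with a warning.
    """
    verbs = {i.verb_lemma for i in instances}
    if len(verbs) < 2:
        raise ValueError("slot association requires >= 2 distinct verbs")
    a = b = c = d = 0
    for inst in instances:
        has = slot in inst.slot_labels()
        if inst.verb_lemma == verb:
            a, b = a + has, b + (not has)
        else:
            c, d = c + has, d + (not has)
    if (a + c) == 0 or (b + d) == 0:
        warnings.warn(
            f"slot {slot!r} has degenerate corpus margins; ll set to 0",
            stacklevel=2,
        )
        return SlotAssociation(verb, slot, 0.0, (a, b, c, d))
    return SlotAssociation(verb, slot, loglik_2x2(a, b, c, d), (a, b, c, d))


# --- JSONL corpus I/O --------------------------------------------------------

def read_corpus_jsonl(path) -> list[ParsedInstance]:
    """Read one instance per line:
    ``{"verb", "sentence_id", "voice", "slots": [{"label", "category",
    "ne_type"?, "text"?}]}``."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            try:
                slots = tuple(
                    Slot(
                        s["label"],
                        s.get("category", "NP"),
                        s.get("ne_type"),
                        s.get("text"),
                    )
                    for s in rec["slots"]
                )
                out.append(
                    ParsedInstance(
                        rec["verb"], rec.get("sentence_id", f"s{lineno}"),
                        rec.get("voice", "active"), slots
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: bad record ({exc})") from exc
    return out


def write_corpus_jsonl(instances: Iterable[ParsedInstance], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for inst in instances:
            rec = {
                "verb": inst.verb_lemma,
                "sentence_id": inst.sentence_id,
                "voice": inst.voice,
                "slots": [
                    {
                        k: v
                        for k, v in (
                            ("label", s.label),
                            ("category", s.category),
                            ("ne_type", s.ne_type),
                            ("text", s.text),
                        )
                        if v is not None
                    }
                    for s in inst.slots
                ],
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
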