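"""Semantic event frames for verbs, and their linking to grammatical frames.

Events in role-annotated corpora are centred on a verb (or a nominalized
verb such as *regulation*) and carry arguments labelled with one of 13
event-independent semantic roles (AGENT, THEME, MANNER, INSTRUMENT,
LOCATION, SOURCE, DESTINATION, TEMPORAL, CONDITION, RATE,
DESCRIPTIVE-AGENT, DESCRIPTIVE-THEME, PURPOSE) and, where available, a
named-entity class from a small biomedical taxonomy (DNA, PROTEIN,
EXPERIMENTAL, ORGANISMS, PROCESSES, with extensible subtypes such as
PROMOTER under DNA).

Frames aggregate events into verb-specific role patterns with NE fillers,
serialized in the ``activate(Agent=>Protein,Theme=>DNA)`` notation.  Frame
linking aligns a semantic frame with a grammatical frame argument by
argument: prototypic realizations are matched first (AGENT to the logical
subject ARG1, INSTRUMENT to a with/through/using/via/by prepositional
phrase, ...), the remaining roles and slots are aligned left-to-right along
the role and grammatical-function hierarchies, and leftovers on either side
link to 0.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .synframes import SynFrame, slot_order

__all__ = [
    "ROLES",
    "DEFAULT_ROLE_HIERARCHY",
    "NE_TOP_CLASSES",
    "DEFAULT_SUBTYPES",
    "resolve_ne_class",
    "Trigger",
    "EventArgument",
    "EventAnnotation",
    "SemFrame",
    "FrameLink",
    "LinkingRules",
    "LinkConflict",
    "extract_sem_frames",
    "link_frames",
    "link_all",
    "read_events_jsonl",
    "write_events_jsonl",
    "read_events_brat",
]

#: Closed 13-role inventory.
ROLES = (
    "AGENT",
    "THEME",
    "MANNER",
    "INSTRUMENT",
    "LOCATION",
    "SOURCE",
    "DESTINATION",
    "TEMPORAL",
    "CONDITION",
    "RATE",
    "DESCRIPTIVE-AGENT",
    "DESCRIPTIVE-THEME",
    "PURPOSE",
)

#: Default total order: core roles first, descriptives last.
DEFAULT_ROLE_HIERARCHY = (
    "AGENT",
    "THEME",
    "INSTRUMENT",
    "SOURCE",
    "DESTINATION",
    "LOCATION",
    "TEMPORAL",
    "CONDITION",
    "RATE",
    "MANNER",
    "PURPOSE",
    "DESCRIPTIVE-AGENT",
    "DESCRIPTIVE-THEME",
)

NE_TOP_CLASSES = ("DNA", "PROTEIN", "EXPERIMENTAL", "ORGANISMS", "PROCESSES")

#: Extensible subtype -> top-level class map.
DEFAULT_SUBTYPES: dict[str, str] = {
    "PROMOTER": "DNA",
    "GENE": "DNA",
    "OPERON": "DNA",
    "BINDING_SITE": "DNA",
    "RNA": "DNA",
    "ENZYME": "PROTEIN",
    "TRANSCRIPTION_FACTOR": "PROTEIN",
    "PROTEIN_COMPLEX": "PROTEIN",
    "SPECIES": "ORGANISMS",
    "STRAIN": "ORGANISMS",
    "CELL": "ORGANISMS",
    "PLASMID": "EXPERIMENTAL",
    "ASSAY": "EXPERIMENTAL",
    "PROCESS": "PROCESSES",
}


def resolve_ne_class(
    ne_type: str, subtypes: Mapping[str, str] = DEFAULT_SUBTYPES
) -> str:
    """Resolve an annotated NE type to its top-level class."""
    t = ne_type.upper()
    if t in NE_TOP_CLASSES:
        return t
    if t in subtypes:
        return subtypes[t]
    raise ValueError(f"NE type {ne_type!r} does not resolve to a top-level class")


def _display_role(role: str) -> str:
    return "-".join(part.capitalize() for part in role.split("-"))


def _display_ne(ne: str) -> str:
    # short all-caps symbols (DNA, RNA) stay as printed; longer classes are
    # capitalized (PROTEIN -> Protein)
    return ne if len(ne) <= 4 else ne.capitalize()


@dataclass(frozen=True)
class Trigger:
    lemma: str
    is_nominalized: bool = False
    span: tuple[int, int] = (0, 0)
    base_lemma: str | None = None  # verb behind a nominalized trigger

    @property
    def verb(self) -> str:
        return self.base_lemma or self.lemma


@dataclass(frozen=True)
class EventArgument:
    role: str
    ne_type: str | None = None
    span: tuple[int, int] = (0, 0)
    text: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role {self.role!r} not in the 13-role inventory")


@dataclass(frozen=True)
class EventAnnotation:
    trigger: Trigger
    arguments: tuple[EventArgument, ...]

    def __post_init__(self) -> None:
        for role in ("AGENT", "THEME"):
            if sum(1 for a in self.arguments if a.role == role) > 1:
                raise ValueError(f"more than one {role} argument")


@dataclass(frozen=True)
class SemFrame:
    """A verb's semantic role pattern with optional NE-class fillers."""

    verb_lemma: str
    roles: tuple[str, ...]
    fillers: tuple[tuple[str, str], ...] = ()  # (role, top-level NE class)
    support: int = 1

    def filler_of(self, role: str) -> str | None:
        return dict(self.fillers).get(role)

    def serialize(self) -> str:
        parts = []
        fillers = dict(self.fillers)
        for role in self.roles:
            if role in fillers:
                parts.append(f"{_display_role(role)}=>{_display_ne(fillers[role])}")
            else:
                parts.append(_display_role(role))
        return f"{self.verb_lemma}({','.join(parts)})"


@dataclass(frozen=True)
class FrameLink:
    """Argument-level alignment of a semantic and a grammatical frame;
    either side of a pair may be "0" (unmatched)."""

    sem: SemFrame
    syn: SynFrame
    arg_links: tuple[tuple[str, str], ...]  # (role or "0", slot or "0")

    def serialize(self) -> str:
        return "#".join(f"{r} > {s}" for r, s in self.arg_links)


class LinkConflict(Exception):
    """Raised when forced prototypic matches contend for the same slot."""


_PP = re.compile(r"^PP-")


def _pp(*preps: str) -> frozenset[str]:
    return frozenset(f"PP-{p}" for p in preps)


@dataclass(frozen=True)
class LinkingRules:
    """Hierarchies and prototypic realizations steering frame linking."""

    role_hierarchy: tuple[str, ...] = DEFAULT_ROLE_HIERARCHY
    prototypic: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: {
            "AGENT": frozenset({"ARG1"}),
            "THEME": frozenset({"ARG2"}),
            "INSTRUMENT": _pp("with", "through", "using", "via", "by"),
            "SOURCE": _pp("from"),
            "DESTINATION": _pp("to", "into", "onto", "towards", "toward"),
            "LOCATION": _pp("in", "on", "at", "within"),
            "TEMPORAL": _pp("after", "before", "during", "until", "upon"),
            "CONDITION": _pp("under", "without", "upon"),
            "RATE": _pp("by"),
            "MANNER": _pp("by", "through", "via", "in"),
            "PURPOSE": frozenset({"TO-INF"}) | _pp("for"),
            "DESCRIPTIVE-AGENT": frozenset({"ARG3"}) | _pp("as"),
            "DESCRIPTIVE-THEME": frozenset({"ARG3"}) | _pp("as"),
        }
    )

    def role_key(self, role: str) -> int:
        return self.role_hierarchy.index(role)


def extract_sem_frames(
    events: Iterable[EventAnnotation],
    subtypes: Mapping[str, str] = DEFAULT_SUBTYPES,
    role_hierarchy: Sequence[str] = DEFAULT_ROLE_HIERARCHY,
    merge_nominalized: bool = True,
) -> list[SemFrame]:
    """Aggregate events into verb-specific semantic frames.

    One frame per distinct (verb, role pattern, filler pattern) with support
    counts; roles are ordered by the role hierarchy; nominalized triggers
    contribute to their base verb's frames when ``merge_nominalized``.
    """
    order = {r: i for i, r in enumerate(role_hierarchy)}
    counts: dict[tuple[str, tuple[str, ...], tuple[tuple[str, str], ...]], int] = {}
    for ev in events:
        verb = ev.trigger.verb if merge_nominalized else ev.trigger.lemma
        roles = tuple(sorted((a.role for a in ev.arguments), key=order.__getitem__))
        fillers = tuple(
            sorted(
                (
                    (a.role, resolve_ne_class(a.ne_type, subtypes))
                    for a in ev.arguments
                    if a.ne_type
                ),
                key=lambda rf: order[rf[0]],
            )
        )
        key = (verb, roles, fillers)
        counts[key] = counts.get(key, 0) + 1
    return [
        SemFrame(verb, roles, fillers, support=n)
        for (verb, roles, fillers), n in sorted(counts.items())
    ]


def link_frames(
    sem: SemFrame, syn: SynFrame, rules: LinkingRules = LinkingRules()
) -> FrameLink:
    """Align one semantic frame with one grammatical frame.

    Three stages: (1) forced matches through prototypic realizations whose
    admissible slots intersect the frame's unclaimed slots in exactly one
    label, prepositional realizations first; (2) left-to-right alignment of
    the remaining roles and slots along the two hierarchies; (3) leftovers
    link to 0.  A role whose prototypic slots exist in the grammatical frame
    but were all claimed by other roles raises :class:`LinkConflict`.
    """
    if sem.verb_lemma != syn.verb_lemma:
        raise ValueError(
            f"verb mismatch: {sem.verb_lemma!r} vs {syn.verb_lemma!r}"
        )
    roles = sorted(sem.roles, key=rules.role_key)
    slots = slot_order(syn.slots)
    claimed: dict[str, str] = {}  # role -> slot
    taken: set[str] = set()

    def fixpoint(slot_filter) -> None:
        changed = True
        while changed:
            changed = False
            for role in roles:
                if role in claimed:
                    continue
                admissible = rules.prototypic.get(role, frozenset())
                free = [
                    s for s in slots
                    if s in admissible and s not in taken and slot_filter(s)
                ]
                if len(free) == 1:
                    claimed[role] = free[0]
                    taken.add(free[0])
                    changed = True

    fixpoint(lambda s: _PP.match(s))      # preposition-compatible first
    fixpoint(lambda s: not _PP.match(s))  # then core/clausal realizations

    # conflict: prototypic slots present in the frame but all claimed by others
    for role in roles:
        if role in claimed:
            continue
        admissible = rules.prototypic.get(role, frozenset())
        present = [s for s in slots if s in admissible]
        if present and all(s in taken for s in present):
            raise LinkConflict(
                f"{sem.verb_lemma}: role {role} contends for "
                f"{'/'.join(present)} already claimed"
            )

    rest_roles = [r for r in roles if r not in claimed]
    rest_slots = [s for s in slots if s not in taken]
    for role, slot in zip(rest_roles, rest_slots):
        claimed[role] = slot
        taken.add(slot)

    pairs: list[tuple[str, str]] = []
    slot_to_role = {s: r for r, s in claimed.items()}
    for slot in slots:
        pairs.append((slot_to_role.get(slot, "0"), slot))
    for role in roles:
        if role not in claimed:
            pairs.append((role, "0"))
    return FrameLink(sem, syn, tuple(pairs))


def link_all(
    sems: Sequence[SemFrame],
    syns: Sequence[SynFrame],
    rules: LinkingRules = LinkingRules(),
) -> tuple[list[FrameLink], list[tuple[SemFrame, SynFrame, str]]]:
    """Link every same-verb (semantic, grammatical) frame pair; pairs whose
    forced-match stage conflicts are reported, not guessed."""
    links: list[FrameLink] = []
    conflicts: list[tuple[SemFrame, SynFrame, str]] = []
    for sem in sems:
        for syn in syns:
            if sem.verb_lemma != syn.verb_lemma:
                continue
            try:
                links.append(link_frames(sem, syn, rules))
            except LinkConflict as exc:
                conflicts.append((sem, syn, str(exc)))
    return links, conflicts


# --- event I/O ---------------------------------------------------------------

def read_events_jsonl(path) -> list[EventAnnotation]:
    """One event per line: ``{"trigger": {"lemma", "nominalized"?,
    "base_lemma"?, "span"?}, "args": [{"role", "ne_type"?, "span"?,
    "text"?}]}``."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            trig = rec["trigger"]
            try:
                out.append(
                    EventAnnotation(
                        Trigger(
                            trig["lemma"],
                            bool(trig.get("nominalized", False)),
                            tuple(trig.get("span", (0, 0))),
                            trig.get("base_lemma"),
                        ),
                        tuple(
                            EventArgument(
                                a["role"].upper(),
                                a.get("ne_type"),
                                tuple(a.get("span", (0, 0))),
                                a.get("text", ""),
                            )
                            for a in rec["args"]
                        ),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: bad event ({exc})") from exc
    return out


def write_events_jsonl(events: Iterable[EventAnnotation], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ev in events:
            rec = {
                "trigger": {
                    "lemma": ev.trigger.lemma,
                    "nominalized": ev.trigger.is_nominalized,
                    "span": list(ev.trigger.span),
                    **(
                        {"base_lemma": ev.trigger.base_lemma}
                        if ev.trigger.base_lemma
                        else {}
                    ),
                },
                "args": [
                    {
                        "role": a.role,
                        **({"ne_type": a.ne_type} if a.ne_type else {}),
                        "span": list(a.span),
                        "text": a.text,
                    }
                    for a in ev.arguments
                ],
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_events_brat(ann_path, txt_path=None) -> list[EventAnnotation]:
    """Read brat-style standoff: T lines for text-bound spans (triggers use
    the reserved type ``Event``; other T types are NE classes), E lines for
    events with role-labelled argument references."""
    spans: dict[str, tuple[str, tuple[int, int], str]] = {}
    text = ""
    if txt_path is not None:
        with open(txt_path, encoding="utf-8") as fh:
            text = fh.read()
    events: list[EventAnnotation] = []
    with open(ann_path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    for ln in lines:
        if ln.startswith("T"):
            tid, meta, surface = ln.split("\t", 2)
            ttype, start, end = meta.split()
            spans[tid] = (ttype, (int(start), int(end)), surface)
    for ln in lines:
        if not ln.startswith("E"):
            continue
        _, body = ln.split("\t", 1)
        parts = body.split()
        _, trig_id = parts[0].split(":", 1)
        ttype, tspan, tsurface = spans[trig_id]
        trigger = Trigger(tsurface, is_nominalized=ttype == "NomEvent", span=tspan)
        args = []
        for part in parts[1:]:
            role, ref = part.split(":", 1)
            netype, span, surface = spans[ref]
            args.append(
                EventArgument(
                    role.upper(),
                    None if netype in ("Event", "NomEvent", "None") else netype,
                    span,
                    surface or (text[span[0] : span[1]] if text else ""),
                )
            )
        events.append(EventAnnotation(trigger, tuple(args)))
    return events
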