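"""Applying the lexicon: dictionary tagging and frame-filtered fact extraction.

Dictionary tagging walks a token sequence and marks maximal token spans
whose surface form is a known written form in the lexicon with the
``NN-BIOMED`` tag (leftmost-longest greedy matching, case-sensitive first
with a case-folded fallback), so multi-token terms such as *met
protooncogene precursor* are treated as single units.

Fact extraction runs parsed, NE-annotated verb instances through three
lexicon filters: (1) the verb must be a lexicon verb; (2) at least one
argument filler must carry a relevant named entity; (3) the instance's
canonical argument pattern must match a stored grammatical frame
(subsumption: the frame's slots are a subset of the instance's, so extra
adjuncts never block extraction).  Survivors become facts, with semantic
roles assigned through the frame's link to a semantic frame, and a report
tallies how much each filter removed.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from typing import Sequence

from .model import Lexicon
from .semframes import FrameLink
from .synframes import FrameStats, ParsedInstance, SynFrame

__all__ = [
    "DEFAULT_AUXILIARIES",
    "TaggedSpan",
    "Fact",
    "FilterReport",
    "dictionary_tag",
    "extract_facts",
]

#: Auxiliary/copular verbs excluded from the lexical-verb denominator.
DEFAULT_AUXILIARIES = frozenset(
    {"be", "have", "do", "will", "shall", "may", "might", "can", "could",
     "would", "should", "must"}
)


def _nfc(s: str) -> str:
    return unicodedata.normalize("NFC", s)


@dataclass(frozen=True)
class TaggedSpan:
    start: int  # token index, inclusive
    end: int    # token index, exclusive
    text: str
    tag: str | None  # "NN-BIOMED" or None for pass-through tokens
    entry_id: str | None = None


def dictionary_tag(tokens: Sequence[str], lexicon: Lexicon) -> list[TaggedSpan]:
    """Tag a token sequence against the lexicon's form index.

    Greedy leftmost-longest: at each position the longest window whose
    space-joined surface matches a lexicon written form (exact first, then
    case-folded) is tagged ``NN-BIOMED``; unmatched tokens pass through.
    Tagged spans never overlap.
    """
    if not tokens:
        raise ValueError("empty token sequence")
    exact: dict[str, str] = {}
    folded: dict[str, str] = {}
    max_len = 1
    for eid in sorted(lexicon.entries):
        for form in lexicon.entries[eid].written_forms():
            form = _nfc(form)
            exact.setdefault(form, eid)
            folded.setdefault(form.casefold(), eid)
            max_len = max(max_len, len(form.split()))

    spans: list[TaggedSpan] = []
    i = 0
    n = len(tokens)
    while i < n:
        match: tuple[int, str] | None = None
        for w in range(min(max_len, n - i), 0, -1):
            surface = _nfc(" ".join(tokens[i : i + w]))
            eid = exact.get(surface) or folded.get(surface.casefold())
            if eid is not None:
                match = (w, eid)
                break
        if match is not None:
            w, eid = match
            spans.append(
                TaggedSpan(i, i + w, " ".join(tokens[i : i + w]), "NN-BIOMED", eid)
            )
            i += w
        else:
            spans.append(TaggedSpan(i, i + 1, tokens[i], None))
            i += 1
    return spans


@dataclass(frozen=True)
class FactArgument:
    slot_label: str
    role: str | None
    text: str | None
    ne_type: str | None


@dataclass(frozen=True)
class Fact:
    verb_lemma: str
    sentence_id: str
    arguments: tuple[FactArgument, ...]
    frame: SynFrame
    link: FrameLink | None


@dataclass
class FilterReport:
    """Tally of the three fact-extraction filters.

    Invariant: verbs_in_lexicon = facts_extracted + frame_mismatch +
    absence_of_ne, and facts_with_prep_args <= facts_extracted.
    """

    total_lexical_verbs: int = 0
    verbs_in_lexicon: int = 0
    facts_extracted: int = 0
    frame_mismatch: int = 0
    absence_of_ne: int = 0
    facts_with_prep_args: int = 0

    def fractions(self) -> dict[str, float]:
        out: dict[str, float] = {}
        if self.total_lexical_verbs:
            out["verbs_in_lexicon_pct"] = (
                100.0 * self.verbs_in_lexicon / self.total_lexical_verbs
            )
        if self.verbs_in_lexicon:
            out["facts_extracted_pct"] = (
                100.0 * self.facts_extracted / self.verbs_in_lexicon
            )
            out["frame_mismatch_pct"] = (
                100.0 * self.frame_mismatch / self.verbs_in_lexicon
            )
            out["absence_of_ne_pct"] = (
                100.0 * self.absence_of_ne / self.verbs_in_lexicon
            )
        if self.facts_extracted:
            out["facts_with_prep_args_pct"] = (
                100.0 * self.facts_with_prep_args / self.facts_extracted
            )
        return out


def _choose_frame(
    labels: set[str],
    frames: Sequence[tuple[SynFrame, FrameStats]],
) -> SynFrame | None:
    """Most specific frame subsuming the instance (largest slot set; ties
    break on higher probability, then pattern for determinism)."""
    best: tuple[int, float, str] | None = None
    chosen = None
    for frame, stats in frames:
        if set(frame.slots) <= labels:
            key = (len(frame.slots), stats.probability, frame.pattern)
            if best is None or key > best:
                best, chosen = key, frame
    return chosen


def extract_facts(
    instances: Sequence[ParsedInstance],
    lexicon: Lexicon,
    frames: Sequence[tuple[SynFrame, FrameStats]],
    links: Sequence[FrameLink] = (),
    auxiliaries: frozenset[str] = DEFAULT_AUXILIARIES,
) -> tuple[list[Fact], FilterReport]:
    """Run the three lexicon filters over parsed, NE-annotated instances.

    Returns the surviving facts (with roles assigned via each frame's first
    matching link, if any) and the filter report.
    """
    verb_entries = {
        e.lemma for e in lexicon.entries.values() if e.pos == "verb"
    }
    frames_by_verb: dict[str, list[tuple[SynFrame, FrameStats]]] = {}
    for frame, stats in frames:
        frames_by_verb.setdefault(frame.verb_lemma, []).append((frame, stats))
    links_by_frame: dict[tuple[str, str], FrameLink] = {}
    for link in links:
        links_by_frame.setdefault(
            (link.syn.verb_lemma, link.syn.pattern), link
        )

    report = FilterReport()
    facts: list[Fact] = []
    for inst in instances:
        if inst.verb_lemma in auxiliaries:
            continue
        report.total_lexical_verbs += 1
        if inst.verb_lemma not in verb_entries:  # filter 1
            continue
        report.verbs_in_lexicon += 1
        if not any(s.ne_type for s in inst.slots):  # filter 2
            report.absence_of_ne += 1
            continue
        frame = _choose_frame(
            inst.slot_labels(), frames_by_verb.get(inst.verb_lemma, ())
        )
        if frame is None:  # filter 3
            report.frame_mismatch += 1
            continue
        link = links_by_frame.get((frame.verb_lemma, frame.pattern))
        slot_roles: dict[str, str] = {}
        if link is not None:
            slot_roles = {
                slot: role
                for role, slot in link.arg_links
                if role != "0" and slot != "0"
            }
        args = tuple(
            FactArgument(s.label, slot_roles.get(s.label), s.text, s.ne_type)
            for s in inst.slots
        )
        facts.append(Fact(inst.verb_lemma, inst.sentence_id, args, frame, link))
        report.facts_extracted += 1
        if any(s.label.startswith("PP-") for s in inst.slots
               if s.label in frame.slots):
            report.facts_with_prep_args += 1
    return facts, report
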