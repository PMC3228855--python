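"""Semantic frame extraction and syntax-semantics frame linking."""

from __future__ import annotations

import pytest

from lexiforge.fixtures import FixtureSpec, gen_events, gen_parsed_corpus
from lexiforge.semframes import (
    DEFAULT_ROLE_HIERARCHY,
    ROLES,
    EventAnnotation,
    EventArgument,
    FrameLink,
    LinkConflict,
    SemFrame,
    Trigger,
    extract_sem_frames,
    link_all,
    link_frames,
    read_events_brat,
    read_events_jsonl,
    resolve_ne_class,
    write_events_jsonl,
)
from lexiforge.synframes import InductionConfig, SynFrame, estimate_frames


def fis_event() -> EventAnnotation:
    return EventAnnotation(
        Trigger("activate", span=(4, 13)),
        (
            EventArgument("AGENT", "PROTEIN", (0, 3), "Fis"),
            EventArgument("THEME", "DNA", (14, 21), "rrnB P1"),
        ),
    )


class TestInventories:
    def test_role_inventory_has_thirteen_roles(self):
        assert len(ROLES) == 13
        assert set(DEFAULT_ROLE_HIERARCHY) == set(ROLES)

    def test_subtypes_resolve_to_top_classes(self):
        assert resolve_ne_class("PROMOTER") == "DNA"
        assert resolve_ne_class("PROTEIN") == "PROTEIN"
        with pytest.raises(ValueError):
            resolve_ne_class("GADGET")

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError):
            EventArgument("VICTIM")

    def test_double_agent_rejected(self):
        with pytest.raises(ValueError):
            EventAnnotation(
                Trigger("bind"),
                (EventArgument("AGENT"), EventArgument("AGENT")),
            )


class TestExtractSemFrames:
    def test_fis_rrnb_worked_example(self):
        frames = extract_sem_frames([fis_event()])
        assert len(frames) == 1
        assert frames[0].serialize() == "activate(Agent=>Protein,Theme=>DNA)"

    def test_theme_only_verb(self):
        ev = EventAnnotation(
            Trigger("accumulate"),
            (EventArgument("THEME", "PROTEIN", text="free rRNA"),),
        )
        (frame,) = extract_sem_frames([ev])
        assert frame.serialize() == "accumulate(Theme=>Protein)"

    def test_empty_corpus(self):
        assert extract_sem_frames([]) == []

    def test_nominalized_trigger_merges_into_base_verb(self):
        nominal = EventAnnotation(
            Trigger("activation", is_nominalized=True, base_lemma="activate"),
            (
                EventArgument("AGENT", "PROTEIN"),
                EventArgument("THEME", "DNA"),
            ),
        )
        frames = extract_sem_frames([fis_event(), nominal])
        assert len(frames) == 1
        assert frames[0].verb_lemma == "activate"
        assert frames[0].support == 2
        separate = extract_sem_frames([fis_event(), nominal],
                                      merge_nominalized=False)
        assert {f.verb_lemma for f in separate} == {"activate", "activation"}

    def test_roles_ordered_by_hierarchy(self):
        ev = EventAnnotation(
            Trigger("transcribe"),
            (
                EventArgument("SOURCE", "DNA"),
                EventArgument("AGENT", "PROTEIN"),
                EventArgument("THEME", "DNA"),
            ),
        )
        (frame,) = extract_sem_frames([ev])
        assert frame.roles == ("AGENT", "THEME", "SOURCE")


class TestLinkFrames:
    def test_equal_arity_worked_example(self):
        sem = SemFrame("activate", ("AGENT", "THEME"))
        link = link_frames(sem, SynFrame("activate", "ARG1#ARG2"))
        assert link.serialize() == "AGENT > ARG1#THEME > ARG2"

    def test_grammatical_surplus_worked_example(self):
        sem = SemFrame("clone", ("THEME", "DESTINATION"))
        link = link_frames(sem, SynFrame("clone", "ARG1#ARG2#PP-into"))
        assert link.serialize() == "0 > ARG1#THEME > ARG2#DESTINATION > PP-into"

    def test_semantic_surplus_worked_example(self):
        sem = SemFrame("express", ("AGENT", "THEME", "LOCATION", "CONDITION"))
        link = link_frames(sem, SynFrame("express", "ARG1#ARG2#PP-in"))
        assert link.serialize() == (
            "AGENT > ARG1#THEME > ARG2#LOCATION > PP-in#CONDITION > 0"
        )

    def test_transcribe_source_alignment(self):
        sem = SemFrame("transcribe", ("AGENT", "THEME", "SOURCE"))
        link = link_frames(sem, SynFrame("transcribe", "ARG1#ARG2#PP-from"))
        assert link.serialize() == "AGENT > ARG1#THEME > ARG2#SOURCE > PP-from"

    def test_unaccusative_theme_takes_subject_slot(self):
        sem = SemFrame("accumulate", ("THEME",))
        link = link_frames(sem, SynFrame("accumulate", "ARG1"))
        assert link.serialize() == "THEME > ARG1"

    def test_verb_mismatch_rejected(self):
        with pytest.raises(ValueError):
            link_frames(SemFrame("a", ("AGENT",)), SynFrame("b", "ARG1"))

    def test_bijectivity_with_zeros(self):
        sem = SemFrame("express", ("AGENT", "THEME", "LOCATION", "CONDITION"))
        syn = SynFrame("express", "ARG1#ARG2#PP-in")
        link = link_frames(sem, syn)
        roles = [r for r, _ in link.arg_links if r != "0"]
        slots = [s for _, s in link.arg_links if s != "0"]
        assert len(roles) == len(set(roles)) == len(sem.roles)
        assert len(slots) == len(set(slots)) == len(syn.slots)
        zeros = sum(1 for r, s in link.arg_links if r == "0" or s == "0")
        assert zeros == abs(len(sem.roles) - len(syn.slots))

    def test_hierarchy_consistency_on_core_slots(self):
        sem = SemFrame("bind", ("AGENT", "THEME"))
        link = link_frames(sem, SynFrame("bind", "ARG1#ARG2"))
        mapping = dict(link.arg_links[::-1])
        pairs = {r: s for r, s in link.arg_links if r != "0" and s != "0"}
        assert pairs["AGENT"] < pairs["THEME"]  # ARG1 before ARG2

    def test_competing_prototypic_pp_raises_conflict(self):
        # INSTRUMENT and RATE both admit only PP-by here
        sem = SemFrame("elevate", ("INSTRUMENT", "RATE"))
        with pytest.raises(LinkConflict):
            link_frames(sem, SynFrame("elevate", "ARG1#PP-by"))


class TestLinkAll:
    def test_conflicting_pair_reported_not_guessed(self):
        sems = [
            SemFrame("elevate", ("AGENT", "THEME")),
            SemFrame("elevate", ("INSTRUMENT", "RATE")),
        ]
        syns = [
            SynFrame("elevate", "ARG1#ARG2"),
            SynFrame("elevate", "ARG1#PP-by"),
        ]
        links, conflicts = link_all(sems, syns)
        assert len(links) == 3
        assert len(conflicts) == 1

    def test_disjoint_verb_sets_yield_nothing(self):
        links, conflicts = link_all(
            [SemFrame("a", ("AGENT",))], [SynFrame("b", "ARG1")]
        )
        assert links == [] and conflicts == []

    def test_paired_fixtures_link_end_to_end(self):
        spec = FixtureSpec(seed=6, instances_per_verb=300)
        sems = extract_sem_frames(gen_events(spec))
        instances, _ = gen_parsed_corpus(spec)
        syns = [f for f, _ in estimate_frames(instances)]
        links, conflicts = link_all(sems, syns)
        assert conflicts == []
        linked_verbs = {l.sem.verb_lemma for l in links}
        assert linked_verbs == set(spec.verbs)


class TestEventIO:
    def test_jsonl_round_trip(self, tmp_path):
        events = gen_events(FixtureSpec(seed=4, events_per_verb=10))
        path = tmp_path / "events.jsonl"
        write_events_jsonl(events, path)
        back = read_events_jsonl(path)
        assert [e.trigger.verb for e in back] == [e.trigger.verb for e in events]
        assert [e.arguments for e in back] != []

    def test_brat_standoff(self, tmp_path):
        txt = tmp_path / "doc.txt"
        ann = tmp_path / "doc.ann"
        txt.write_text("Fis activates rrnB P1")
        ann.write_text(
            "T1\tPROTEIN 0 3\tFis\n"
            "T2\tEvent 4 13\tactivates\n"
            "T3\tDNA 14 21\trrnB P1\n"
            "E1\tEvent:T2 Agent:T1 Theme:T3\n"
        )
        (event,) = read_events_brat(ann, txt)
        assert event.trigger.lemma == "activates"
        assert {(a.role, a.ne_type) for a in event.arguments} == {
            ("AGENT", "PROTEIN"),
            ("THEME", "DNA"),
        }
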