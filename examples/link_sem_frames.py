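"""Extract a semantic frame from an annotated event and link frame pairs.

Shows the *Fis activates rrnB P1* annotation becoming a role frame, and
the three canonical alignment cases: equal arity, grammatical surplus
(agentless passive), and semantic surplus (a role with no grammatical
counterpart).
"""

from lexiforge import (
    EventAnnotation,
    EventArgument,
    SemFrame,
    SynFrame,
    Trigger,
    extract_sem_frames,
    link_frames,
)

event = EventAnnotation(
    Trigger("activate", span=(4, 13)),
    (
        EventArgument("AGENT", "PROTEIN", (0, 3), "Fis"),
        EventArgument("THEME", "DNA", (14, 21), "rrnB P1"),
    ),
)
(frame,) = extract_sem_frames([event])
print("semantic frame:", frame.serialize())

cases = [
    ("equal arity", SemFrame("activate", ("AGENT", "THEME")),
     SynFrame("activate", "ARG1#ARG2")),
    ("grammatical surplus", SemFrame("clone", ("THEME", "DESTINATION")),
     SynFrame("clone", "ARG1#ARG2#PP-into")),
    ("semantic surplus",
     SemFrame("express", ("AGENT", "THEME", "LOCATION", "CONDITION")),
     SynFrame("express", "ARG1#ARG2#PP-in")),
]
for label, sem, syn in cases:
    link = link_frames(sem, syn)
    print(f"{label:20s} {syn.pattern:18s} -> {link.serialize()}")
# "ROLE > SLOT" pairs; 0 marks an argument with no counterpart on the
# other side (e.g. the unexpressed AGENT of an agentless passive).
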