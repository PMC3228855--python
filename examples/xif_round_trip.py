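"""Serialize a lexicon to XIF and load it back, staged and all-or-nothing.

Builds a tiny lexicon (one protein noun with variants and an accession
link, one verb with a stored frame), round-trips it through XIF, then
corrupts the file to show that staged loading commits nothing on failure.
"""

import tempfile
from pathlib import Path

from lexiforge import (
    AccessionLink,
    FrameRecord,
    LexicalEntry,
    Lexicon,
    Variant,
    load_xif,
    save_xif,
)
from lexiforge.model import XifValidationError

lex = Lexicon()
noun = LexicalEntry("N-0001", "interleukin-2", "noun", semantic_type="Protein")
noun.accession_links.append(AccessionLink("UniProt", "P60568", curated=True))
noun.variants.append(Variant("IL-2", "acronym", "UniProt"))
noun.variants.append(Variant("il2", "text-mined", "corpus", 0.91))
lex.add(noun)
verb = LexicalEntry("V-0001", "activate", "verb")
verb.frames.append(FrameRecord("syn", "ARG1#ARG2", (("probability", "0.60"),)))
lex.add(verb)

tmp = Path(tempfile.mkdtemp())
path = tmp / "lexicon.xif"
save_xif(lex, path)
print(path.read_text()[:500], "...")
back = load_xif(path)
print("round trip structural identity:", back == lex)
print("form index for 'IL-2':", back.lookup("IL-2"))

broken = tmp / "broken.xif"
broken.write_text(path.read_text().replace('pos="verb"', 'pos="verbish"'))
try:
    load_xif(broken)
except XifValidationError as exc:
    print("staged load rejected corrupted file:", exc.problems)
# validation failure commits nothing: there is no partially loaded lexicon
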