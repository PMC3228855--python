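"""Lexicon data model and XIF (XML interchange format) round-tripping.

The model follows the Lexical Markup Framework style: a lexicon is a set of
lexical entries, each carrying a lemma, part of speech, an optional semantic
type, accession links into reference databases (UniProt, ChEBI, NCBI
taxonomy, ...), scored written variants, inflected word forms, derivational
relations to other entries, and free attribute-value data categories.

Serialization is a deliberately small, deterministic XML dialect (see
docs/xif.md): entries ordered by id, attributes in fixed order, so that two
saves of the same lexicon are byte-identical and load/save round-trips are
exact.  Loading is staged: the file is parsed and fully validated before
anything is committed, so a corrupted input never yields a partial lexicon.
"""

from __future__ import annotations

import fnmatch
import hashlib
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from lxml import etree

__all__ = [
    "POS_TAGS",
    "SEMANTIC_TYPES",
    "VARIANT_TYPES",
    "RELATION_KINDS",
    "Variant",
    "WordForm",
    "AccessionLink",
    "DataCategory",
    "FrameRecord",
    "LexicalEntry",
    "Lexicon",
    "XifError",
    "XifValidationError",
    "load_xif",
    "save_xif",
    "staged_load",
    "filter_import_terms",
    "DEFAULT_STOPLIST",
]

POS_TAGS = ("noun", "verb", "adjective", "adverb")

#: Closed inventory of term semantic types.
SEMANTIC_TYPES = (
    "Cell",
    "Cell Component",
    "Chemical",
    "Disease",
    "Enzyme",
    "Gene",
    "Ligand",
    "Nuclear Receptor",
    "Nucleic Acid Region",
    "Operon",
    "Organism",
    "Transcription-Factor-Binding-Site",
    "Protein",
    "Protein Complex",
    "Protein Domain",
    "Transcription Regulator",
)

VARIANT_TYPES = (
    "orthographic",
    "morphological",
    "acronym",
    "synonym",
    "structural",
    "semantic",
    "text-mined",
)

RELATION_KINDS = (
    "nominalization",
    "adjectival",
    "adverbial",
    "orthographic-variant",
    "nominalized-verb-of",
)


def _nfc(s: str) -> str:
    return unicodedata.normalize("NFC", s)


@dataclass(frozen=True)
class Variant:
    written_form: str
    variant_type: str = "synonym"
    source: str = "unknown"
    confidence_score: float = 1.0

    def __post_init__(self) -> None:
        if not self.written_form:
            raise ValueError("variant written_form must be non-empty")
        if self.variant_type not in VARIANT_TYPES:
            raise ValueError(f"unknown variant type: {self.variant_type!r}")
        if not (0.0 <= self.confidence_score <= 1.0):
            raise ValueError("confidence_score must be in [0, 1]")
        if self.confidence_score < 1.0 and self.source != "corpus":
            raise ValueError(
                "confidence_score < 1.0 is reserved for corpus-derived variants"
            )


@dataclass(frozen=True)
class WordForm:
    written_form: str
    features: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.written_form:
            raise ValueError("word form must be non-empty")


@dataclass(frozen=True)
class AccessionLink:
    database_name: str
    accession_id: str
    curated: bool = False


@dataclass(frozen=True)
class DataCategory:
    attribute: str
    value: str

    def __post_init__(self) -> None:
        if not self.attribute:
            raise ValueError("data category attribute must be non-empty")


@dataclass(frozen=True)
class FrameRecord:
    """Serialized frame attached to a verb entry.

    ``kind`` is ``syn`` (grammatical pattern, e.g. ``ARG1#ARG2#PP-in``),
    ``sem`` (role pattern, e.g. ``activate(Agent=>Protein,Theme=>DNA)``) or
    ``link`` (argument alignment, e.g. ``AGENT > ARG1#THEME > ARG2``).
    Statistics travel as string attributes so round-tripping is exact.
    """

    kind: str
    text: str
    attrs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("syn", "sem", "link"):
            raise ValueError(f"unknown frame kind: {self.kind!r}")
        if not self.text:
            raise ValueError("frame text must be non-empty")


@dataclass(eq=False)
class LexicalEntry:
    entry_id: str
    lemma: str
    pos: str
    semantic_type: str | None = None
    accession_links: list[AccessionLink] = field(default_factory=list)
    variants: list[Variant] = field(default_factory=list)
    inflected_forms: list[WordForm] = field(default_factory=list)
    related_entries: list[tuple[str, str]] = field(default_factory=list)
    data_categories: list[DataCategory] = field(default_factory=list)
    frequency: list[tuple[str, int]] = field(default_factory=list)
    frames: list[FrameRecord] = field(default_factory=list)

    def _canonical(self):
        # collection order is not meaningful; serialization sorts it anyway
        return (
            self.entry_id,
            self.lemma,
            self.pos,
            self.semantic_type,
            sorted(self.accession_links,
                   key=lambda a: (a.database_name, a.accession_id)),
            sorted(self.variants, key=lambda v: (v.written_form, v.variant_type)),
            sorted(self.inflected_forms, key=lambda w: w.written_form),
            sorted(self.related_entries),
            sorted(self.data_categories, key=lambda d: (d.attribute, d.value)),
            sorted(self.frequency),
            sorted(self.frames, key=lambda f: (f.kind, f.text)),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LexicalEntry):
            return NotImplemented
        return self._canonical() == other._canonical()

    def validate(self) -> list[str]:
        problems = []
        if not self.lemma:
            problems.append(f"{self.entry_id}: empty lemma")
        if self.pos not in POS_TAGS:
            problems.append(f"{self.entry_id}: unknown pos {self.pos!r}")
        if self.semantic_type is not None and self.semantic_type not in SEMANTIC_TYPES:
            problems.append(
                f"{self.entry_id}: unknown semantic type {self.semantic_type!r}"
            )
        seen_var = set()
        for v in self.variants:
            key = (v.written_form, v.variant_type)
            if key in seen_var:
                problems.append(
                    f"{self.entry_id}: duplicate variant {key!r}"
                )
            seen_var.add(key)
        seen_acc = set()
        for a in self.accession_links:
            key = (a.database_name, a.accession_id)
            if key in seen_acc:
                problems.append(f"{self.entry_id}: duplicate accession link {key!r}")
            seen_acc.add(key)
        for _, kind in self.related_entries:
            if kind not in RELATION_KINDS:
                problems.append(f"{self.entry_id}: unknown relation kind {kind!r}")
        return problems

    def written_forms(self) -> set[str]:
        forms = {self.lemma}
        forms.update(v.written_form for v in self.variants)
        forms.update(w.written_form for w in self.inflected_forms)
        return forms

    @staticmethod
    def derive_id(lemma: str, pos: str) -> str:
        digest = hashlib.sha256(f"{_nfc(lemma)}\t{pos}".encode()).hexdigest()[:12]
        return f"E-{digest}"


class Lexicon:
    """Collection of lexical entries with a derived written-form index."""

    def __init__(self, entries: Iterable[LexicalEntry] = ()) -> None:
        self.entries: dict[str, LexicalEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: LexicalEntry) -> None:
        if entry.entry_id in self.entries:
            raise ValueError(f"duplicate entry id {entry.entry_id!r}")
        self.entries[entry.entry_id] = entry
        self._index = None

    _index: dict[str, set[str]] | None = None

    @property
    def form_index(self) -> dict[str, set[str]]:
        if self._index is None:
            idx: dict[str, set[str]] = {}
            for eid, entry in self.entries.items():
                for form in entry.written_forms():
                    idx.setdefault(_nfc(form), set()).add(eid)
            self._index = idx
        return self._index

    def lookup(self, form: str) -> set[str]:
        return set(self.form_index.get(_nfc(form), set()))

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Lexicon):
            return NotImplemented
        return self.entries == other.entries

    def validate(self) -> list[str]:
        problems = []
        for entry in self.entries.values():
            problems.extend(entry.validate())
            for target, kind in entry.related_entries:
                if target not in self.entries:
                    problems.append(
                        f"{entry.entry_id}: related entry {target!r} not in lexicon"
                    )
        return problems


class XifError(Exception):
    """Malformed XIF input (XML parse failure)."""


class XifValidationError(Exception):
    """Schema-level violations; carries the full list of problems."""

    def __init__(self, problems: Sequence[str]):
        super().__init__("; ".join(problems))
        self.problems = list(problems)


# --- serialization -----------------------------------------------------------

def _entry_to_xml(entry: LexicalEntry) -> etree._Element:
    el = etree.Element("Entry", id=entry.entry_id, pos=entry.pos)
    lemma = etree.SubElement(el, "Lemma")
    lemma.set("writtenForm", entry.lemma)
    if entry.semantic_type is not None:
        etree.SubElement(el, "SemanticType").set("value", entry.semantic_type)
    for a in sorted(entry.accession_links,
                    key=lambda a: (a.database_name, a.accession_id)):
        acc = etree.SubElement(el, "AccessionLink")
        acc.set("db", a.database_name)
        acc.set("id", a.accession_id)
        acc.set("curated", "true" if a.curated else "false")
    for v in sorted(entry.variants, key=lambda v: (v.written_form, v.variant_type)):
        var = etree.SubElement(el, "Variant")
        var.set("writtenForm", v.written_form)
        var.set("type", v.variant_type)
        var.set("source", v.source)
        var.set("confidence", repr(v.confidence_score))
    for w in sorted(entry.inflected_forms, key=lambda w: w.written_form):
        wf = etree.SubElement(el, "WordForm")
        wf.set("writtenForm", w.written_form)
        for attr, val in w.features:
            feat = etree.SubElement(wf, "Feature")
            feat.set("att", attr)
            feat.set("val", val)
    for target, kind in sorted(entry.related_entries):
        rel = etree.SubElement(el, "Related")
        rel.set("entry", target)
        rel.set("relation", kind)
    for dc in sorted(entry.data_categories, key=lambda d: (d.attribute, d.value)):
        d = etree.SubElement(el, "DC")
        d.set("att", dc.attribute)
        d.set("val", dc.value)
    for corpus, count in sorted(entry.frequency):
        f = etree.SubElement(el, "Frequency")
        f.set("corpus", corpus)
        f.set("count", str(count))
    for fr in sorted(entry.frames, key=lambda f: (f.kind, f.text)):
        fe = etree.SubElement(el, "Frame")
        fe.set("kind", fr.kind)
        fe.set("text", fr.text)
        for attr, val in fr.attrs:
            a = etree.SubElement(fe, "Stat")
            a.set("att", attr)
            a.set("val", val)
    return el


def save_xif(lexicon: Lexicon, path) -> None:
    """Write a lexicon as XIF XML; deterministic (byte-identical re-saves)."""
    problems = lexicon.validate()
    if problems:
        raise XifValidationError(problems)
    root = etree.Element("Lexicon")
    for eid in sorted(lexicon.entries):
        root.append(_entry_to_xml(lexicon.entries[eid]))
    tree = etree.ElementTree(root)
    tree.write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def _parse_entry(el: etree._Element, problems: list[str]) -> LexicalEntry:
    eid = el.get("id") or ""
    pos = el.get("pos") or ""
    lemma_el = el.find("Lemma")
    lemma = lemma_el.get("writtenForm") if lemma_el is not None else ""
    if not eid:
        problems.append("entry without id")
    sem_el = el.find("SemanticType")
    entry = LexicalEntry(
        entry_id=eid,
        lemma=lemma or "",
        pos=pos,
        semantic_type=sem_el.get("value") if sem_el is not None else None,
    )
    for acc in el.findall("AccessionLink"):
        entry.accession_links.append(
            AccessionLink(acc.get("db") or "", acc.get("id") or "",
                          acc.get("curated") == "true")
        )
    for var in el.findall("Variant"):
        try:
            entry.variants.append(
                Variant(
                    var.get("writtenForm") or "",
                    var.get("type") or "synonym",
                    var.get("source") or "unknown",
                    float(var.get("confidence") or 1.0),
                )
            )
        except ValueError as exc:
            problems.append(f"{eid}: bad variant ({exc})")
    for wf in el.findall("WordForm"):
        feats = tuple(
            (f.get("att") or "", f.get("val") or "") for f in wf.findall("Feature")
        )
        try:
            entry.inflected_forms.append(WordForm(wf.get("writtenForm") or "", feats))
        except ValueError as exc:
            problems.append(f"{eid}: bad word form ({exc})")
    for rel in el.findall("Related"):
        entry.related_entries.append((rel.get("entry") or "", rel.get("relation") or ""))
    for dc in el.findall("DC"):
        try:
            entry.data_categories.append(
                DataCategory(dc.get("att") or "", dc.get("val") or "")
            )
        except ValueError as exc:
            problems.append(f"{eid}: bad data category ({exc})")
    for f in el.findall("Frequency"):
        entry.frequency.append((f.get("corpus") or "", int(f.get("count") or 0)))
    for fe in el.findall("Frame"):
        attrs = tuple(
            (s.get("att") or "", s.get("val") or "") for s in fe.findall("Stat")
        )
        try:
            entry.frames.append(FrameRecord(fe.get("kind") or "", fe.get("text") or "", attrs))
        except ValueError as exc:
            problems.append(f"{eid}: bad frame ({exc})")
    return entry


def staged_load(path) -> Lexicon:
    """Two-phase load: parse and validate everything into a staging list,
    commit to a Lexicon only if validation passes (all-or-nothing).

    Raises :class:`XifError` on malformed XML (message names the line) and
    :class:`XifValidationError` listing every offending entry otherwise.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise XifError(f"{path}: XML parse error: {exc}") from exc
    root = tree.getroot()
    if root.tag != "Lexicon":
        raise XifValidationError([f"root element is {root.tag!r}, expected Lexicon"])

    problems: list[str] = []
    staging: list[LexicalEntry] = []
    seen_ids: set[str] = set()
    for el in root.findall("Entry"):
        entry = _parse_entry(el, problems)
        if entry.entry_id in seen_ids:
            problems.append(f"duplicate entry id {entry.entry_id!r}")
        seen_ids.add(entry.entry_id)
        problems.extend(entry.validate())
        staging.append(entry)
    for entry in staging:
        for target, _ in entry.related_entries:
            if target not in seen_ids:
                problems.append(
                    f"{entry.entry_id}: related entry {target!r} not in lexicon"
                )
    if problems:
        raise XifValidationError(problems)
    return Lexicon(staging)


#: alias: loading is always staged
load_xif = staged_load


DEFAULT_STOPLIST = (
    "hypothetical protein*",
    "uncharacterized protein*",
    "putative uncharacterized protein*",
    "unknown protein*",
    "predicted protein*",
)


def filter_import_terms(
    terms: Sequence[tuple[str, str, str]],
    stoplist: Sequence[str] = DEFAULT_STOPLIST,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Partition ``(accession, term, source)`` rows into (kept, rejected).

    Low-information formal labels (e.g. high-throughput placeholders like
    "hypothetical protein") are rejected by case-insensitive literal or
    ``fnmatch``-style wildcard patterns; order is preserved.
    """
    pats = [p.lower() for p in stoplist]
    kept, rejected = [], []
    for row in terms:
        term = row[1].lower()
        if any(fnmatch.fnmatchcase(term, p) for p in pats):
            rejected.append(row)
        else:
            kept.append(row)
    return kept, rejected
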