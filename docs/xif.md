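# XIF: the XML interchange format

`lexiforge` serializes lexicons in a small, deterministic XML dialect
(XIF).  The dialect is deliberately minimal: it exists so that lexicons can
be exchanged, diffed and round-tripped exactly, and so that loading can be
staged (parse → validate everything → commit all-or-nothing).

## Structure

```xml
<?xml version='1.0' encoding='UTF-8'?>
<Lexicon>
  <Entry id="N-ACC00001" pos="noun">
    <Lemma writtenForm="interleukin-2"/>
    <SemanticType value="Protein"/>
    <AccessionLink db="UniProt" id="P60568" curated="true"/>
    <Variant writtenForm="IL-2" type="acronym" source="UniProt" confidence="1.0"/>
    <Variant writtenForm="il2 variant" type="text-mined" source="corpus" confidence="0.87"/>
    <WordForm writtenForm="interleukins-2">
      <Feature att="number" val="plural"/>
    </WordForm>
    <Related entry="V-00" relation="nominalized-verb-of"/>
    <DC att="SourceDC" val="UniProt"/>
    <Frequency corpus="MEDLINE" count="1234"/>
    <Frame kind="syn" text="ARG1#ARG2">
      <Stat att="probability" val="0.60"/>
    </Frame>
  </Entry>
</Lexicon>
```

## Elements

| element | attributes | notes |
|---|---|---|
| `Lexicon` | — | root; holds `Entry` elements sorted by `id` |
| `Entry` | `id`, `pos` | `pos` ∈ noun, verb, adjective, adverb |
| `Lemma` | `writtenForm` | required, non-empty |
| `SemanticType` | `value` | optional; closed inventory (Cell, Chemical, Disease, Enzyme, Gene, Protein, ...) |
| `AccessionLink` | `db`, `id`, `curated` | unique (`db`, `id`) per entry |
| `Variant` | `writtenForm`, `type`, `source`, `confidence` | `confidence` < 1 only for `source="corpus"`; `type` ∈ orthographic, morphological, acronym, synonym, structural, semantic, text-mined |
| `WordForm` | `writtenForm` | inflected form; nested `Feature att= val=` pairs |
| `Related` | `entry`, `relation` | relation ∈ nominalization, adjectival, adverbial, orthographic-variant, nominalized-verb-of; target must exist in the lexicon |
| `DC` | `att`, `val` | free attribute-value data category |
| `Frequency` | `corpus`, `count` | corpus occurrence metadata |
| `Frame` | `kind`, `text` | kind ∈ syn, sem, link; `text` is the frame serialization; nested `Stat att= val=` pairs carry statistics as strings |

## Determinism

`save_xif` emits entries sorted by id and all collections in a fixed sort
order with a fixed attribute order, so two saves of the same lexicon are
byte-identical, and `save(load(F))` is byte-identical to `F` for any file
`F` that `save_xif` produced.

## Staged loading

`staged_load` (alias `load_xif`) parses the whole file into a volatile
staging structure, validates every entry (unknown part of speech, empty
lemma, duplicate variants, dangling `Related` targets, duplicate ids) and
commits to a `Lexicon` only when validation is clean.  Any problem raises
`XifValidationError` carrying the full list of offending entries; nothing
is partially committed.  Malformed XML raises `XifError` naming the parse
location.
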