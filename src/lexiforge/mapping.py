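"""Mapping mined term candidates to accession identifiers.

Candidates produced by a named-entity recogniser carry a recognition
probability; only high-confidence candidates (strictly above 0.99 by
default) enter mapping.  Mapping normalizes the candidate with the same
rule set that built the inverse index and looks the normalized form up;
forms hitting no cluster are unmapped, forms hitting more than
``max_accessions`` clusters (default 10) are discarded as hopelessly
ambiguous.  Dictionary clusters are sub-clustered by soft string matching
so that a mapped candidate's confidence is the best similarity to the
sub-cluster(s) it lands in.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from typing import Iterable, Sequence

from .normalization import ClusteredDictionary, InverseIndex, RuleSet

__all__ = [
    "CandidateTerm",
    "MappingConfig",
    "MappingResult",
    "filter_candidates",
    "string_similarity",
    "subcluster_terms",
    "map_term",
    "map_terms",
]


def _nfc(s: str) -> str:
    return unicodedata.normalize("NFC", s)


@dataclass(frozen=True)
class CandidateTerm:
    surface_form: str
    ner_probability: float
    doc_id: str = ""
    span: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.ner_probability <= 1.0):
            raise ValueError("ner_probability must be in [0, 1]")


@dataclass(frozen=True)
class MappingConfig:
    ner_prob_min: float = 0.99
    max_accessions: int = 10
    similarity_threshold: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.ner_prob_min <= 1.0):
            raise ValueError("ner_prob_min must be in [0, 1]")
        if self.max_accessions < 1:
            raise ValueError("max_accessions must be >= 1")


@dataclass
class MappingResult:
    candidate: CandidateTerm
    accessions: set[str]
    confidence_score: float
    status: str  # mapped | discarded_ambiguous | unmapped | rejected_low_prob
    polysemy_flag: bool = False


def filter_candidates(
    candidates: Sequence[CandidateTerm], cfg: MappingConfig = MappingConfig()
) -> tuple[list[CandidateTerm], list[CandidateTerm]]:
    """Partition candidates on the strict recognition-probability cutoff
    (p > ner_prob_min; a candidate at exactly the cutoff is rejected)."""
    selected = [c for c in candidates if c.ner_probability > cfg.ner_prob_min]
    rejected = [c for c in candidates if c.ner_probability <= cfg.ner_prob_min]
    return selected, rejected


_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


def _bigrams(s: str) -> set[str]:
    return {s[i : i + 2] for i in range(len(s) - 1)} if len(s) > 1 else {s}


def string_similarity(a: str, b: str) -> float:
    """Soft string similarity in [0, 1].

    Mean of character-bigram Dice and token-set Jaccard, both computed on
    casefolded NFC text; exactly 1.0 iff the NFC forms are identical, so
    case-only variants score just below 1 (0.999 cap).
    """
    a, b = _nfc(a), _nfc(b)
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    af, bf = a.casefold(), b.casefold()
    ba, bb = _bigrams(af), _bigrams(bf)
    dice = 2 * len(ba & bb) / (len(ba) + len(bb))
    ta, tb = set(_TOKEN_RE.findall(af)), set(_TOKEN_RE.findall(bf))
    jaccard = len(ta & tb) / len(ta | tb) if ta | tb else 0.0
    return min(0.5 * (dice + jaccard), 0.999)


def subcluster_terms(
    cluster: Iterable[str], cfg: MappingConfig = MappingConfig()
) -> list[set[str]]:
    """Single-linkage partition of a term cluster: terms are joined when
    their similarity reaches the threshold; returns the connected
    components, each a set covering the cluster exactly once."""
    terms = sorted(set(cluster))
    if not terms:
        raise ValueError("empty cluster")
    parent = list(range(len(terms)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(terms)):
        for j in range(i + 1, len(terms)):
            if string_similarity(terms[i], terms[j]) >= cfg.similarity_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, set[str]] = {}
    for i, t in enumerate(terms):
        groups.setdefault(find(i), set()).add(t)
    return sorted(groups.values(), key=lambda g: sorted(g)[0])


def map_term(
    candidate: CandidateTerm,
    index: InverseIndex,
    rules: RuleSet,
    dictionary: ClusteredDictionary,
    cfg: MappingConfig = MappingConfig(),
) -> MappingResult:
    """Normalize, look up, and filter one candidate.

    Statuses: ``rejected_low_prob`` (probability at or below the cutoff),
    ``unmapped`` (no cluster), ``discarded_ambiguous`` (more than
    ``max_accessions`` clusters), else ``mapped`` with confidence equal to
    the best soft similarity between the surface form and the matched
    sub-cluster members; ``polysemy_flag`` marks multi-accession hits.
    """
    if index.ruleset_id != rules.identifier():
        raise ValueError(
            "inverse index was built with a different rule set "
            f"({index.ruleset_id} != {rules.identifier()})"
        )
    if candidate.ner_probability <= cfg.ner_prob_min:
        return MappingResult(candidate, set(), 0.0, "rejected_low_prob")
    form = rules.normalize(candidate.surface_form)
    accessions = index.lookup(form)
    if not accessions:
        return MappingResult(candidate, set(), 0.0, "unmapped")
    if len(accessions) > cfg.max_accessions:
        return MappingResult(candidate, accessions, 0.0, "discarded_ambiguous")
    # confidence: best similarity against members of the matched sub-clusters
    best = 0.0
    for acc in accessions:
        members = dictionary.clusters.get(acc, set())
        matched = {t for t in members if rules.normalize(t) == form}
        if not matched:
            matched = members
        if members:
            for sub in subcluster_terms(members, cfg):
                if sub & matched:
                    best = max(
                        best,
                        max(string_similarity(candidate.surface_form, t) for t in sub),
                    )
    return MappingResult(
        candidate,
        accessions,
        best,
        "mapped",
        polysemy_flag=len(accessions) >= 2,
    )


def map_terms(
    candidates: Sequence[CandidateTerm],
    index: InverseIndex,
    rules: RuleSet,
    dictionary: ClusteredDictionary,
    cfg: MappingConfig = MappingConfig(),
) -> list[MappingResult]:
    """Map a batch of candidates; every candidate receives exactly one
    status, so counts across statuses partition the input."""
    return [map_term(c, index, rules, dictionary, cfg) for c in candidates]
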