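"""Term-normalization rules, dictionary metrics, and greedy rule induction.

Biomedical term variants ("NF-KB" / "NF-kb", "amino acid" / "amino-acid",
"tumour" / "tumor") are collapsed onto shared canonical forms by an ordered
set of deterministic string rewrites.  Rule sets are scored against an
accession-clustered synonym dictionary with two metrics:

* variability  -- average number of distinct normalized forms per accession
  cluster (1.0 = every cluster collapses to a single form);
* ambiguity    -- average number of clusters sharing a normalized form
  (1.0 = no normalized form is shared across clusters).

A good rule reduces variability while increasing ambiguity as little as
possible; rules are induced greedily under that objective from candidate
rewrites proposed by aligning variant pairs within clusters.  The induced
rule set also defines the inverse index (normalized form -> accessions)
used for fast term-to-accession mapping.
"""

from __future__ import annotations

import hashlib
import itertools
import unicodedata
from dataclasses import dataclass, field
from difflib import SequenceMatcher
from typing import Iterable, Iterator, Mapping

__all__ = [
    "NormalizationRule",
    "RuleSet",
    "ClusteredDictionary",
    "MetricsReport",
    "InverseIndex",
    "compute_metrics",
    "generate_candidate_rules",
    "induce_ruleset",
    "build_inverse_index",
]

RULE_KINDS = ("case_fold", "delete_class", "substring_rewrite", "token_sort")

#: Character classes deletable by ``delete_class`` rules.  ``hyphens`` is a
#: strict subset of ``punctuation``; candidate generation prefers the most
#: specific sufficient class.
CHAR_CLASSES: dict[str, str] = {
    "hyphens": "-‐‑‒–—/",
    "punctuation": "-‐‑‒–—/.,;:'\"()[]{}!?*+",
    "whitespace": " \t\u00a0",
}

_MAX_REWRITE_PASSES = 8


def nfc(s: str) -> str:
    return unicodedata.normalize("NFC", s)


@dataclass(frozen=True)
class NormalizationRule:
    """One deterministic, idempotent string rewrite.

    ``pattern`` is empty for parameterless kinds (``case_fold``,
    ``token_sort``); for ``delete_class`` it names a character class from
    :data:`CHAR_CLASSES`; for ``substring_rewrite`` it is the literal
    substring to rewrite into ``replacement``.
    """

    kind: str
    pattern: str = ""
    replacement: str = ""
    rank: int = 0

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise ValueError(f"unknown rule kind: {self.kind!r}")
        if self.kind == "delete_class" and self.pattern not in CHAR_CLASSES:
            raise ValueError(f"unknown character class: {self.pattern!r}")
        if self.kind == "substring_rewrite" and not self.pattern:
            raise ValueError("substring_rewrite requires a non-empty pattern")

    def apply(self, s: str) -> str:
        if self.kind == "case_fold":
            return s.lower()
        if self.kind == "delete_class":
            table = str.maketrans("", "", CHAR_CLASSES[self.pattern])
            return s.translate(table)
        if self.kind == "token_sort":
            return " ".join(sorted(s.split()))
        # substring_rewrite: iterate to a fixpoint so the rule is idempotent;
        # a replacement containing its own pattern is applied once only.
        if self.pattern in self.replacement:
            return s.replace(self.pattern, self.replacement)
        for _ in range(_MAX_REWRITE_PASSES):
            out = s.replace(self.pattern, self.replacement)
            if out == s:
                return out
            s = out
        return s

    def key(self) -> tuple[str, str, str]:
        """Identity of the rewrite, independent of rank."""
        return (self.kind, self.pattern, self.replacement)


@dataclass
class RuleSet:
    """Ordered collection of normalization rules applied in rank order."""

    rules: list[NormalizationRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        ranks = [r.rank for r in self.rules]
        if any(b <= a for a, b in zip(ranks, ranks[1:])):
            raise ValueError("rule ranks must be strictly increasing")

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self) -> Iterator[NormalizationRule]:
        return iter(self.rules)

    def normalize(self, term: str) -> str:
        s = nfc(term)
        for rule in self.rules:
            s = rule.apply(s)
        return s

    def extended(self, rule: NormalizationRule) -> "RuleSet":
        next_rank = self.rules[-1].rank + 1 if self.rules else 1
        new = NormalizationRule(rule.kind, rule.pattern, rule.replacement, next_rank)
        return RuleSet(self.rules + [new])

    def identifier(self) -> str:
        """Stable digest identifying this rule set (index provenance)."""
        payload = "\n".join(
            f"{r.rank}\t{r.kind}\t{r.pattern}\t{r.replacement}" for r in self.rules
        )
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("rank\tkind\tpattern\treplacement\n")
            for r in self.rules:
                fh.write(f"{r.rank}\t{r.kind}\t{r.pattern}\t{r.replacement}\n")

    @classmethod
    def from_tsv(cls, path) -> "RuleSet":
        rules = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("rank\t"):
                raise ValueError(f"{path}: not a rule-set TSV")
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                rank, kind, pattern, replacement = line.split("\t")
                rules.append(NormalizationRule(kind, pattern, replacement, int(rank)))
        return cls(rules)


class ClusteredDictionary:
    """Synonym dictionary clustered by accession identifier.

    Each cluster maps one accession (e.g. a UniProt AC) to the set of term
    strings recorded for it.  A term string may legitimately belong to
    several clusters (genuine ambiguity).  Sources are tracked per
    (accession, term).
    """

    def __init__(self) -> None:
        self.clusters: dict[str, set[str]] = {}
        self._sources: dict[tuple[str, str], str] = {}

    def add(self, accession: str, term: str, source: str = "unknown") -> None:
        if not term:
            raise ValueError("empty term")
        self.clusters.setdefault(accession, set()).add(term)
        self._sources[(accession, term)] = source

    def source(self, accession: str, term: str) -> str:
        return self._sources.get((accession, term), "unknown")

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def n_terms(self) -> int:
        return sum(len(ts) for ts in self.clusters.values())

    def terms(self) -> Iterator[tuple[str, str]]:
        for acc in sorted(self.clusters):
            for term in sorted(self.clusters[acc]):
                yield acc, term

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "ClusteredDictionary":
        d = cls()
        for acc, term in pairs:
            d.add(acc, term)
        return d

    @classmethod
    def from_tsv(cls, path) -> "ClusteredDictionary":
        """Read ``accession<TAB>term<TAB>source[<TAB>semantic_type[<TAB>curated]]``."""
        d = cls()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
                acc, term = parts[0], parts[1]
                source = parts[2] if len(parts) > 2 else "unknown"
                d.add(acc, term, source)
        return d


@dataclass(frozen=True)
class MetricsReport:
    ambiguity: float
    variability: float
    n_forms: int
    n_clusters: int


def _normalized_views(
    dictionary: ClusteredDictionary, rules: RuleSet
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Per-cluster normalized form sets, and form -> clusters mapping."""
    cluster_forms: dict[str, set[str]] = {}
    form_clusters: dict[str, set[str]] = {}
    for acc, terms in dictionary.clusters.items():
        forms = {rules.normalize(t) for t in terms}
        cluster_forms[acc] = forms
        for f in forms:
            form_clusters.setdefault(f, set()).add(acc)
    return cluster_forms, form_clusters


def compute_metrics(dictionary: ClusteredDictionary, rules: RuleSet) -> MetricsReport:
    """Score a rule set against a clustered dictionary.

    variability = mean over clusters of the number of distinct normalized
    forms in the cluster; ambiguity = mean over distinct normalized forms of
    the number of clusters containing a term with that form.
    """
    if len(dictionary) == 0:
        raise ValueError("empty dictionary")
    cluster_forms, form_clusters = _normalized_views(dictionary, rules)
    variability = sum(len(v) for v in cluster_forms.values()) / len(cluster_forms)
    ambiguity = sum(len(v) for v in form_clusters.values()) / len(form_clusters)
    return MetricsReport(
        ambiguity=ambiguity,
        variability=variability,
        n_forms=len(form_clusters),
        n_clusters=len(cluster_forms),
    )


def _class_candidates(a: str, b: str) -> list[str]:
    """Deletable-class candidates explaining a case-folded pair difference.

    Classes are tried cumulatively, most specific first; every class in the
    minimal sufficient prefix whose characters actually occur in the pair is
    a candidate (a hyphen/space alternation yields both ``hyphens`` and
    ``whitespace``).
    """
    order = ["hyphens", "punctuation", "whitespace"]
    stripped_a, stripped_b = a, b
    used: list[str] = []
    for cls in order:
        table = str.maketrans("", "", CHAR_CLASSES[cls])
        stripped_a = stripped_a.translate(table)
        stripped_b = stripped_b.translate(table)
        used.append(cls)
        if stripped_a == stripped_b and stripped_a:
            present = [
                c
                for c in used
                if any(ch in CHAR_CLASSES[c] for ch in a + b)
            ]
            # drop "punctuation" when the hyphen class alone explains its share
            if "punctuation" in present and "hyphens" in present:
                hyph = str.maketrans("", "", CHAR_CLASSES["hyphens"])
                punct = str.maketrans("", "", CHAR_CLASSES["punctuation"])
                if (a.translate(hyph) + b.translate(hyph)).translate(punct) == (
                    a.translate(hyph) + b.translate(hyph)
                ):
                    present.remove("punctuation")
            return present
    return []


def _rewrite_candidate(a: str, b: str) -> NormalizationRule | None:
    """Bounded substring rewrite from a single-block diff, with one char of
    context on each side ("tumour"/"tumor" -> "our"->"or")."""
    sm = SequenceMatcher(a=a, b=b, autojunk=False)
    blocks = [op for op in sm.get_opcodes() if op[0] != "equal"]
    if len(blocks) != 1:
        return None
    _, i1, i2, j1, j2 = blocks[0]
    if (i2 - i1) > 4 or (j2 - j1) > 4:
        return None
    # the rewrite must sit inside shared context; a block covering both
    # whole strings is a word substitution, not an orthographic rule
    if (i2 - i1) >= len(a) and (j2 - j1) >= len(b):
        return None
    lo = max(i1 - 1, 0)
    pat = a[lo : i2 + 1]
    rep = b[max(j1 - 1, 0) : j2 + 1]
    if not pat or pat == rep:
        return None
    # orient longer -> shorter (tie: lexicographically greater side is the
    # pattern) so e.g. "our" -> "or" regardless of pair order
    if (len(rep), rep) > (len(pat), pat):
        pat, rep = rep, pat
    if not pat:
        return None
    return NormalizationRule("substring_rewrite", pat, rep)


def generate_candidate_rules(
    dictionary: ClusteredDictionary, include_token_sort: bool = False
) -> list[tuple[NormalizationRule, int]]:
    """Propose normalization rules from intra-cluster variant pairs.

    Returns ``(rule, support)`` pairs, support being the number of
    supporting variant pairs, sorted by support (desc) then rule key.
    """
    support: dict[tuple[str, str, str], int] = {}

    def vote(rule: NormalizationRule) -> None:
        support[rule.key()] = support.get(rule.key(), 0) + 1

    for terms in dictionary.clusters.values():
        for a, b in itertools.combinations(sorted(terms), 2):
            a, b = nfc(a), nfc(b)
            if a == b:
                continue
            fa, fb = a.lower(), b.lower()
            if fa == fb:
                vote(NormalizationRule("case_fold"))
                continue
            classes = _class_candidates(fa, fb)
            if classes:
                if a != fa or b != fb:
                    vote(NormalizationRule("case_fold"))
                for cls in classes:
                    vote(NormalizationRule("delete_class", cls))
                continue
            if include_token_sort and sorted(fa.split()) == sorted(fb.split()):
                vote(NormalizationRule("token_sort"))
                continue
            rw = _rewrite_candidate(fa, fb)
            if rw is not None:
                if a != fa or b != fb:
                    vote(NormalizationRule("case_fold"))
                vote(rw)

    out = [
        (NormalizationRule(k[0], k[1], k[2]), n) for k, n in support.items()
    ]
    out.sort(key=lambda rn: (-rn[1], rn[0].key()))
    return out


def induce_ruleset(
    dictionary: ClusteredDictionary,
    k_max: int = 1000,
    lam: float = 1.0,
    include_token_sort: bool = False,
) -> RuleSet:
    """Greedily select rules maximizing variability reduction minus
    ``lam`` times ambiguity increase; stop at ``k_max`` rules or when no
    candidate scores above zero.

    Ties break on higher supporting-pair count, then on the lexicographic
    rule representation, so induction is deterministic.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    candidates = generate_candidate_rules(dictionary, include_token_sort)
    ruleset = RuleSet()
    current = compute_metrics(dictionary, ruleset)
    chosen: set[tuple[str, str, str]] = set()
    while len(ruleset) < k_max and candidates:
        best: tuple[float, int, tuple[str, str, str]] | None = None
        best_rule = None
        best_metrics = None
        for rule, supp in candidates:
            if rule.key() in chosen:
                continue
            trial = ruleset.extended(rule)
            m = compute_metrics(dictionary, trial)
            score = (current.variability - m.variability) - lam * (
                m.ambiguity - current.ambiguity
            )
            rank_key = (-score, -supp, rule.key())
            if best is None or rank_key < best:
                best = rank_key
                best_rule, best_metrics = rule, m
        if best is None or -best[0] <= 0:
            break
        ruleset = ruleset.extended(best_rule)
        chosen.add(best_rule.key())
        current = best_metrics
    return ruleset


class InverseIndex:
    """Mapping normalized form -> set of accessions, tied to the RuleSet
    (by identifier) that produced it."""

    def __init__(self, mapping: Mapping[str, set[str]], ruleset_id: str) -> None:
        self.mapping: dict[str, set[str]] = {k: set(v) for k, v in mapping.items()}
        self.ruleset_id = ruleset_id

    def lookup(self, normalized_form: str) -> set[str]:
        return set(self.mapping.get(normalized_form, set()))

    def __len__(self) -> int:
        return len(self.mapping)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"#ruleset\t{self.ruleset_id}\n")
            for form in sorted(self.mapping):
                accs = ",".join(sorted(self.mapping[form]))
                fh.write(f"{form}\t{accs}\n")

    @classmethod
    def from_tsv(cls, path) -> "InverseIndex":
        mapping: dict[str, set[str]] = {}
        ruleset_id = ""
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#ruleset\t"):
                    ruleset_id = line.split("\t", 1)[1]
                    continue
                if not line:
                    continue
                form, accs = line.split("\t")
                mapping[form] = set(accs.split(",")) if accs else set()
        return cls(mapping, ruleset_id)


def build_inverse_index(
    dictionary: ClusteredDictionary, rules: RuleSet
) -> InverseIndex:
    """Index every dictionary term's normalized form to its accessions."""
    mapping: dict[str, set[str]] = {}
    for acc, term in dictionary.terms():
        mapping.setdefault(rules.normalize(term), set()).add(acc)
    return InverseIndex(mapping, rules.identifier())
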