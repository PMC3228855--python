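"""Normalization rules, dictionary metrics, rule induction, inverse index."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lexiforge.fixtures import FixtureSpec, gen_dictionary
from lexiforge.normalization import (
    ClusteredDictionary,
    NormalizationRule,
    RuleSet,
    build_inverse_index,
    compute_metrics,
    generate_candidate_rules,
    induce_ruleset,
)

CASE_HYPHEN = RuleSet(
    [
        NormalizationRule("case_fold", rank=1),
        NormalizationRule("delete_class", "hyphens", rank=2),
    ]
)


def brute_metrics(d: ClusteredDictionary, rules: RuleSet) -> tuple[float, float]:
    """Independent enumeration of (variability, ambiguity)."""
    per_cluster = {}
    form_owners: dict[str, set[str]] = {}
    for acc, terms in d.clusters.items():
        forms = set()
        for t in terms:
            f = rules.normalize(t)
            forms.add(f)
            form_owners.setdefault(f, set()).add(acc)
        per_cluster[acc] = forms
    variability = np.mean([len(v) for v in per_cluster.values()])
    ambiguity = np.mean([len(v) for v in form_owners.values()])
    return float(variability), float(ambiguity)


class TestRules:
    @pytest.mark.parametrize(
        "term,expected",
        [
            ("NF-KB", "nfkb"),
            ("", ""),
            ("Il-2", "il2"),
            ("amino-acid", "aminoacid"),
        ],
    )
    def test_case_and_hyphen_rules(self, term, expected):
        assert CASE_HYPHEN.normalize(term) == expected

    @given(st.text(max_size=40))
    @settings(derandomize=True, max_examples=200)
    def test_normalization_idempotent(self, term):
        rules = RuleSet(
            [
                NormalizationRule("case_fold", rank=1),
                NormalizationRule("delete_class", "punctuation", rank=2),
                NormalizationRule("substring_rewrite", "our", "or", rank=3),
                NormalizationRule("token_sort", rank=4),
            ]
        )
        once = rules.normalize(term)
        assert rules.normalize(once) == once

    def test_rewrite_fixpoint_is_idempotent(self):
        # "ab"->"a" on "abb": one left-to-right pass gives "ab" again
        r = NormalizationRule("substring_rewrite", "ab", "a")
        assert r.apply(r.apply("abbb")) == r.apply("abbb")

    def test_ranks_must_increase(self):
        with pytest.raises(ValueError):
            RuleSet([NormalizationRule("case_fold", rank=2),
                     NormalizationRule("token_sort", rank=1)])


class TestMetrics:
    def test_hand_enumerated_example(self):
        d = ClusteredDictionary.from_pairs(
            [("A", "IL-2"), ("A", "Il2"), ("B", "il2")]
        )
        m0 = compute_metrics(d, RuleSet())
        assert (m0.variability, m0.ambiguity) == (1.5, 1.0)
        m1 = compute_metrics(d, CASE_HYPHEN)
        assert (m1.variability, m1.ambiguity) == (1.0, 2.0)

    def test_unique_forms_give_unit_metrics(self):
        d = ClusteredDictionary.from_pairs([("A", "abc"), ("B", "def")])
        m = compute_metrics(d, RuleSet())
        assert (m.variability, m.ambiguity) == (1.0, 1.0)

    def test_empty_dictionary_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ClusteredDictionary(), RuleSet())

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force(self, seed):
        d, _ = gen_dictionary(
            FixtureSpec(seed=seed, n_concepts=12, variants_per_concept=3,
                        ambiguity_injection_rate=0.2)
        )
        m = compute_metrics(d, CASE_HYPHEN)
        bv, ba = brute_metrics(d, CASE_HYPHEN)
        assert m.variability == pytest.approx(bv)
        assert m.ambiguity == pytest.approx(ba)

    def test_appending_rules_is_monotone(self):
        """Rules are many-to-one rewrites: variability never increases and
        ambiguity never decreases as rules are appended."""
        d, _ = gen_dictionary(
            FixtureSpec(seed=4, n_concepts=40, ambiguity_injection_rate=0.1)
        )
        rules = RuleSet()
        prev = compute_metrics(d, rules)
        for r in [NormalizationRule("case_fold"),
                  NormalizationRule("delete_class", "hyphens"),
                  NormalizationRule("substring_rewrite", "our", "or")]:
            rules = rules.extended(r)
            cur = compute_metrics(d, rules)
            assert cur.variability <= prev.variability + 1e-12
            assert cur.ambiguity >= prev.ambiguity - 1e-12
            prev = cur


class TestCandidateGeneration:
    def test_hyphen_variant_pair(self):
        d = ClusteredDictionary.from_pairs(
            [("X", "amino acid"), ("X", "amino-acid")]
        )
        kinds = {r.key() for r, _ in generate_candidate_rules(d)}
        assert ("delete_class", "hyphens", "") in kinds

    def test_spelling_variant_pair(self):
        d = ClusteredDictionary.from_pairs([("Y", "tumour"), ("Y", "tumor")])
        kinds = {r.key() for r, _ in generate_candidate_rules(d)}
        assert ("substring_rewrite", "our", "or") in kinds

    def test_case_variant_pair(self):
        d = ClusteredDictionary.from_pairs([("Z", "NF-KB"), ("Z", "NF-kb")])
        kinds = {r.key() for r, _ in generate_candidate_rules(d)}
        assert ("case_fold", "", "") in kinds

    def test_singleton_clusters_yield_nothing(self):
        d = ClusteredDictionary.from_pairs([("A", "abc"), ("B", "xyz")])
        assert generate_candidate_rules(d) == []


class TestInduction:
    def test_case_only_dictionary(self):
        d = ClusteredDictionary.from_pairs(
            [("A", "abc"), ("A", "ABC"), ("B", "xyz"), ("B", "Xyz")]
        )
        rules = induce_ruleset(d)
        assert [r.kind for r in rules] == ["case_fold"]
        m = compute_metrics(d, rules)
        assert m.variability == 1.0
        assert m.ambiguity == 1.0

    def test_huge_lambda_blocks_ambiguity_increasing_rules(self):
        # collapsing case here merges forms across clusters
        d = ClusteredDictionary.from_pairs(
            [("A", "ABC"), ("A", "abc"), ("B", "abc"), ("B", "abcd")]
        )
        rules = induce_ruleset(d, lam=1e9)
        assert len(rules) == 0

    def test_k_max_one_picks_single_best(self):
        d, _ = gen_dictionary(FixtureSpec(seed=2, n_concepts=50))
        best = induce_ruleset(d, k_max=1)
        assert len(best) == 1
        # brute force: no single candidate scores better
        m0 = compute_metrics(d, RuleSet())
        best_m = compute_metrics(d, best)
        best_score = (m0.variability - best_m.variability) - (
            best_m.ambiguity - m0.ambiguity
        )
        for cand, _ in generate_candidate_rules(d):
            m = compute_metrics(d, RuleSet().extended(cand))
            score = (m0.variability - m.variability) - (m.ambiguity - m0.ambiguity)
            assert score <= best_score + 1e-12

    def test_determinism(self):
        d, _ = gen_dictionary(FixtureSpec(seed=9, n_concepts=60))
        r1 = induce_ruleset(d)
        r2 = induce_ruleset(d)
        assert [r.key() for r in r1] == [r.key() for r in r2]


class TestInverseIndex:
    def test_q8k4r9_cluster(self, q8k4r9_dict):
        rules = RuleSet([NormalizationRule("case_fold", rank=1)])
        index = build_inverse_index(q8k4r9_dict, rules)
        for _, term in q8k4r9_dict.terms():
            assert index.lookup(rules.normalize(term)) == {"Q8K4R9"}

    def test_empty_ruleset_keys_are_raw_forms(self, q8k4r9_dict):
        index = build_inverse_index(q8k4r9_dict, RuleSet())
        assert set(index.mapping) == {t for _, t in q8k4r9_dict.terms()}

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force(self, seed):
        d, _ = gen_dictionary(FixtureSpec(seed=seed, n_concepts=20))
        index = build_inverse_index(d, CASE_HYPHEN)
        brute: dict[str, set[str]] = {}
        for acc, term in d.terms():
            brute.setdefault(CASE_HYPHEN.normalize(term), set()).add(acc)
        assert index.mapping == brute

    def test_tsv_round_trip(self, q8k4r9_dict, tmp_path):
        rules = RuleSet([NormalizationRule("case_fold", rank=1)])
        index = build_inverse_index(q8k4r9_dict, rules)
        path = tmp_path / "index.tsv"
        index.to_tsv(path)
        from lexiforge.normalization import InverseIndex

        back = InverseIndex.from_tsv(path)
        assert back.mapping == index.mapping
        assert back.ruleset_id == index.ruleset_id


def test_ruleset_tsv_round_trip(tmp_path):
    rules = RuleSet(
        [
            NormalizationRule("case_fold", rank=1),
            NormalizationRule("delete_class", "hyphens", rank=2),
            NormalizationRule("substring_rewrite", "ise", "ize", rank=3),
        ]
    )
    path = tmp_path / "rules.tsv"
    rules.to_tsv(path)
    back = RuleSet.from_tsv(path)
    assert [r.key() for r in back] == [r.key() for r in rules]
    assert back.identifier() == rules.identifier()
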