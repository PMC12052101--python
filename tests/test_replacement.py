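"""Replacement plan construction and application.

The key check is oracle equivalence: an independent brute-force
re-derivation of candidacy and argmax, written against the raw pool
table, must agree with the plan builder on randomized instances.
"""

from __future__ import annotations

import random

import pytest

from synnorm import (
    Corpus,
    FixtureSynonyms,
    apply_replacement,
    build_replacement_plan,
    count_frequencies,
    default_threshold,
    read_plan,
    write_plan,
)
from synnorm.synonyms import normalize_lemma

from conftest import make_random_instance


def protected_pred(token: str) -> bool:
    return token.startswith("prot")


def oracle_plan(counts: dict[str, int], pools: dict[str, set[str]], tau: float):
    """Exhaustive per-token re-derivation of the replacement dictionary."""
    mapping: dict[str, str] = {}
    n_cand = n_allinf = n_nopool = 0
    for w in counts:
        if counts[w] >= tau or protected_pred(w):
            continue
        n_cand += 1
        pool = {
            m
            for m in (normalize_lemma(x) for x in pools.get(w, set()))
            if m is not None
        }
        if not pool:
            n_nopool += 1
            continue
        best = None
        for s in sorted(pool):  # lexicographic scan; strict > keeps first
            if best is None or counts.get(s, 0) > counts.get(best, 0):
                best = s
        if counts.get(best, 0) >= tau and best != w:
            mapping[w] = best
        else:
            n_allinf += 1
    return mapping, n_cand, n_allinf, n_nopool


class TestDefaultThreshold:
    def test_mu_from_hand_count(self):
        freq = count_frequencies(Corpus([["a", "b", "a"], ["c"]]))
        assert default_threshold(freq, 1.0) == pytest.approx(4 / 3)
        assert default_threshold(freq, 2.0) == pytest.approx(8 / 3)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            default_threshold(count_frequencies(Corpus([])), 1.0)

    def test_uniform_counts_give_empty_plan(self):
        # every token has count k = mu = tau, so nothing is below threshold
        corpus = Corpus([["a", "b", "c"], ["a", "b", "c"]])
        freq = count_frequencies(corpus)
        tau = default_threshold(freq, 1.0)
        resource = FixtureSynonyms.from_classes([["a", "b", "c"]])
        plan = build_replacement_plan(freq, resource, tau, protected=protected_pred)
        assert plan.mapping == {} and plan.n_candidates == 0


class TestPlanOracle:
    def test_agrees_with_brute_force_on_random_instances(self):
        for seed in range(300):
            rng = random.Random(seed)
            corpus, pools, tau, resource = make_random_instance(rng)
            freq = count_frequencies(corpus)
            plan = build_replacement_plan(freq, resource, tau, protected=protected_pred)
            mapping, n_cand, n_allinf, n_nopool = oracle_plan(freq.counts, pools, tau)
            assert plan.mapping == mapping, f"seed {seed}"
            assert plan.n_candidates == n_cand
            assert plan.n_retained_all_infrequent == n_allinf
            assert plan.n_retained_no_pool == n_nopool

    def test_invariants_on_random_instances(self):
        for seed in range(300):
            rng = random.Random(1000 + seed)
            corpus, _, tau, resource = make_random_instance(rng)
            freq = count_frequencies(corpus)
            plan = build_replacement_plan(freq, resource, tau, protected=protected_pred)
            sources, targets = plan.sources, plan.targets
            assert sources.isdisjoint(targets)
            for w, s in plan.mapping.items():
                assert freq[w] < tau and freq[s] >= tau
                assert not protected_pred(w)
            assert plan.n_candidates == (
                plan.n_replaced
                + plan.n_retained_all_infrequent
                + plan.n_retained_no_pool
            )

    def test_ties_broken_lexicographically(self):
        corpus = Corpus([["rare"] + ["bb"] * 5 + ["aa"] * 5])
        freq = count_frequencies(corpus)
        resource = FixtureSynonyms.from_mapping({"rare": {"aa", "bb"}})
        plan = build_replacement_plan(freq, resource, 3.0, protected=protected_pred)
        assert plan.mapping == {"rare": "aa"}

    def test_all_infrequent_pool_retained(self):
        # rare words whose synonyms are rare too keep their specific meaning
        corpus = Corpus([["peregrinate", "wander"] + ["common"] * 10])
        freq = count_frequencies(corpus)
        resource = FixtureSynonyms.from_mapping({"peregrinate": {"wander", "roam"}})
        plan = build_replacement_plan(freq, resource, 5.0, protected=protected_pred)
        assert "peregrinate" not in plan.mapping
        assert plan.n_retained_all_infrequent == 1


class TestApply:
    def test_direct_substitution(self):
        corpus = Corpus([["amount", "bill", "measure"]])
        freq = count_frequencies(Corpus([["amount", "bill"] + ["measure"] * 9]))
        resource = FixtureSynonyms.from_mapping(
            {"amount": {"measure"}, "bill": {"measure"}}
        )
        plan = build_replacement_plan(freq, resource, 2.0, protected=protected_pred)
        out = apply_replacement(corpus, plan)
        assert out.documents == [["measure", "measure", "measure"]]

    def test_empty_plan_is_identity(self, tmp_path):
        corpus = Corpus([["a", "b"], ["c"]])
        freq = count_frequencies(corpus)
        plan = build_replacement_plan(
            freq, FixtureSynonyms(), 0.5, protected=protected_pred
        )
        out = apply_replacement(corpus, plan)
        assert out.documents == corpus.documents

    def test_conservation_vocabulary_and_idempotence(self):
        for seed in range(200):
            rng = random.Random(2000 + seed)
            corpus, _, tau, resource = make_random_instance(rng)
            freq = count_frequencies(corpus)
            plan = build_replacement_plan(freq, resource, tau, protected=protected_pred)
            out = apply_replacement(corpus, plan)
            assert out.n_tokens == corpus.n_tokens
            assert len(out) == len(corpus)
            assert len(out.vocabulary()) <= len(corpus.vocabulary())
            twice = apply_replacement(out, plan)
            assert twice.documents == out.documents

    def test_distinct_token_set_arithmetic(self):
        for seed in range(100):
            rng = random.Random(3000 + seed)
            corpus, _, tau, resource = make_random_instance(rng)
            freq = count_frequencies(corpus)
            plan = build_replacement_plan(freq, resource, tau, protected=protected_pred)
            before = corpus.vocabulary()
            after = apply_replacement(corpus, plan).vocabulary()
            sources_present = {w for w in plan.mapping if w in before}
            introduced = {
                plan.mapping[w] for w in sources_present
            } - (before - sources_present)
            assert after == (before - sources_present) | {
                plan.mapping[w] for w in sources_present
            }
            assert len(after) == len(before) - len(sources_present) + len(introduced)

    def test_target_frequency_strictly_increases(self):
        corpus = Corpus([["amount", "measure", "measure", "other"]])
        freq = count_frequencies(corpus)
        resource = FixtureSynonyms.from_mapping({"amount": {"measure"}})
        plan = build_replacement_plan(freq, resource, 2.0, protected=protected_pred)
        assert plan.mapping == {"amount": "measure"}
        after = count_frequencies(apply_replacement(corpus, plan))
        assert after["measure"] > freq["measure"]

    def test_plan_tsv_round_trip(self, tmp_path):
        corpus = Corpus([["amount", "bill"] + ["measure"] * 9])
        freq = count_frequencies(corpus)
        resource = FixtureSynonyms.from_mapping(
            {"amount": {"measure"}, "bill": {"measure"}}
        )
        plan = build_replacement_plan(freq, resource, 2.0, protected=protected_pred)
        p = tmp_path / "plan.tsv"
        write_plan(plan, freq, p)
        assert read_plan(p).mapping == plan.mapping
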