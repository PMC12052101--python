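"""Shared fixtures: the packaged synonym table and random-instance makers."""

from __future__ import annotations

import random

import pytest

from synnorm import Corpus, FixtureSynonyms
from synnorm.synonyms import default_fixture_path


@pytest.fixture(scope="session")
def example_resource() -> FixtureSynonyms:
    return FixtureSynonyms.from_tsv(default_fixture_path())


@pytest.fixture
def worked_example_corpus() -> Corpus:
    """Corpus in which 'measure' and '13' dominate their synonym pools.

    Frequencies: measure 10, 13 8, each rare variant 1. With tau at the
    per-type mean (23/7 ~ 3.3) the five rare variants are candidates and
    both dominant forms clear the threshold.
    """
    docs = [
        ["measure"] * 10 + ["13"] * 8,
        ["amount", "bill", "step", "thirteen", "xiii"],
    ]
    return Corpus(docs, source_label="worked-example")


def make_random_instance(rng: random.Random, alphabet_size: int = 24):
    """A random (corpus, pool table, tau) triple for oracle comparisons.

    Tokens are underscore-free so pools survive lemma normalization; a
    slice of the alphabet is marked protected via the 'prot' prefix.
    """
    words = [f"w{i}" for i in range(alphabet_size)] + ["prot1x", "prot2x"]
    n_docs = rng.randint(1, 12)
    docs = [
        [rng.choice(words) for _ in range(rng.randint(1, 30))] for _ in range(n_docs)
    ]
    pools = {}
    for w in rng.sample(words, rng.randint(0, len(words))):
        pools[w] = set(rng.sample(words, rng.randint(1, 6))) | (
            {w} if rng.random() < 0.5 else set()
        )
    tau = rng.uniform(0.5, 8.0)
    resource = FixtureSynonyms.from_mapping(pools)
    return Corpus(docs), pools, tau, resource
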