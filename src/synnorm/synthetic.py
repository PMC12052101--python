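"""Synthetic corpora with known synonym structure and concept sets.

Stands in for a full annotated-abstract corpus so the whole pipeline —
frequency counting, replacement, embedding, set-coherence evaluation —
can be exercised end to end with a known ground truth. The generator
emulates the features the normalization heuristic relies on:

* **Topics.** Each document belongs to one topic; topic-specific concept
  identifier tokens (``cid_t<topic>_c<i>``, matching the default
  protected-token convention) appear at a configurable per-position rate.
  The concepts of a topic form one concept set — these are the clusters
  whose embedding coherence is evaluated.
* **Synonym classes.** Topic-characteristic context words come from
  synonym classes assigned to topics. Within a class the member is drawn
  from a Zipf law (rank^-s), so one member dominates and the rest are
  rare: exactly the frequency skew that makes "replace a rare word by its
  most frequent synonym" well-defined and useful. The generator emits a
  fixture synonym resource mapping every member to its full class.
* **Filler.** Shared topic-neutral filler words, Zipf-distributed, give
  the corpus a realistic long-tail background.

Replacing the rare class members by their dominant sibling consolidates
the contexts in which a topic's concepts appear, which is what tightens
intra-set embedding distances — the mechanism under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .conceptsets import ConceptSet, filter_sets
from .corpus import Corpus, count_frequencies
from .embedding import EmbeddingParams, EmbeddingSpace, train_embeddings
from .evaluation import CategorySummary, SetComparison, compare_set, summarize
from .replacement import (
    ReplacementPlan,
    apply_replacement,
    build_replacement_plan,
    default_threshold,
    protect_regex_predicate,
)
from .synonyms import FixtureSynonyms

#: Fraction of non-concept positions filled from a topic synonym class
#: (the rest is shared filler). Fixed: it sets the context-to-background
#: ratio of the generator, not a property under study.
_SYNONYM_SHARE = 0.5

_CATEGORY_CYCLE = ("M", "B", "K", "G", "P")


@dataclass(frozen=True)
class SynthConfig:
    """Generator knobs.

    Defaults describe a desk-scale corpus (~100k tokens) with strong
    within-class frequency skew: rank-1 class members land well above the
    mean per-type frequency and the deepest ranks well below half of it,
    so threshold sweeps exercise every replacement regime.
    """

    n_topics: int = 10
    concepts_per_topic: int = 8
    n_synonym_classes: int = 10
    class_size: int = 5
    zipf_exponent: float = 1.5
    n_filler_words: int = 100
    docs_per_topic: int = 200
    doc_length: int = 50
    concept_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_topics,
            self.concepts_per_topic,
            self.n_synonym_classes,
            self.class_size,
            self.n_filler_words,
            self.docs_per_topic,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be positive")
        if not (0.0 < self.concept_rate < 1.0):
            raise ValueError("concept_rate must be in (0, 1)")
        if self.doc_length < 5:
            raise ValueError("doc_length must be >= 5")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually put into the corpus."""

    synonym_classes: Mapping[int, tuple[tuple[str, ...], np.ndarray]]
    concept_sets: tuple[ConceptSet, ...]
    topic_of_doc: tuple[int, ...]

    def dominant_member(self, class_id: int) -> str:
        members, weights = self.synonym_classes[class_id]
        return members[int(np.argmax(weights))]


def _zipf_weights(n: int, s: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=np.float64) ** -s
    return w / w.sum()


def generate(config: SynthConfig) -> tuple[Corpus, GroundTruth, FixtureSynonyms]:
    """Generate (corpus, ground truth, fixture synonym resource).

    Deterministic under ``config.seed``: the same config produces the same
    corpus bytes.
    """
    rng = np.random.default_rng(config.seed)

    concept_sets = []
    for t in range(config.n_topics):
        members = frozenset(
            f"cid_t{t}_c{i}" for i in range(config.concepts_per_topic)
        )
        concept_sets.append(
            ConceptSet(
                name=f"topicset_{t}",
                members=members,
                category=_CATEGORY_CYCLE[t % len(_CATEGORY_CYCLE)],
            )
        )

    classes: dict[int, tuple[tuple[str, ...], np.ndarray]] = {}
    for c in range(config.n_synonym_classes):
        # no underscores: members must survive single-token lemma normalization
        members = tuple(f"syn{c}r{r}" for r in range(config.class_size))
        classes[c] = (members, _zipf_weights(config.class_size, config.zipf_exponent))
    classes_of_topic = {
        t: [c for c in range(config.n_synonym_classes) if c % config.n_topics == t]
        for t in range(config.n_topics)
    }

    fillers = [f"fill_{i}" for i in range(config.n_filler_words)]
    filler_weights = _zipf_weights(config.n_filler_words, 1.0)

    documents: list[list[str]] = []
    topic_of_doc: list[int] = []
    for t in range(config.n_topics):
        topic_concepts = sorted(concept_sets[t].members)
        topic_classes = classes_of_topic[t]
        for _ in range(config.docs_per_topic):
            doc: list[str] = []
            u = rng.random(config.doc_length)
            for pos in range(config.doc_length):
                if u[pos] < config.concept_rate:
                    doc.append(topic_concepts[rng.integers(len(topic_concepts))])
                elif topic_classes and u[pos] < config.concept_rate + (
                    1 - config.concept_rate
                ) * _SYNONYM_SHARE:
                    cid = topic_classes[rng.integers(len(topic_classes))]
                    members, weights = classes[cid]
                    doc.append(members[rng.choice(len(members), p=weights)])
                else:
                    doc.append(fillers[rng.choice(len(fillers), p=filler_weights)])
            documents.append(doc)
            topic_of_doc.append(t)

    corpus = Corpus(documents, source_label=f"synthetic(seed={config.seed})")
    truth = GroundTruth(
        synonym_classes=classes,
        concept_sets=tuple(concept_sets),
        topic_of_doc=tuple(topic_of_doc),
    )
    resource = FixtureSynonyms.from_classes([list(m) for m, _ in classes.values()])
    return corpus, truth, resource


@dataclass(frozen=True)
class ExperimentResult:
    """All artifacts of one end-to-end baseline-vs-normalized run."""

    corpus_baseline: Corpus
    corpus_replaced: Corpus
    plan: ReplacementPlan
    threshold: float
    space_baseline: EmbeddingSpace
    space_replaced: EmbeddingSpace
    comparisons: tuple[SetComparison, ...]
    summaries: tuple[CategorySummary, ...]
    truth: GroundTruth

    @property
    def replaced_better_fraction(self) -> float:
        """Fraction of non-tie sets where the normalized space is tighter."""
        wins = sum(c.winner == "B" for c in self.comparisons)
        decided = sum(c.winner != "tie" for c in self.comparisons)
        return wins / decided if decided else 0.0

    @property
    def tie_fraction(self) -> float:
        return sum(c.winner == "tie" for c in self.comparisons) / len(self.comparisons)


def end_to_end_experiment(
    config: SynthConfig,
    embedding_params: EmbeddingParams | None = None,
    tau_multiplier: float = 1.0,
    alpha: float = 0.05,
    min_members: int = 5,
) -> ExperimentResult:
    """Generate, normalize, embed both corpora and compare set coherence.

    ``tau_multiplier = 0`` is the null control: an empty plan, identical
    corpora, and (with the shared embedding seed) identical spaces — every
    set comparison is then a tie.
    """
    if embedding_params is None:
        embedding_params = EmbeddingParams(dim=32, epochs=5, seed=config.seed + 1)
    corpus, truth, resource = generate(config)
    freq = count_frequencies(corpus)

    if tau_multiplier > 0:
        threshold = default_threshold(freq, tau_multiplier)
        plan = build_replacement_plan(
            freq, resource, threshold, protected=protect_regex_predicate()
        )
    else:
        threshold = 0.0
        plan = ReplacementPlan(
            mapping={}, threshold=0.0, n_candidates=0, n_replaced=0,
            n_retained_all_infrequent=0, n_retained_no_pool=0,
        )
    replaced = apply_replacement(corpus, plan)

    space_a = train_embeddings(corpus, embedding_params)
    space_b = train_embeddings(replaced, embedding_params)

    surviving = filter_sets(truth.concept_sets, space_a.vocab, space_b.vocab, min_members)
    comparisons = tuple(
        compare_set(space_a, space_b, cs, alpha=alpha) for cs in surviving
    )
    summaries = tuple(summarize(comparisons))
    return ExperimentResult(
        corpus_baseline=corpus,
        corpus_replaced=replaced,
        plan=plan,
        threshold=threshold,
        space_baseline=space_a,
        space_replaced=space_b,
        comparisons=comparisons,
        summaries=summaries,
        truth=truth,
    )
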