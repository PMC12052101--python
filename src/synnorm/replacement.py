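"""Infrequent-word -> most-frequent-synonym replacement.

The normalization heuristic: words that occur rarely in a corpus but have
a frequent synonym carry generic meaning and only fragment contexts, so
each such word w with corpus frequency f(w) below a threshold tau is
replaced, corpus-wide, by the member s_max of its synonym pool with the
highest corpus frequency — provided f(s_max) >= tau. Rare words whose
synonyms are *all* rare are assumed to carry specific, discriminative
meaning and are retained, as are words with no synonym pool at all.
Biomedical concept identifiers are protected from replacement by a
configurable predicate (by default a regex matching the corpus's
identifier convention), since the normalization targets only general
vocabulary.

The plan is built once, from frequencies counted before any replacement,
and applied in a single pass; frequencies are never recomputed mid-run.
By construction sources are infrequent (f < tau) and targets frequent
(f >= tau), so the source and target sets are disjoint and replacement
chains cannot arise — applying a plan twice equals applying it once.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from .corpus import Corpus, FrequencyTable
from .synonyms import SynonymResource

#: Default protected-token pattern: concept-identifier conventions
#: (MeSH / NCBI Gene style prefixes, and the ``cid_`` prefix of the
#: synthetic generator).
DEFAULT_PROTECT_REGEX = r"^(mesh|ncbigene|omim|cid)_?[a-z0-9]*\d"


@dataclass(frozen=True)
class ReplacementPlan:
    """The dictionary S mapping each replaced word to its target synonym.

    Attributes
    ----------
    mapping
        source token -> target token; for every entry f(source) < tau and
        f(target) >= tau.
    threshold
        The tau used to build the plan.
    n_candidates
        Number of unprotected tokens with f < tau (the set R).
    n_replaced
        len(mapping).
    n_retained_all_infrequent
        Candidates whose pool was non-empty but whose best synonym was
        still infrequent (or was the word itself).
    n_retained_no_pool
        Candidates with an empty synonym pool.
    """

    mapping: dict[str, str]
    threshold: float
    n_candidates: int
    n_replaced: int
    n_retained_all_infrequent: int
    n_retained_no_pool: int

    @property
    def sources(self) -> set[str]:
        return set(self.mapping)

    @property
    def targets(self) -> set[str]:
        return set(self.mapping.values())

    def summary(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_candidates": self.n_candidates,
            "n_replaced": self.n_replaced,
            "n_retained_all_infrequent": self.n_retained_all_infrequent,
            "n_retained_no_pool": self.n_retained_no_pool,
        }


def default_threshold(freq: FrequencyTable, multiplier: float = 1.0) -> float:
    """tau = multiplier * mu, where mu is the per-type mean frequency.

    The multiplier sweep {0.5, 1, 2, 4} spans the regimes from conservative
    (few replacements) to aggressive. Raises on an empty table, where mu is
    undefined.
    """
    if freq.empty or freq.vocab_size == 0:
        raise ValueError("cannot derive a threshold from an empty frequency table")
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    return multiplier * freq.mean_frequency


def protect_regex_predicate(pattern: str = DEFAULT_PROTECT_REGEX) -> Callable[[str], bool]:
    """Build a protected-token predicate from a regex (search semantics on ^)."""
    compiled = re.compile(pattern)
    return lambda token: compiled.match(token) is not None


def build_replacement_plan(
    freq: FrequencyTable,
    resource: SynonymResource,
    threshold: float,
    protected: Callable[[str], bool] | None = None,
) -> ReplacementPlan:
    """Derive the replacement dictionary S from corpus frequencies.

    For every unprotected token w with f(w) < threshold, look up its
    synonym pool; the candidate target is the pool member with the highest
    corpus frequency (members absent from the corpus count 0), ties broken
    lexicographically so the plan is deterministic. w is mapped to that
    target only if the target is frequent (f >= threshold) and differs
    from w; otherwise w is retained and counted by retention reason.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if protected is None:
        protected = protect_regex_predicate()

    mapping: dict[str, str] = {}
    n_candidates = 0
    n_all_infrequent = 0
    n_no_pool = 0

    for word in sorted(freq.counts):
        if freq.counts[word] >= threshold or protected(word):
            continue
        n_candidates += 1
        pool = resource.get_pool(word)
        if not pool:
            n_no_pool += 1
            continue
        # argmax of f over the pool; ties lexicographic (min name wins)
        smax = min(pool.members, key=lambda s: (-freq.get(s, 0), s))
        if freq.get(smax, 0) >= threshold and smax != word:
            mapping[word] = smax
        else:
            n_all_infrequent += 1

    return ReplacementPlan(
        mapping=mapping,
        threshold=threshold,
        n_candidates=n_candidates,
        n_replaced=len(mapping),
        n_retained_all_infrequent=n_all_infrequent,
        n_retained_no_pool=n_no_pool,
    )


def apply_replacement(corpus: Corpus, plan: ReplacementPlan) -> Corpus:
    """Substitute every source occurrence by its target, one pass.

    Token and document counts are preserved exactly; tokens outside the
    plan are untouched. The plan is held fixed throughout — the operation
    is idempotent because targets are never sources.
    """
    mapping = plan.mapping
    documents = [[mapping.get(tok, tok) for tok in doc] for doc in corpus.documents]
    return Corpus(documents, source_label=f"{corpus.source_label} [replaced]")


def write_plan(plan: ReplacementPlan, freq: FrequencyTable, path: str | Path) -> None:
    """Export TSV ``source<TAB>target<TAB>f_source<TAB>f_target``."""
    with open(path, "w", encoding="utf-8") as fh:
        for src in sorted(plan.mapping):
            tgt = plan.mapping[src]
            fh.write(f"{src}\t{tgt}\t{freq.get(src, 0)}\t{freq.get(tgt, 0)}\n")


def read_plan(path: str | Path) -> ReplacementPlan:
    """Load a plan TSV; summary counts are reconstructed from the mapping."""
    mapping: dict[str, str] = {}
    max_src = 0.0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            src, tgt, f_src, _f_tgt = line.rstrip("\n").split("\t")
            mapping[src] = tgt
            max_src = max(max_src, float(f_src))
    return ReplacementPlan(
        mapping=mapping,
        threshold=max_src + 1.0,
        n_candidates=len(mapping),
        n_replaced=len(mapping),
        n_retained_all_infrequent=0,
        n_retained_no_pool=0,
    )


def write_plan_summary(plan: ReplacementPlan, path: str | Path, **extra) -> None:
    payload = plan.summary() | extra
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
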