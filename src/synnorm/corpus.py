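"""Tokenized corpora and token frequency statistics.

A corpus is an ordered list of documents, each an ordered list of
whitespace-free lowercase tokens. Biomedical concepts are assumed to have
been collapsed to identifier tokens (e.g. ``mesh_d009203``) by upstream
annotation tools; this module takes tokens as given and never re-normalizes
them.

The frequency statistic that drives the replacement algorithm is f(w), the
number of occurrences of token *w* anywhere in the corpus (multiple
occurrences within one document all count). The derived mean frequency

    mu = total_tokens / vocab_size

is the mean of f(w) over *distinct* tokens (types, not occurrences); the
default replacement threshold tau is a multiple of mu. The per-type mean is
the only reading under which tau comes out as a small number on a large
corpus, and it is the one this package uses throughout.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping


@dataclass(frozen=True)
class LoadReport:
    """Bookkeeping from reading a corpus file."""

    n_documents: int
    n_empty_lines: int
    empty_corpus: bool


@dataclass
class Corpus:
    """An ordered collection of tokenized documents.

    Parameters
    ----------
    documents
        List of documents; each document is a list of tokens. Tokens must
        not contain whitespace.
    source_label
        Free-text provenance (file path, generator config, ...).
    """

    documents: list[list[str]]
    source_label: str = ""

    def __post_init__(self) -> None:
        for doc in self.documents:
            for tok in doc:
                if not tok or any(c.isspace() for c in tok):
                    raise ValueError(
                        f"token {tok!r} is empty or contains whitespace"
                    )

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[list[str]]:
        return iter(self.documents)

    @property
    def n_tokens(self) -> int:
        return sum(len(d) for d in self.documents)

    def vocabulary(self) -> set[str]:
        vocab: set[str] = set()
        for doc in self.documents:
            vocab.update(doc)
        return vocab


@dataclass(frozen=True)
class FrequencyTable:
    """Token occurrence counts with derived statistics.

    ``mean_frequency`` is total_tokens / vocab_size (mean count per
    distinct token); 0.0 with ``empty=True`` for an empty corpus.
    """

    counts: Mapping[str, int]
    total_tokens: int
    vocab_size: int
    mean_frequency: float
    empty: bool = field(default=False)

    def __getitem__(self, token: str) -> int:
        return self.counts.get(token, 0)

    def get(self, token: str, default: int = 0) -> int:
        return self.counts.get(token, default)

    def __contains__(self, token: str) -> bool:
        return token in self.counts


def read_corpus(path: str | Path) -> tuple[Corpus, LoadReport]:
    """Read a corpus from a one-document-per-line plain-text file.

    Each non-empty line becomes one document; tokens are split on runs of
    whitespace. Empty (all-whitespace) lines are skipped and counted in the
    returned :class:`LoadReport`. A file with zero documents is not an
    error but is flagged via ``report.empty_corpus``.
    """
    path = Path(path)
    documents: list[list[str]] = []
    n_empty = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            tokens = line.split()
            if tokens:
                documents.append(tokens)
            else:
                n_empty += 1
    report = LoadReport(
        n_documents=len(documents),
        n_empty_lines=n_empty,
        empty_corpus=len(documents) == 0,
    )
    return Corpus(documents, source_label=str(path)), report


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus in the one-document-per-line format.

    Round-trips exactly: ``read_corpus(write_corpus(c))`` yields the same
    token sequences.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus.documents:
            fh.write(" ".join(doc))
            fh.write("\n")


def count_frequencies(corpus: Corpus | Iterable[Iterable[str]]) -> FrequencyTable:
    """Tally f(w) for every token in the corpus.

    Every occurrence counts: a token appearing three times in one document
    contributes 3. Deterministic; an empty corpus yields an empty table
    with ``empty=True`` and mean frequency 0.
    """
    counts: Counter[str] = Counter()
    documents = corpus.documents if isinstance(corpus, Corpus) else corpus
    for doc in documents:
        counts.update(doc)
    total = sum(counts.values())
    vocab = len(counts)
    mu = total / vocab if vocab else 0.0
    return FrequencyTable(
        counts=dict(counts),
        total_tokens=total,
        vocab_size=vocab,
        mean_frequency=mu,
        empty=vocab == 0,
    )


def write_frequency_table(freq: FrequencyTable, path: str | Path) -> None:
    """Export as TSV ``token<TAB>count``, descending count then token."""
    items = sorted(freq.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w", encoding="utf-8") as fh:
        for token, count in items:
            fh.write(f"{token}\t{count}\n")


def read_frequency_table(path: str | Path) -> FrequencyTable:
    counts: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            token, count = line.rstrip("\n").split("\t")
            counts[token] = int(count)
    total = sum(counts.values())
    vocab = len(counts)
    return FrequencyTable(
        counts=counts,
        total_tokens=total,
        vocab_size=vocab,
        mean_frequency=total / vocab if vocab else 0.0,
        empty=vocab == 0,
    )
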