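"""Synonym pools: which words count as interchangeable.

The replacement algorithm needs, for any word, the set of candidate
synonyms it could be collapsed into. Two backends provide that pool:

* ``FixtureSynonyms`` — an in-repo TSV table (``word<TAB>member,member,...``),
  deterministic and version-independent; the backend used by the test
  suite and the synthetic pipeline.
* ``WordNetSynonyms`` — the English WordNet lexical database via nltk,
  pooling lemma names over *all* synsets of the word across all parts of
  speech. No word-sense disambiguation is attempted: the pool for a word
  is the union of its senses.

Both backends normalize pool members the same way: lowercased, and any
lemma that could never match a single corpus token — one containing
whitespace, an underscore (WordNet's multiword joiner), an apostrophe or a
hyphen — is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class SynonymPool:
    """The candidate synonyms of one word (may include the word itself)."""

    word: str
    members: frozenset[str]

    def __bool__(self) -> bool:
        return bool(self.members)

    def __contains__(self, token: str) -> bool:
        return token in self.members

    def __len__(self) -> int:
        return len(self.members)


_EXCLUDED_CHARS = ("_", "'", "-", "’")


def normalize_lemma(lemma: str) -> str | None:
    """Lowercase a lemma; return None if it cannot be a single corpus token."""
    lemma = lemma.lower()
    if not lemma:
        return None
    if any(c.isspace() for c in lemma):
        return None
    if any(c in lemma for c in _EXCLUDED_CHARS):
        return None
    return lemma


class SynonymResource:
    """Abstract word -> SynonymPool lookup."""

    backend_label: str = "abstract"

    def get_pool(self, word: str) -> SynonymPool:
        raise NotImplementedError


@dataclass
class FixtureSynonyms(SynonymResource):
    """Synonym table held in memory; loadable from TSV.

    An unknown word gets an empty pool — absence from the resource is not
    an error, it simply means the word has no synonyms to collapse into.
    """

    table: dict[str, frozenset[str]] = field(default_factory=dict)
    backend_label: str = "fixture"

    def get_pool(self, word: str) -> SynonymPool:
        members = self.table.get(word, frozenset())
        return SynonymPool(word=word, members=members)

    @classmethod
    def from_mapping(cls, mapping: dict[str, set[str] | frozenset[str] | list[str]]) -> "FixtureSynonyms":
        table: dict[str, frozenset[str]] = {}
        for word, members in mapping.items():
            normalized = {m for m in (normalize_lemma(x) for x in members) if m}
            table[word] = frozenset(normalized)
        return cls(table=table)

    @classmethod
    def from_classes(cls, classes: list[set[str] | list[str]]) -> "FixtureSynonyms":
        """Build a table where every member of a class maps to the full class."""
        mapping: dict[str, list[str]] = {}
        for members in classes:
            members = list(members)
            for m in members:
                mapping.setdefault(m, []).extend(members)
        return cls.from_mapping({w: set(ms) for w, ms in mapping.items()})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FixtureSynonyms":
        mapping: dict[str, set[str]] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 'word<TAB>members', got {line!r}"
                    )
                word, members = parts
                mapping[word] = set(members.split(","))
        return cls.from_mapping(mapping)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for word in sorted(self.table):
                fh.write(f"{word}\t{','.join(sorted(self.table[word]))}\n")


class WordNetSynonyms(SynonymResource):
    """WordNet-backed pools (requires the optional nltk dependency).

    The pool for a word is the union of lemma names over every synset of
    the word, every part of speech, normalized as module docstring
    describes. A word with at least one synset always contains itself.
    """

    backend_label = "wordnet"

    def __init__(self) -> None:
        try:
            from nltk.corpus import wordnet  # type: ignore
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise ImportError(
                "The wordnet backend requires nltk with the WordNet corpus "
                "(pip install nltk; nltk.download('wordnet')). "
                "Use FixtureSynonyms for a self-contained resource."
            ) from exc
        self._wordnet = wordnet

    def get_pool(self, word: str) -> SynonymPool:
        members: set[str] = set()
        for synset in self._wordnet.synsets(word):
            for lemma in synset.lemma_names():
                norm = normalize_lemma(lemma)
                if norm:
                    members.add(norm)
        return SynonymPool(word=word, members=frozenset(members))


def default_fixture_path() -> Path:
    """Path of the packaged example synonym table."""
    return Path(__file__).parent / "data" / "example_synonyms.tsv"


def load_resource(spec: str) -> SynonymResource:
    """Resolve a backend spec string: ``wordnet`` or ``fixture:PATH``."""
    if spec == "wordnet":
        return WordNetSynonyms()
    if spec == "fixture":
        return FixtureSynonyms.from_tsv(default_fixture_path())
    if spec.startswith("fixture:"):
        return FixtureSynonyms.from_tsv(spec.split(":", 1)[1])
    raise ValueError(f"unknown synonym backend {spec!r}")
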