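"""Concept sets: curated groups of related biomedical tokens.

Gene sets in MSigDB's GMT format (one tab-separated line per set:
``name<TAB>description<TAB>member...``) or MeSH-style category lists.
Evaluation categories follow the usual collection labels: M (MeSH),
B (Biocarta), K (KEGG), G (GO biological process), P (PID).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Collection, Iterable

logger = logging.getLogger(__name__)

CATEGORIES = ("M", "B", "K", "G", "P", "other")


@dataclass(frozen=True)
class ConceptSet:
    """A named set of concept tokens with a collection category."""

    name: str
    members: frozenset[str]
    category: str = "other"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"concept set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


def read_gmt(path: str | Path, category: str = "other") -> list[ConceptSet]:
    """Parse a GMT file into concept sets; members are lowercased.

    A line with fewer than three fields raises a ValueError naming the
    line number. Duplicate members on a line are collapsed with a logged
    warning.
    """
    sets: list[ConceptSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 member, got {len(fields)} field(s)"
                )
            name = fields[0]
            raw = [m.lower() for m in fields[2:] if m]
            members = frozenset(raw)
            if len(members) < len(raw):
                logger.warning(
                    "%s:%d: set %s has duplicate members, collapsed", path, lineno, name
                )
            sets.append(ConceptSet(name=name, members=members, category=category))
    return sets


def write_gmt(sets: Iterable[ConceptSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cs in sets:
            fh.write(f"{cs.name}\t{cs.category}\t" + "\t".join(sorted(cs.members)) + "\n")


def read_category_map(path: str | Path) -> dict[str, str]:
    """Sidecar map TSV ``set_name<TAB>category`` for GMT files."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            name, cat = line.rstrip("\n").split("\t")
            mapping[name] = cat
    return mapping


def filter_sets(
    sets: Iterable[ConceptSet],
    vocab_a: Collection[str],
    vocab_b: Collection[str],
    min_members: int = 5,
) -> list[ConceptSet]:
    """Keep sets with >= min_members members present in BOTH vocabularies.

    Surviving sets are restricted to the shared-present members, so
    downstream pairwise-distance lists are length-matched between the two
    embedding spaces. A set with 100 members of which only 3 occur in the
    corpus says nothing about embedding coherence and is dropped.
    """
    if min_members < 2:
        raise ValueError("min_members must be >= 2 (need at least one pair)")
    kept: list[ConceptSet] = []
    for cs in sets:
        present = frozenset(m for m in cs.members if m in vocab_a and m in vocab_b)
        if len(present) >= min_members:
            kept.append(ConceptSet(name=cs.name, members=present, category=cs.category))
    return kept
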