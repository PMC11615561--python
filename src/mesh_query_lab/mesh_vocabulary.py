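"""MeSH thesaurus representation: descriptors, entry terms, tree numbers.

A descriptor has a preferred term, synonymous entry terms, and one or more
dotted tree numbers placing it in the poly-hierarchy (e.g. ``C14.280.067``).
Searching a descriptor with explosion includes every descriptor whose tree
number extends one of its tree numbers — PubMed's ``[MeSH Terms]`` behaviour.

The on-disk format is a project-defined TSV/JSON (columns ``descriptor_id``,
``preferred_term``, ``entry_terms`` pipe-separated, ``tree_numbers``
pipe-separated) so that tests and simulations need no vocabulary download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "MeshDescriptor",
    "MeshVocabulary",
    "VocabularyError",
    "load_vocabulary",
    "FILTER_TERMS",
    "is_filter_term",
]

#: The 14 MeSH check tags PubMed uses as population/species filters.  These
#: keep their MeSH tag when a mixed query is rewritten to free text, so they
#: can continue to act as filters.
FILTER_TERMS = frozenset(
    {
        "80 and over",
        "adolescent",
        "adult",
        "aged",
        "animals",
        "child",
        "female",
        "humans",
        "infant",
        "male",
        "middle aged",
        "newborn",
        "preschool",
        "young adult",
    }
)


def is_filter_term(term: str) -> bool:
    """Case-insensitive membership in the 14-term check-tag whitelist."""
    return term.strip().lower() in FILTER_TERMS


class VocabularyError(ValueError):
    pass


@dataclass(frozen=True)
class MeshDescriptor:
    descriptor_id: str
    preferred_term: str
    entry_terms: frozenset[str] = frozenset()
    tree_numbers: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.tree_numbers:
            raise VocabularyError(
                f"descriptor {self.descriptor_id} has no tree numbers"
            )

    @property
    def all_terms(self) -> frozenset[str]:
        return self.entry_terms | {self.preferred_term}


class MeshVocabulary:
    """Indexed descriptor collection supporting lookup and explosion."""

    def __init__(self, descriptors: Iterable[MeshDescriptor] = ()):
        self._descriptors: dict[str, MeshDescriptor] = {}
        self._term_index: dict[str, str] = {}
        for d in descriptors:
            self.add(d)
        self._explode_cache: dict[str, frozenset[str]] = {}

    def add(self, descriptor: MeshDescriptor) -> None:
        if descriptor.descriptor_id in self._descriptors:
            raise VocabularyError(f"duplicate descriptor id {descriptor.descriptor_id}")
        for term in descriptor.all_terms:
            key = term.strip().lower()
            if key in self._term_index:
                raise VocabularyError(
                    f"term {term!r} maps to both {self._term_index[key]} "
                    f"and {descriptor.descriptor_id}"
                )
        self._descriptors[descriptor.descriptor_id] = descriptor
        for term in descriptor.all_terms:
            self._term_index[term.strip().lower()] = descriptor.descriptor_id
        self._explode_cache = {}

    def __len__(self) -> int:
        return len(self._descriptors)

    def __contains__(self, descriptor_id: str) -> bool:
        return descriptor_id in self._descriptors

    def __iter__(self):
        return iter(self._descriptors.values())

    def get(self, descriptor_id: str) -> MeshDescriptor:
        try:
            return self._descriptors[descriptor_id]
        except KeyError:
            raise VocabularyError(f"unknown descriptor {descriptor_id!r}") from None

    def normalize_term(self, term: str) -> Optional[str]:
        """Resolve preferred or entry-term spelling to a descriptor id.

        Matching is case-insensitive; ``None`` on a vocabulary miss (PubMed
        silently ignores MeSH-tagged terms absent from the thesaurus).
        """
        return self._term_index.get(term.strip().lower())

    def explode(self, descriptor_id: str) -> frozenset[str]:
        """The descriptor plus all narrower descriptors in any of its trees.

        ``d2 in explode(d1)`` iff ``d2 == d1`` or some tree number of ``d2``
        extends a tree number of ``d1`` by the dotted-prefix relation.
        Reflexive and transitively closed by construction.
        """
        if descriptor_id in self._explode_cache:
            return self._explode_cache[descriptor_id]
        root = self.get(descriptor_id)
        prefixes = tuple(tn + "." for tn in root.tree_numbers)
        members = {
            d.descriptor_id
            for d in self._descriptors.values()
            if any(tn.startswith(p) for tn in d.tree_numbers for p in prefixes)
        }
        members.add(descriptor_id)
        result = frozenset(members)
        self._explode_cache[descriptor_id] = result
        return result


def _build(rows: list[dict], source: str) -> MeshVocabulary:
    vocab = MeshVocabulary()
    for lineno, row in enumerate(rows, start=1):
        try:
            descriptor = MeshDescriptor(
                descriptor_id=str(row["descriptor_id"]).strip(),
                preferred_term=str(row["preferred_term"]).strip(),
                entry_terms=frozenset(
                    t for t in (s.strip() for s in row.get("entry_terms") or []) if t
                ),
                tree_numbers=frozenset(
                    t for t in (s.strip() for s in row.get("tree_numbers") or []) if t
                ),
            )
            vocab.add(descriptor)
        except (KeyError, VocabularyError) as exc:
            raise VocabularyError(f"{source}, row {lineno}: {exc}") from exc
    return vocab


def load_vocabulary(path: str | Path) -> MeshVocabulary:
    """Load a vocabulary from the TSV or JSON schema (chosen by suffix).

    TSV columns: descriptor_id, preferred_term, entry_terms (pipe-separated),
    tree_numbers (pipe-separated).  JSON: a list of objects with the same
    keys, entry_terms/tree_numbers as lists.  An empty file yields an empty
    vocabulary (every MeSH lookup misses).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text) if text.strip() else []
        rows = [
            {
                "descriptor_id": obj.get("descriptor_id"),
                "preferred_term": obj.get("preferred_term"),
                "entry_terms": obj.get("entry_terms", []),
                "tree_numbers": obj.get("tree_numbers", []),
            }
            for obj in data
        ]
        return _build(rows, path.name)

    rows = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return MeshVocabulary()
    header = lines[0].split("\t")
    expected = ["descriptor_id", "preferred_term", "entry_terms", "tree_numbers"]
    if [h.strip() for h in header] != expected:
        raise VocabularyError(
            f"{path.name}: header must be {expected!r}, got {header!r}"
        )
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 4:
            raise VocabularyError(
                f"{path.name}, line {lineno}: expected 4 tab-separated fields, "
                f"got {len(parts)}"
            )
        rows.append(
            {
                "descriptor_id": parts[0],
                "preferred_term": parts[1],
                "entry_terms": [s for s in parts[2].split("|") if s.strip()],
                "tree_numbers": [s for s in parts[3].split("|") if s.strip()],
            }
        )
    return _build(rows, path.name)


def save_vocabulary(vocab: MeshVocabulary, path: str | Path) -> None:
    """Write the TSV (or JSON, by suffix) mirror of :func:`load_vocabulary`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = [
            {
                "descriptor_id": d.descriptor_id,
                "preferred_term": d.preferred_term,
                "entry_terms": sorted(d.entry_terms),
                "tree_numbers": sorted(d.tree_numbers),
            }
            for d in vocab
        ]
        path.write_text(json.dumps(data, indent=1), encoding="utf-8")
        return
    lines = ["descriptor_id\tpreferred_term\tentry_terms\ttree_numbers"]
    for d in vocab:
        lines.append(
            "\t".join(
                [
                    d.descriptor_id,
                    d.preferred_term,
                    "|".join(sorted(d.entry_terms)),
                    "|".join(sorted(d.tree_numbers)),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
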