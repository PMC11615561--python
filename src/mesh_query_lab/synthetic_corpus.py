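"""Synthetic literature worlds for exercising the full pipeline offline.

Each world has a small MeSH-like thesaurus (a rooted tree of condition
descriptors, each with text synonyms as entry terms), a corpus of
MEDLINE-like records, a gold standard about one designated target
condition, and a mixed query in the authors' style
``OR(target[MeSH Terms], synonym_1[Title/Abstract], ...)`` optionally
AND-ed with a ``humans[MeSH Terms]`` check-tag clause.

The probabilistic knobs emulate the mechanisms that make MeSH terms and
free text complementary in real searching: ``p_text`` is the chance a
relevant concept surfaces verbatim in the title/abstract, ``p_index`` the
chance the record is MeSH-indexed at all (incomplete indexing stands in
for indexing lag), and ``p_broader`` the chance the indexer chose a different granularity
than the query's exact descriptor — a child of the target, the
finer-grained heading practice NLM indexers follow — which the query term
only recovers through explosion.
Distractor records may leak a target synonym with a small probability so
that precision is not degenerate at 1.
"""

from __future__ import annotations

import datetime as _dt
import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .local_retrieval import Corpus, DocumentRecord, evaluate_query
from .mesh_vocabulary import MeshDescriptor, MeshVocabulary
from .pubmed_query import Bool, FieldTag, QueryExpr, Term
from .query_transform import to_free_text, to_mesh_only
from .evaluation_metrics import score

__all__ = ["SyntheticSpec", "generate_world", "sweep_indexing"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic world.

    Defaults describe a mid-sized review setting: a few hundred candidate
    records, a modest thesaurus, strong but imperfect text signal
    (p_text=0.9), the roughly four-fifths indexing completeness seen for
    recent records (p_index=0.8), and occasional broader-than-exact
    indexing (p_broader=0.15).
    """

    n_docs: int = 400
    n_concepts: int = 12
    tree_branching: int = 3
    synonyms_per_concept: int = 3
    p_text: float = 0.9
    p_index: float = 0.8
    p_broader: float = 0.15
    p_distractor_leak: float = 0.02
    n_gold: int = 40
    with_filter_clause: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_text", "p_index", "p_broader", "p_distractor_leak"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.n_gold > self.n_docs:
            raise ValueError(f"n_gold={self.n_gold} exceeds n_docs={self.n_docs}")
        if self.n_concepts < 2 or self.n_docs < 1:
            raise ValueError("need at least 2 concepts and 1 document")


def _build_vocabulary(spec: SyntheticSpec) -> tuple[MeshVocabulary, list[str]]:
    """A rooted tree of condition descriptors plus the 'humans' check tag.

    Concept 0 is the tree root; concept ``i`` hangs under concept
    ``(i - 1) // branching``.  Returns the vocabulary and the concept
    descriptor ids in index order.
    """
    tree_numbers: list[str] = []
    for i in range(spec.n_concepts):
        if i == 0:
            tree_numbers.append("C01")
        else:
            parent = (i - 1) // spec.tree_branching
            sibling = (i - 1) % spec.tree_branching
            tree_numbers.append(f"{tree_numbers[parent]}.{sibling + 1:03d}")
    descriptors = []
    ids = []
    for i in range(spec.n_concepts):
        did = f"D{i:06d}"
        ids.append(did)
        descriptors.append(
            MeshDescriptor(
                descriptor_id=did,
                preferred_term=f"condition{i:03d}",
                entry_terms=frozenset(
                    f"synonym{i:03d}x{j}" for j in range(spec.synonyms_per_concept)
                ),
                tree_numbers=frozenset({tree_numbers[i]}),
            )
        )
    descriptors.append(
        MeshDescriptor(
            descriptor_id="D900000",
            preferred_term="humans",
            entry_terms=frozenset(),
            tree_numbers=frozenset({"B01"}),
        )
    )
    return MeshVocabulary(descriptors), ids


def _sentence(rng: np.random.Generator, mentions: Sequence[str]) -> tuple[str, str]:
    """Title and abstract from fixed templates with whole-word mentions."""
    fillers = ["cohort", "trial", "registry", "survey", "series"]
    filler = fillers[int(rng.integers(len(fillers)))]
    title_terms = " and ".join(mentions[:2]) if mentions else "unrelated findings"
    title = f"A {filler} study of {title_terms} in adults"
    body = " ".join(f"Patients with {m} were assessed." for m in mentions)
    abstract = body or "No specific condition was assessed."
    return title, abstract


def generate_world(
    spec: SyntheticSpec,
) -> tuple[MeshVocabulary, Corpus, frozenset[int], QueryExpr]:
    """Deterministically generate (vocabulary, corpus, gold standard, V1 query).

    Gold documents are about concept 0's first child (so explosion and
    broader indexing are both exercisable); the V1 query OR-joins the
    target descriptor as a MeSH term with every synonym as a
    title/abstract term, AND-ed with a ``humans[MeSH Terms]`` clause when
    ``with_filter_clause`` is set.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    vocab, ids = _build_vocabulary(spec)
    target_idx = 1 if spec.n_concepts > 1 else 0
    target = vocab.get(ids[target_idx])
    # first child of the target in the tree, if the spec is large enough;
    # used when the indexer picked a finer-grained heading (p_broader)
    child_idx = target_idx * spec.tree_branching + 1
    narrower = vocab.get(ids[child_idx]) if child_idx < spec.n_concepts else target
    synonyms = sorted(target.entry_terms)

    records = []
    gold = set()
    for i in range(spec.n_docs):
        pmid = 1000 + i
        is_gold = i < spec.n_gold
        headings: list[tuple[str, bool]] = []
        if is_gold:
            gold.add(pmid)
            mentions = [s for s in synonyms if rng.random() < spec.p_text]
            if rng.random() < spec.p_index:
                off_exact = rng.random() < spec.p_broader
                headings.append(
                    (narrower.preferred_term if off_exact else target.preferred_term,
                     True)
                )
            concept_terms = mentions
        else:
            other_idx = int(rng.integers(2, spec.n_concepts)) if spec.n_concepts > 2 \
                else 0
            other = vocab.get(ids[other_idx])
            concept_terms = [sorted(other.all_terms)[0]]
            if rng.random() < spec.p_index:
                headings.append((other.preferred_term, True))
            if rng.random() < spec.p_distractor_leak and synonyms:
                concept_terms.append(synonyms[int(rng.integers(len(synonyms)))])
        if rng.random() < spec.p_index:
            headings.append(("humans", False))
        title, abstract = _sentence(rng, concept_terms)
        records.append(
            DocumentRecord(
                pmid=pmid,
                title=title,
                abstract=abstract,
                mesh_headings=tuple(headings),
                journal="Synthetic Journal of Medicine",
                pub_date=_dt.date(2015, 1, 1) + _dt.timedelta(
                    days=int(rng.integers(0, 2555))
                ),
                filters=frozenset({"journal article"}),
            )
        )

    clause: QueryExpr = Bool(
        "OR",
        (Term(target.preferred_term, FieldTag.MESH),)
        + tuple(Term(s, FieldTag.TITLE_ABSTRACT) for s in synonyms),
    )
    if spec.with_filter_clause:
        clause = Bool("AND", (clause, Term("humans", FieldTag.MESH)))
    return vocab, Corpus(records), frozenset(gold), clause


def sweep_indexing(
    spec: SyntheticSpec,
    p_index_values: Sequence[float],
    replicates: int = 1,
) -> pd.DataFrame:
    """Monte-Carlo sweep of indexing completeness.

    For every grid value of ``p_index`` and every replicate (substream
    seed = spec.seed + replicate index), generates a world, derives V2 and
    V3 from the V1 query, runs all three, and records sensitivity and PPV
    per arm.  Long-format frame with one row per (p_index, replicate, arm).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    for p_index in p_index_values:
        for rep in range(replicates):
            sub = replace(spec, p_index=p_index, seed=spec.seed + rep)
            vocab, corpus, gold, v1 = generate_world(sub)
            queries = {
                "V1": v1,
                "V2": to_free_text(v1),
                "V3": to_mesh_only(v1, vocab),
            }
            for arm, q in queries.items():
                result = evaluate_query(corpus, q, vocab)
                rec = score(set(result.pmids), gold)
                rows.append(
                    {
                        "p_index": p_index,
                        "replicate": rep,
                        "arm": arm,
                        "items": result.total_matched,
                        "gs_found": rec.gs_found,
                        "sensitivity": rec.se,
                        "ppv": rec.ppv,
                    }
                )
    return pd.DataFrame(rows)
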