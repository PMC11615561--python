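"""Rewrite a mixed PubMed query (V1) into free-text-only (V2) and
MeSH-only (V3) variants.

V2 swaps every MeSH-class tag for [Title/Abstract], except the 14 check
tags (humans, female, ...) which keep their MeSH tag so they can continue
to act as population filters.  V3 retags every free-text term as a MeSH
term and then deletes any MeSH-tagged term the thesaurus does not know —
PubMed silently ignores such terms, which is equivalent to deleting them.
Deleting every content term leaves the nonviable empty query that returns
zero results.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Callable, Literal, Optional

from .mesh_vocabulary import MeshVocabulary, is_filter_term
from .pubmed_query import (
    FREE_TEXT_TAGS,
    MESH_TAGS,
    Bool,
    Empty,
    FieldTag,
    QueryExpr,
    Term,
    map_terms,
)

__all__ = ["to_free_text", "to_mesh_only", "simplify"]


def simplify(expr: QueryExpr) -> QueryExpr:
    """Collapse Empty children out of a tree (idempotent).

    Set semantics drive the NOT rules: ``A \\ empty = A`` but
    ``empty \\ A = empty``.  A boolean node left with one child collapses to
    that child; with none, to Empty.
    """
    if not isinstance(expr, Bool):
        return expr
    children = [simplify(c) for c in expr.children]
    if expr.op == "NOT":
        left, right = children
        if isinstance(left, Empty):
            return Empty()
        if isinstance(right, Empty):
            return left
        return Bool("NOT", (left, right))
    kept = [c for c in children if not isinstance(c, Empty)]
    if not kept:
        return Empty()
    if len(kept) == 1:
        return kept[0]
    return Bool(expr.op, tuple(kept))


def to_free_text(expr: QueryExpr) -> QueryExpr:
    """Derive the free-text-only (V2) variant of a parsed V1 tree.

    Every term tagged [MeSH Terms]/[Mesh:NoExp]/[Majr] whose text is outside
    the 14-term whitelist is retagged [Title/Abstract]; whitelist terms and
    all other nodes are untouched, and the tree shape is preserved.
    """

    def retag(term: Term) -> QueryExpr:
        if term.tag in MESH_TAGS and not is_filter_term(term.text):
            return replace(term, tag=FieldTag.TITLE_ABSTRACT)
        return term

    return map_terms(expr, retag)


def to_mesh_only(
    expr: QueryExpr,
    vocab: MeshVocabulary,
    *,
    deletion: Literal["prune", "empty_set"] = "prune",
    preserve_whitelist: bool = False,
    on_delete: Optional[Callable[[Term], None]] = None,
) -> QueryExpr:
    """Derive the MeSH-only (V3) variant of a parsed V1 tree.

    Free-text terms ([Title/Abstract], [Title], [Text Word], [All Fields])
    are retagged [MeSH Terms]; then every MeSH-tagged term the vocabulary
    cannot resolve is deleted and the tree simplified.  Journal, filter,
    publication-type and date nodes pass through unchanged.

    Parameters
    ----------
    deletion:
        ``"prune"`` (default) removes the unresolvable term so an AND
        sibling survives (``A AND bad -> A``), mirroring PubMed's observed
        treatment of nonexistent headings.  ``"empty_set"`` instead keeps
        the term as a clause matching nothing (``A AND bad -> nothing``),
        for sensitivity analysis.
    preserve_whitelist:
        When true, free-text occurrences of the 14 check tags keep their
        free-text tag instead of being rewritten (the whitelist is only
        stated for the MeSH-to-free-text direction, so the default rewrites
        them like any other term).
    on_delete:
        Callback invoked with each deleted term (drives the mandatory
        deleted-term log in pipeline runs).
    """

    def retag(term: Term) -> QueryExpr:
        tag = term.tag
        if tag in FREE_TEXT_TAGS:
            if preserve_whitelist and is_filter_term(term.text):
                return term
            term = replace(term, tag=FieldTag.MESH, untagged=False)
            tag = FieldTag.MESH
        if tag in MESH_TAGS and vocab.normalize_term(term.text) is None:
            if on_delete is not None:
                on_delete(term)
            if deletion == "prune":
                return Empty()
            # empty-set propagation: keep a node that matches nothing
            return term
        return term

    return simplify(map_terms(expr, retag))
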