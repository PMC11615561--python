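"""PubMed boolean query trees: parsing, serialization, and ATM emulation.

PubMed's search dialect is a flat boolean language: terms (optionally
quoted phrases) carry a trailing bracketed field tag (``asthma[MeSH Terms]``,
``wheeze[tiab]``), AND/OR/NOT associate left to right at equal precedence,
and parentheses override.  ``NOT`` is PubMed's binary set difference, not a
unary negation.  Untagged terms are the ones PubMed's automatic term mapping
(ATM) would expand; :func:`atm_expand` emulates the minimal two-branch form
of that expansion (descriptor branch + all-fields branch).
"""

from __future__ import annotations

import datetime as _dt
import enum
import re
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence, Union

__all__ = [
    "FieldTag",
    "Term",
    "Bool",
    "DateRange",
    "Empty",
    "QueryExpr",
    "QueryParseError",
    "parse_query",
    "serialize_query",
    "atm_expand",
    "count_terms",
]


class QueryParseError(ValueError):
    """Raised for malformed query strings; carries the offending position."""

    def __init__(self, message: str, position: Optional[int] = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class FieldTag(enum.Enum):
    MESH = "MeSH Terms"
    MESH_NOEXP = "Mesh:NoExp"
    MESH_MAJOR = "Majr"
    TITLE_ABSTRACT = "Title/Abstract"
    TITLE = "Title"
    ALL_FIELDS = "All Fields"
    TEXT_WORD = "Text Word"
    JOURNAL = "Journal"
    FILTER = "Filter"
    DATE_PUBLICATION = "Date - Publication"
    PUBLICATION_TYPE = "Publication Type"

    @property
    def canonical(self) -> str:
        return f"[{self.value}]"


#: The tag classes whose terms address the MeSH thesaurus.
MESH_TAGS = frozenset({FieldTag.MESH, FieldTag.MESH_NOEXP, FieldTag.MESH_MAJOR})

#: The tag classes that address free text.
FREE_TEXT_TAGS = frozenset(
    {FieldTag.TITLE_ABSTRACT, FieldTag.TITLE, FieldTag.TEXT_WORD, FieldTag.ALL_FIELDS}
)

# Surface spellings (case-folded, whitespace-normalized) -> tag class.
# Real systematic-review queries mix these spellings freely.
_TAG_SPELLINGS = {
    "mesh terms": FieldTag.MESH,
    "mesh": FieldTag.MESH,
    "mh": FieldTag.MESH,
    "mesh:noexp": FieldTag.MESH_NOEXP,
    "mh:noexp": FieldTag.MESH_NOEXP,
    "mesh terms:noexp": FieldTag.MESH_NOEXP,
    "majr": FieldTag.MESH_MAJOR,
    "mesh major topic": FieldTag.MESH_MAJOR,
    "title/abstract": FieldTag.TITLE_ABSTRACT,
    "tiab": FieldTag.TITLE_ABSTRACT,
    "title": FieldTag.TITLE,
    "ti": FieldTag.TITLE,
    "all fields": FieldTag.ALL_FIELDS,
    "all": FieldTag.ALL_FIELDS,
    "text word": FieldTag.TEXT_WORD,
    "tw": FieldTag.TEXT_WORD,
    "journal": FieldTag.JOURNAL,
    "ta": FieldTag.JOURNAL,
    "filter": FieldTag.FILTER,
    "sb": FieldTag.FILTER,
    "publication type": FieldTag.PUBLICATION_TYPE,
    "pt": FieldTag.PUBLICATION_TYPE,
    "date - publication": FieldTag.DATE_PUBLICATION,
    "dp": FieldTag.DATE_PUBLICATION,
}


@dataclass(frozen=True)
class Term:
    """A leaf: term text plus the field it searches.

    ``untagged`` marks bare terms that carried no bracketed tag in the input
    (they default to ALL_FIELDS and are the targets of ATM expansion).
    """

    text: str
    tag: FieldTag = FieldTag.ALL_FIELDS
    quoted: bool = False
    untagged: bool = False


@dataclass(frozen=True)
class Bool:
    op: str  # "AND" | "OR" | "NOT"
    children: tuple["QueryExpr", ...]

    def __post_init__(self):
        if self.op not in ("AND", "OR", "NOT"):
            raise ValueError(f"unknown boolean op {self.op!r}")
        if self.op == "NOT" and len(self.children) != 2:
            raise ValueError("NOT is binary set difference: exactly 2 children")
        if self.op in ("AND", "OR") and len(self.children) < 2:
            raise ValueError(f"{self.op} requires >= 2 children")


@dataclass(frozen=True)
class DateRange:
    start: _dt.date
    end: _dt.date
    tag: FieldTag = FieldTag.DATE_PUBLICATION


@dataclass(frozen=True)
class Empty:
    """A query segment that matches nothing (e.g. after term deletion)."""


QueryExpr = Union[Term, Bool, DateRange, Empty]


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<quote>"[^"]*")
  | (?P<lparen>\()
  | (?P<rparen>\))
  | (?P<tag>\[[^\[\]]*\])
  | (?P<word>[^\s()\[\]"]+)
    """,
    re.VERBOSE,
)


@dataclass
class _Token:
    kind: str
    value: str
    pos: int


def _tokenize(text: str) -> list[_Token]:
    if text.count('"') % 2:
        raise QueryParseError("unbalanced quotes", text.rfind('"'))
    tokens: list[_Token] = []
    i = 0
    while i < len(text):
        m = _TOKEN_RE.match(text, i)
        if m is None:  # pragma: no cover - regex covers any character
            raise QueryParseError("unexpected character", i)
        kind = m.lastgroup
        if kind != "ws":
            tokens.append(_Token(kind, m.group(), i))
        i = m.end()
    depth = 0
    for tok in tokens:
        if tok.kind == "lparen":
            depth += 1
        elif tok.kind == "rparen":
            depth -= 1
            if depth < 0:
                raise QueryParseError("unbalanced parentheses", tok.pos)
    if depth:
        raise QueryParseError("unbalanced parentheses", len(text) - 1)
    return tokens


def _resolve_tag(raw: str, pos: int) -> FieldTag:
    key = re.sub(r"\s+", " ", raw[1:-1].strip()).lower()
    try:
        return _TAG_SPELLINGS[key]
    except KeyError:
        known = sorted({t for t in _TAG_SPELLINGS})
        raise QueryParseError(
            f"unknown field tag [{raw[1:-1]}]; known tags: {', '.join(known)}", pos
        ) from None


_DATE_PAIR_RE = re.compile(
    r"^(\d{4})(?:/(\d{1,2}))?(?:/(\d{1,2}))?"
    r":(\d{4})(?:/(\d{1,2}))?(?:/(\d{1,2}))?$"
)


def _parse_date_parts(y: str, m: Optional[str], d: Optional[str]) -> _dt.date:
    # Half-open months/years resolve to the first day.
    return _dt.date(int(y), int(m) if m else 1, int(d) if d else 1)


# ---------------------------------------------------------------------------
# Parser: flat left-to-right boolean fold over term groups
# ---------------------------------------------------------------------------


class _Parser:
    def __init__(self, tokens: list[_Token], length: int):
        self.tokens = tokens
        self.i = 0
        self.length = length

    def peek(self) -> Optional[_Token]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def parse(self) -> QueryExpr:
        expr = self.parse_expr()
        if self.peek() is not None:
            raise QueryParseError("trailing input", self.peek().pos)
        return expr

    def parse_expr(self) -> QueryExpr:
        left = self.parse_operand(first=True)
        while True:
            tok = self.peek()
            if tok is None or tok.kind == "rparen":
                return left
            if tok.kind == "word" and tok.value.upper() in ("AND", "OR", "NOT"):
                op = self.next().value.upper()
                right = self.parse_operand(first=False)
                if isinstance(left, Bool) and left.op == op and op != "NOT":
                    left = Bool(op, left.children + (right,))
                else:
                    left = Bool(op, (left, right))
            else:
                raise QueryParseError(
                    f"expected AND/OR/NOT between query segments, got {tok.value!r}",
                    tok.pos,
                )

    def parse_operand(self, first: bool) -> QueryExpr:
        tok = self.peek()
        if tok is None:
            raise QueryParseError("query ended where a term was expected", self.length)
        if tok.kind == "word" and tok.value.upper() == "NOT":
            raise QueryParseError(
                "NOT is binary (A NOT B); a query cannot start with NOT", tok.pos
            )
        if tok.kind == "lparen":
            self.next()
            expr = self.parse_expr()
            closing = self.peek()
            if closing is None or closing.kind != "rparen":
                raise QueryParseError("unbalanced parentheses", tok.pos)
            self.next()
            return expr
        return self.parse_term_group()

    def parse_term_group(self) -> QueryExpr:
        """One term: a run of words / one quoted phrase, plus optional [tag]."""
        words: list[str] = []
        quoted = False
        start = self.peek()
        while True:
            tok = self.peek()
            if tok is None or tok.kind in ("lparen", "rparen"):
                break
            if tok.kind == "word":
                if tok.value.upper() in ("AND", "OR", "NOT"):
                    break
                words.append(self.next().value)
            elif tok.kind == "quote":
                if words:
                    break
                quoted = True
                words.append(self.next().value[1:-1])
                break
            else:
                break
        if not words:
            tok = self.peek()
            raise QueryParseError(
                f"expected a term, got {tok.value!r}" if tok else "expected a term",
                tok.pos if tok else self.length,
            )
        text = " ".join(words)
        tok = self.peek()
        if tok is not None and tok.kind == "tag":
            tag = _resolve_tag(self.next().value, tok.pos)
            if tag is FieldTag.DATE_PUBLICATION:
                m = _DATE_PAIR_RE.match(text)
                if m is None:
                    raise QueryParseError(
                        f"expected a start:end date pair before {tok.value}", start.pos
                    )
                return DateRange(
                    _parse_date_parts(*m.groups()[:3]),
                    _parse_date_parts(*m.groups()[3:]),
                )
            return Term(text, tag, quoted=quoted)
        return Term(text, FieldTag.ALL_FIELDS, quoted=quoted, untagged=True)


def parse_query(text: str) -> QueryExpr:
    """Parse a PubMed search string into a query tree.

    Newlines are treated as spaces (queries are often line-wrapped in
    published appendices).  Raises :class:`QueryParseError` for unbalanced
    quotes/parentheses or unknown bracketed tags.
    """
    if not text or not text.strip():
        raise QueryParseError("empty query")
    tokens = _tokenize(text)
    if not tokens:
        raise QueryParseError("empty query")
    return _Parser(tokens, len(text)).parse()


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_RESERVED = ("AND", "OR", "NOT")


def _needs_quotes(text: str) -> bool:
    return any(w.upper() in _RESERVED for w in text.split()) or bool(
        re.search(r'[()\[\]":]', text)
    )


def _serialize(expr: QueryExpr, parent: Optional[str]) -> str:
    if isinstance(expr, Empty):
        return ""
    if isinstance(expr, Term):
        text = expr.text
        if expr.quoted or _needs_quotes(text):
            text = f'"{text}"'
        if expr.untagged and expr.tag is FieldTag.ALL_FIELDS:
            return text
        return f"{text}{expr.tag.canonical}"
    if isinstance(expr, DateRange):
        fmt = "%Y/%m/%d"
        return (
            f"{expr.start.strftime(fmt)}:{expr.end.strftime(fmt)}"
            f"{FieldTag.DATE_PUBLICATION.canonical}"
        )
    parts = [_serialize(c, expr.op) for c in expr.children]
    out = f" {expr.op} ".join(parts)
    # Flat left-to-right semantics: any nested boolean needs parentheses.
    if parent is not None:
        out = f"({out})"
    return out


def serialize_query(expr: QueryExpr) -> str:
    """Render a query tree back to PubMed syntax with canonical tag spellings.

    ``parse_query(serialize_query(t))`` is structurally equal to ``t`` for
    simplified trees.  An :class:`Empty` root serializes to the empty string.
    """
    return _serialize(expr, None)


# ---------------------------------------------------------------------------
# Tree utilities
# ---------------------------------------------------------------------------


def iter_terms(expr: QueryExpr) -> Iterator[Term]:
    """Yield every TERM leaf in document order."""
    if isinstance(expr, Term):
        yield expr
    elif isinstance(expr, Bool):
        for child in expr.children:
            yield from iter_terms(child)


def map_terms(expr: QueryExpr, fn) -> QueryExpr:
    """Rebuild the tree applying ``fn`` to each TERM leaf.

    ``fn`` may return any QueryExpr (including :class:`Empty` to delete).
    """
    if isinstance(expr, Term):
        return fn(expr)
    if isinstance(expr, Bool):
        return Bool(expr.op, tuple(map_terms(c, fn) for c in expr.children))
    return expr


def count_terms(expr: QueryExpr, tag: Optional[FieldTag] = None) -> int:
    """Count TERM leaves, optionally restricted to one tag class.

    DATE_RANGE and EMPTY nodes contribute zero; a ``tag`` of ``None``
    counts every leaf.
    """
    return sum(1 for t in iter_terms(expr) if tag is None or t.tag is tag)


def atm_expand(expr: QueryExpr, vocab) -> QueryExpr:
    """Emulate PubMed's automatic term mapping on untagged terms.

    Each untagged term ``t`` becomes ``OR(t[MeSH Terms], t[All Fields])``
    when the vocabulary resolves it to a descriptor, and a plain
    ``t[All Fields]`` otherwise.  Tagged terms pass through; the result
    carries no untagged flags, which makes the operation idempotent.
    """

    def expand(term: Term) -> QueryExpr:
        if not term.untagged:
            return term
        tagged = replace(term, untagged=False)
        if vocab.normalize_term(term.text) is not None:
            return Bool(
                "OR",
                (
                    replace(tagged, tag=FieldTag.MESH),
                    replace(tagged, tag=FieldTag.ALL_FIELDS),
                ),
            )
        return replace(tagged, tag=FieldTag.ALL_FIELDS)

    return map_terms(expr, expand)
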