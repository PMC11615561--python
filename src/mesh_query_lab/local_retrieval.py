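"""A desk-scale boolean retrieval engine over MEDLINE-like records.

Stands in for the PubMed engine: set semantics for AND/OR/NOT, tag-specific
field matching, MeSH explosion through the vocabulary, a 10,000-result cap,
and a deterministic surrogate for "Best Match" ranking (number of distinct
query terms matched, descending; ties by ascending PMID).  The surrogate is
a documented divergence from PubMed — it only matters when the cap bites.

Corpora load from MEDLINE flat files (``PMID- / TI  - / AB  - / MH  - /
JT  - / DP  -`` fields, via Biopython's Medline parser) or from a JSONL
schema with keys pmid/title/abstract/mesh_headings/journal/pub_date/filters.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio import Medline

from .mesh_vocabulary import MeshVocabulary
from .pubmed_query import Bool, DateRange, Empty, FieldTag, QueryExpr, Term, iter_terms

__all__ = [
    "DocumentRecord",
    "Corpus",
    "RetrievalResult",
    "read_medline",
    "read_jsonl",
    "write_jsonl",
    "read_gold_standard",
    "match_term",
    "evaluate_query",
    "DEFAULT_CAP",
]

DEFAULT_CAP = 10_000

#: Records whose publication date cannot be parsed keep this sentinel and
#: fail every date filter.
SENTINEL_DATE = _dt.date(1, 1, 1)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Case-folded alphanumeric tokens; no stemming, no spelling variants."""
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class DocumentRecord:
    pmid: int
    title: str = ""
    abstract: str = ""
    mesh_headings: tuple[tuple[str, bool], ...] = ()  # (term, major)
    journal: str = ""
    pub_date: _dt.date = SENTINEL_DATE
    filters: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.pmid <= 0:
            raise ValueError(f"pmid must be positive, got {self.pmid}")


class Corpus:
    """Immutable-ish collection of records indexed by PMID."""

    def __init__(self, records: Iterable[DocumentRecord] = ()):
        self._records: dict[int, DocumentRecord] = {}
        self._tokens: dict[int, dict] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: DocumentRecord) -> None:
        if record.pmid in self._records:
            raise ValueError(f"duplicate pmid {record.pmid}")
        self._records[record.pmid] = record
        self._tokens[record.pmid] = {
            "tiab": tokenize(record.title) + ["\x00"] + tokenize(record.abstract),
            "title": tokenize(record.title),
        }

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[DocumentRecord]:
        return iter(self._records.values())

    def __contains__(self, pmid: int) -> bool:
        return pmid in self._records

    def get(self, pmid: int) -> DocumentRecord:
        return self._records[pmid]

    @property
    def pmids(self) -> list[int]:
        return list(self._records)

    def _field_tokens(self, pmid: int, which: str) -> list[str]:
        return self._tokens[pmid][which]


def _phrase_in(phrase_tokens: Sequence[str], doc_tokens: Sequence[str]) -> bool:
    """Contiguous token-subsequence match."""
    n = len(phrase_tokens)
    if n == 0:
        return False
    if n == 1:
        return phrase_tokens[0] in doc_tokens
    limit = len(doc_tokens) - n
    first = phrase_tokens[0]
    for i in range(limit + 1):
        if doc_tokens[i] == first and list(doc_tokens[i : i + n]) == list(
            phrase_tokens
        ):
            return True
    return False


def _mesh_match(
    doc: DocumentRecord, term_text: str, vocab: MeshVocabulary, tag: FieldTag
) -> bool:
    target = vocab.normalize_term(term_text)
    if target is None:
        return False  # nonexistent heading: matches nothing
    if tag is FieldTag.MESH_NOEXP:
        allowed = frozenset({target})
    else:
        allowed = vocab.explode(target)
    for heading, major in doc.mesh_headings:
        if tag is FieldTag.MESH_MAJOR and not major:
            continue
        did = vocab.normalize_term(heading)
        if did is not None and did in allowed:
            return True
    return False


def match_term(
    doc: DocumentRecord,
    node: Term,
    vocab: MeshVocabulary,
    corpus: Optional[Corpus] = None,
) -> bool:
    """Does one document satisfy one TERM leaf?

    Field semantics: [Title/Abstract] and [Text Word] do a case-insensitive
    contiguous phrase match over title+abstract tokens; [Title] over the
    title only; MeSH tags resolve the term to a descriptor and test the
    document's headings against its explosion ([Mesh:NoExp] exact,
    [Majr] additionally requires the major-topic flag); [All Fields] is
    the union of text, MeSH, and journal matches; [Journal] is full-title
    equality; [Filter] and [Publication Type] test membership in the
    record's filter set.
    """
    text = node.text
    tag = node.tag
    if corpus is not None and doc.pmid in corpus:
        tiab = corpus._field_tokens(doc.pmid, "tiab")
        title = corpus._field_tokens(doc.pmid, "title")
    else:
        tiab = tokenize(doc.title) + ["\x00"] + tokenize(doc.abstract)
        title = tokenize(doc.title)
    if tag in (FieldTag.TITLE_ABSTRACT, FieldTag.TEXT_WORD):
        return _phrase_in(tokenize(text), tiab)
    if tag is FieldTag.TITLE:
        return _phrase_in(tokenize(text), title)
    if tag in (FieldTag.MESH, FieldTag.MESH_NOEXP, FieldTag.MESH_MAJOR):
        return _mesh_match(doc, text, vocab, tag)
    if tag is FieldTag.ALL_FIELDS:
        return (
            _phrase_in(tokenize(text), tiab)
            or _mesh_match(doc, text, vocab, FieldTag.MESH)
            or text.strip().lower() == doc.journal.strip().lower()
        )
    if tag is FieldTag.JOURNAL:
        return text.strip().lower() == doc.journal.strip().lower()
    if tag in (FieldTag.FILTER, FieldTag.PUBLICATION_TYPE):
        return text.strip().lower() in {f.lower() for f in doc.filters}
    raise ValueError(f"unsupported tag {tag}")  # pragma: no cover


@dataclass(frozen=True)
class RetrievalResult:
    pmids: tuple[int, ...]
    total_matched: int
    capped: bool

    def __post_init__(self):
        if self.capped != (self.total_matched > len(self.pmids)):
            raise ValueError("capped flag inconsistent with counts")


def _eval_set(corpus: Corpus, expr: QueryExpr, vocab: MeshVocabulary) -> set[int]:
    if isinstance(expr, Empty):
        return set()
    if isinstance(expr, Term):
        return {
            doc.pmid for doc in corpus if match_term(doc, expr, vocab, corpus=corpus)
        }
    if isinstance(expr, DateRange):
        return {
            doc.pmid
            for doc in corpus
            if doc.pub_date != SENTINEL_DATE and expr.start <= doc.pub_date <= expr.end
        }
    sets = [_eval_set(corpus, c, vocab) for c in expr.children]
    if expr.op == "AND":
        out = sets[0]
        for s in sets[1:]:
            out = out & s
        return out
    if expr.op == "OR":
        out = sets[0]
        for s in sets[1:]:
            out = out | s
        return out
    return sets[0] - sets[1]  # NOT: set difference


def evaluate_query(
    corpus: Corpus,
    expr: QueryExpr,
    vocab: MeshVocabulary,
    cap: int = DEFAULT_CAP,
) -> RetrievalResult:
    """Evaluate a simplified query tree against the corpus.

    Returns matches ranked by the deterministic surrogate (distinct TERM
    leaves matched, descending; PMID ascending) and truncated to ``cap``,
    mirroring PubMed's 10,000-result extraction limit.
    """
    matched = _eval_set(corpus, expr, vocab)
    terms = list(iter_terms(expr))

    def rank(pmid: int) -> tuple[int, int]:
        doc = corpus.get(pmid)
        hits = sum(1 for t in terms if match_term(doc, t, vocab, corpus=corpus))
        return (-hits, pmid)

    if len(matched) > cap:
        ordered = sorted(matched, key=rank)[:cap]
        return RetrievalResult(tuple(ordered), len(matched), True)
    ordered = sorted(matched, key=rank)
    return RetrievalResult(tuple(ordered), len(matched), False)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MEDLINE_DATE_FORMATS = ("%Y %b %d", "%Y %b", "%Y", "%Y/%m/%d", "%Y-%m-%d")


def _parse_pub_date(raw: str) -> Optional[_dt.date]:
    raw = raw.strip()
    # Season/range forms like "2001 Jul-Aug": keep the first month.
    raw = re.sub(r"([A-Za-z]{3})-[A-Za-z]{3}", r"\1", raw)
    for fmt in _MEDLINE_DATE_FORMATS:
        try:
            return _dt.datetime.strptime(raw, fmt).date()
        except ValueError:
            continue
    return None


def _parse_mh(value: str) -> tuple[str, bool]:
    major = "*" in value
    term = value.split("/")[0].replace("*", "").strip()
    return term, major


def read_medline(path: str | Path, warnings: Optional[list[str]] = None) -> Corpus:
    """Read a MEDLINE flat file into a corpus.

    MH values are split on ``/`` (qualifiers dropped) with ``*`` marking the
    major topic; DP values with only a year map to January 1; an unparseable
    DP keeps the record with a sentinel date and a warning.  Publication
    types (PT) populate the record's filter set, lower-cased, so printed
    filter clauses like ``systematic review[Filter]`` can match.
    """
    path = Path(path)
    records = []
    with open(path, encoding="utf-8") as handle:
        for rec in Medline.parse(handle):
            pmid_raw = rec.get("PMID")
            if not pmid_raw:
                raise ValueError(f"{path.name}: record without PMID")
            date = _parse_pub_date(rec.get("DP", ""))
            if date is None:
                if warnings is not None:
                    warnings.append(
                        f"PMID {pmid_raw}: unparseable DP {rec.get('DP')!r}; "
                        "record kept with sentinel date"
                    )
                date = SENTINEL_DATE
            records.append(
                DocumentRecord(
                    pmid=int(pmid_raw),
                    title=rec.get("TI", ""),
                    abstract=rec.get("AB", ""),
                    mesh_headings=tuple(_parse_mh(v) for v in rec.get("MH", [])),
                    journal=rec.get("JT", ""),
                    pub_date=date,
                    filters=frozenset(v.lower() for v in rec.get("PT", [])),
                )
            )
    return Corpus(records)


def read_jsonl(path: str | Path) -> Corpus:
    records = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        obj = json.loads(line)
        records.append(
            DocumentRecord(
                pmid=int(obj["pmid"]),
                title=obj.get("title", ""),
                abstract=obj.get("abstract", ""),
                mesh_headings=tuple(
                    (str(t), bool(m)) for t, m in obj.get("mesh_headings", [])
                ),
                journal=obj.get("journal", ""),
                pub_date=_dt.date.fromisoformat(obj["pub_date"])
                if obj.get("pub_date")
                else SENTINEL_DATE,
                filters=frozenset(obj.get("filters", [])),
            )
        )
    return Corpus(records)


def write_jsonl(corpus: Corpus, path: str | Path) -> None:
    lines = []
    for doc in corpus:
        lines.append(
            json.dumps(
                {
                    "pmid": doc.pmid,
                    "title": doc.title,
                    "abstract": doc.abstract,
                    "mesh_headings": [[t, m] for t, m in doc.mesh_headings],
                    "journal": doc.journal,
                    "pub_date": doc.pub_date.isoformat()
                    if doc.pub_date != SENTINEL_DATE
                    else None,
                    "filters": sorted(doc.filters),
                },
                sort_keys=True,
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_gold_standard(path: str | Path) -> frozenset[int]:
    """Newline-separated PMIDs; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#")[0].strip()
        if line:
            out.add(int(line))
    return frozenset(out)
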