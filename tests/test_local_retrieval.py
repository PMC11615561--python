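"""MEDLINE/JSONL I/O, field matching, and boolean set evaluation."""

import datetime as dt
import random

import pytest

from mesh_query_lab.local_retrieval import (
    Corpus,
    DocumentRecord,
    SENTINEL_DATE,
    evaluate_query,
    match_term,
    read_gold_standard,
    read_jsonl,
    read_medline,
    write_jsonl,
)
from mesh_query_lab.mesh_vocabulary import MeshDescriptor, MeshVocabulary
from mesh_query_lab.pubmed_query import Bool, DateRange, Empty, FieldTag, Term

MEDLINE = """\
PMID- 101
TI  - Effect of famotidine on gastric acid secretion in
      healthy adults
AB  - A randomized trial of famotidine versus placebo.
MH  - *Famotidine/therapeutic use
MH  - Humans
JT  - Synthetic Journal of Medicine
DP  - 2018 Mar 1
PT  - Randomized Controlled Trial

PMID- 102
TI  - Renal outcomes in severe hypertension
AB  - Cohort of patients with high blood pressure.
MH  - Hypertension, Renal
JT  - Another Journal
DP  - 2015
"""


class TestReadMedline:
    def test_two_record_fixture(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text(MEDLINE)
        corpus = read_medline(p)
        assert len(corpus) == 2

    def test_mh_qualifier_split_and_major_flag(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text(MEDLINE)
        corpus = read_medline(p)
        assert corpus.get(101).mesh_headings == (
            ("Famotidine", True),
            ("Humans", False),
        )

    def test_continuation_lines_joined(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text(MEDLINE)
        assert "healthy adults" in read_medline(p).get(101).title

    def test_year_only_dp_maps_to_january_first(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text(MEDLINE)
        assert read_medline(p).get(102).pub_date == dt.date(2015, 1, 1)

    def test_unparseable_dp_keeps_record_with_sentinel(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text("PMID- 7\nTI  - T\nDP  - Winter solstice\n")
        warnings = []
        corpus = read_medline(p, warnings=warnings)
        assert corpus.get(7).pub_date == SENTINEL_DATE
        assert len(warnings) == 1

    def test_record_without_pmid_errors(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text("TI  - No id here\n")
        with pytest.raises(ValueError, match="PMID"):
            read_medline(p)

    def test_jsonl_roundtrip_preserves_fields(self, tmp_path, corpus):
        p = tmp_path / "c.jsonl"
        write_jsonl(corpus, p)
        back = read_jsonl(p)
        assert len(back) == len(corpus)
        for doc in corpus:
            assert back.get(doc.pmid) == doc

    def test_gold_standard_reader(self, tmp_path):
        p = tmp_path / "gold.txt"
        p.write_text("101\n102  # included at full text\n\n")
        assert read_gold_standard(p) == {101, 102}


class TestMatchTerm:
    def test_title_abstract_phrase(self, corpus, vocab):
        doc = corpus.get(101)
        assert match_term(doc, Term("famotidine", FieldTag.TITLE_ABSTRACT), vocab)
        assert match_term(doc, Term("gastric acid", FieldTag.TITLE_ABSTRACT), vocab)
        assert not match_term(doc, Term("acid gastric", FieldTag.TITLE_ABSTRACT), vocab)

    def test_phrase_does_not_span_title_abstract_boundary(self, vocab):
        doc = DocumentRecord(pmid=1, title="alpha beta", abstract="gamma delta")
        assert not match_term(doc, Term("beta gamma", FieldTag.TITLE_ABSTRACT), vocab)

    def test_title_only(self, corpus, vocab):
        doc = corpus.get(101)
        assert match_term(doc, Term("famotidine", FieldTag.TITLE), vocab)
        assert not match_term(doc, Term("placebo", FieldTag.TITLE), vocab)

    def test_mesh_explosion_reaches_narrower_heading(self, corpus, vocab):
        # doc 102 carries "Hypertension, Renal", a child of "Hypertension"
        doc = corpus.get(102)
        assert match_term(doc, Term("hypertension", FieldTag.MESH), vocab)
        assert not match_term(doc, Term("hypertension", FieldTag.MESH_NOEXP), vocab)

    def test_mesh_major_requires_major_flag(self, corpus, vocab):
        assert match_term(
            corpus.get(101), Term("famotidine", FieldTag.MESH_MAJOR), vocab
        )
        assert not match_term(
            corpus.get(101), Term("humans", FieldTag.MESH_MAJOR), vocab
        )

    def test_entry_term_resolves_before_matching(self, corpus, vocab):
        assert match_term(
            corpus.get(102), Term("high blood pressure", FieldTag.MESH), vocab
        )

    def test_unresolvable_mesh_term_matches_nothing(self, corpus, vocab):
        assert not match_term(corpus.get(102), Term("bogus", FieldTag.MESH), vocab)

    def test_all_fields_is_union_of_text_mesh_journal(self, corpus, vocab):
        assert match_term(
            corpus.get(102), Term("hypertension", FieldTag.ALL_FIELDS), vocab
        )  # via MeSH explosion; the word also appears in the title
        assert match_term(
            corpus.get(103), Term("Another Journal", FieldTag.ALL_FIELDS), vocab
        )  # journal equality only
        assert not match_term(corpus.get(103), Term("humans", FieldTag.ALL_FIELDS), vocab)

    def test_journal_and_filter_fields(self, corpus, vocab):
        assert match_term(
            corpus.get(102), Term("systematic review", FieldTag.FILTER), vocab
        )
        assert match_term(
            corpus.get(101),
            Term("synthetic journal of medicine", FieldTag.JOURNAL),
            vocab,
        )
        assert not match_term(corpus.get(101), Term("BMJ", FieldTag.JOURNAL), vocab)


class TestEvaluateQuery:
    def test_empty_query_returns_nothing(self, corpus, vocab):
        result = evaluate_query(corpus, Empty(), vocab)
        assert result.pmids == () and result.total_matched == 0 and not result.capped

    def test_or_of_disjoint_terms(self, corpus, vocab):
        tree = Bool(
            "OR",
            (
                Term("famotidine", FieldTag.TITLE),
                Term("renal outcomes", FieldTag.TITLE),
            ),
        )
        assert set(evaluate_query(corpus, tree, vocab).pmids) == {101, 102}

    def test_not_is_set_difference(self, corpus, vocab):
        tree = Bool(
            "NOT",
            (
                Term("humans", FieldTag.MESH),  # docs 101 and 102
                Term("famotidine", FieldTag.TITLE),  # doc 101
            ),
        )
        assert set(evaluate_query(corpus, tree, vocab).pmids) == {102}

    def test_date_range_filters_and_sentinel_fails(self, vocab):
        docs = Corpus(
            [
                DocumentRecord(pmid=1, title="a", pub_date=dt.date(2015, 6, 1)),
                DocumentRecord(pmid=2, title="a", pub_date=dt.date(2022, 1, 1)),
                DocumentRecord(pmid=3, title="a"),  # sentinel date
            ]
        )
        tree = DateRange(dt.date(2012, 1, 1), dt.date(2021, 12, 31))
        assert set(evaluate_query(docs, tree, vocab).pmids) == {1}

    def test_cap_truncates_and_flags(self, vocab):
        docs = Corpus(
            [DocumentRecord(pmid=i, title="common word") for i in range(1, 21)]
        )
        result = evaluate_query(
            docs, Term("common", FieldTag.TITLE), vocab, cap=5
        )
        assert result.capped and result.total_matched == 20 and len(result.pmids) == 5
        # deterministic surrogate ranking: equal term hits, so ascending pmid
        assert result.pmids == (1, 2, 3, 4, 5)

    def test_ranking_prefers_more_matched_terms(self, vocab):
        docs = Corpus(
            [
                DocumentRecord(pmid=1, title="alpha"),
                DocumentRecord(pmid=2, title="alpha beta"),
            ]
        )
        tree = Bool(
            "OR", (Term("alpha", FieldTag.TITLE), Term("beta", FieldTag.TITLE))
        )
        assert evaluate_query(docs, tree, vocab).pmids == (2, 1)


# --- brute-force equivalence oracle -----------------------------------------


def _truth(doc, expr, vocab):
    """Independent per-document recursive truth evaluation."""
    if isinstance(expr, Empty):
        return False
    if isinstance(expr, Term):
        return match_term(doc, expr, vocab)
    if isinstance(expr, DateRange):
        return doc.pub_date != SENTINEL_DATE and expr.start <= doc.pub_date <= expr.end
    values = [_truth(doc, c, vocab) for c in expr.children]
    if expr.op == "AND":
        return all(values)
    if expr.op == "OR":
        return any(values)
    return values[0] and not values[1]


def _random_world(rng: random.Random):
    words = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta"]
    headings = ["Hypertension", "Hypertension, Renal", "Famotidine", "Humans"]
    docs = []
    for pmid in range(1, rng.randint(2, 40)):
        docs.append(
            DocumentRecord(
                pmid=pmid,
                title=" ".join(rng.choices(words, k=rng.randint(1, 5))),
                abstract=" ".join(rng.choices(words, k=rng.randint(0, 8))),
                mesh_headings=tuple(
                    (h, rng.random() < 0.5)
                    for h in rng.sample(headings, k=rng.randint(0, 3))
                ),
                journal=rng.choice(["J One", "J Two"]),
                pub_date=dt.date(rng.randint(2010, 2022), rng.randint(1, 12), 1),
            )
        )
    return Corpus(docs), words, headings


def _random_tree(rng: random.Random, words, depth=0):
    if depth >= 3 or rng.random() < 0.45:
        roll = rng.random()
        if roll < 0.55:
            return Term(rng.choice(words), rng.choice(
                [FieldTag.TITLE_ABSTRACT, FieldTag.TITLE, FieldTag.ALL_FIELDS]
            ))
        if roll < 0.8:
            return Term(
                rng.choice(["hypertension", "famotidine", "humans", "bogus"]),
                rng.choice([FieldTag.MESH, FieldTag.MESH_NOEXP, FieldTag.MESH_MAJOR]),
            )
        if roll < 0.9:
            return DateRange(dt.date(2012, 1, 1), dt.date(2018, 12, 31))
        return Term(rng.choice(["J One", "J Two"]), FieldTag.JOURNAL)
    op = rng.choice(["AND", "OR", "NOT"])
    n = 2 if op == "NOT" else rng.randint(2, 3)
    return Bool(op, tuple(_random_tree(rng, words, depth + 1) for _ in range(n)))


def test_set_evaluation_matches_per_document_truth_oracle(vocab):
    rng = random.Random(20240917)
    for _ in range(150):
        corpus, words, _ = _random_world(rng)
        tree = _random_tree(rng, words)
        result = evaluate_query(corpus, tree, vocab, cap=10_000)
        expected = {d.pmid for d in corpus if _truth(d, tree, vocab)}
        assert set(result.pmids) == expected


def test_monotonicity_of_or_and_and_branches(vocab):
    rng = random.Random(7)
    for _ in range(40):
        corpus, words, _ = _random_world(rng)
        base = _random_tree(rng, words)
        extra = _random_tree(rng, words)
        base_set = set(evaluate_query(corpus, base, vocab).pmids)
        or_set = set(evaluate_query(corpus, Bool("OR", (base, extra)), vocab).pmids)
        and_set = set(evaluate_query(corpus, Bool("AND", (base, extra)), vocab).pmids)
        assert base_set <= or_set
        assert and_set <= base_set


def test_de_morgan_against_oracle(vocab):
    # U \ (A OR B) == (U \ A) AND (U \ B), with U a universal title match
    rng = random.Random(99)
    for _ in range(20):
        corpus, words, _ = _random_world(rng)
        a = _random_tree(rng, words)
        b = _random_tree(rng, words)
        union = Bool("OR", (a, b))
        universe = {d.pmid for d in corpus}
        lhs = universe - set(evaluate_query(corpus, union, vocab).pmids)
        rhs = (universe - set(evaluate_query(corpus, a, vocab).pmids)) & (
            universe - set(evaluate_query(corpus, b, vocab).pmids)
        )
        assert lhs == rhs
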