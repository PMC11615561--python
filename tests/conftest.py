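import datetime as dt

import pytest

from mesh_query_lab import (
    Corpus,
    DocumentRecord,
    MeshDescriptor,
    MeshVocabulary,
    load_table1,
)


@pytest.fixture(scope="session")
def vocab() -> MeshVocabulary:
    """Small thesaurus: a hypertension subtree, a drug, and two check tags."""
    return MeshVocabulary(
        [
            MeshDescriptor(
                "D006973",
                "Hypertension",
                frozenset({"High Blood Pressure"}),
                frozenset({"C14.907.489"}),
            ),
            MeshDescriptor(
                "D006978",
                "Hypertension, Renal",
                frozenset({"Renal Hypertension"}),
                frozenset({"C14.907.489.631"}),
            ),
            MeshDescriptor(
                "D006977",
                "Hypertension, Malignant",
                frozenset(),
                frozenset({"C14.907.489.480"}),
            ),
            MeshDescriptor(
                "D005293", "Famotidine", frozenset(), frozenset({"D02.455.426.559"})
            ),
            MeshDescriptor("D006801", "Humans", frozenset(), frozenset({"B01.050"})),
            MeshDescriptor(
                "D008875", "Middle Aged", frozenset(), frozenset({"M01.060.116"})
            ),
        ]
    )


@pytest.fixture(scope="session")
def corpus() -> Corpus:
    return Corpus(
        [
            DocumentRecord(
                pmid=101,
                title="Effect of famotidine on gastric acid",
                abstract="A randomized trial of famotidine in adults.",
                mesh_headings=(("Famotidine", True), ("Humans", False)),
                journal="Synthetic Journal of Medicine",
                pub_date=dt.date(2018, 3, 1),
                filters=frozenset({"randomized controlled trial"}),
            ),
            DocumentRecord(
                pmid=102,
                title="Renal outcomes in severe hypertension",
                abstract="Cohort with high blood pressure followed for renal disease.",
                mesh_headings=(("Hypertension, Renal", True), ("Humans", False)),
                journal="Synthetic Journal of Medicine",
                pub_date=dt.date(2015, 7, 15),
                filters=frozenset({"systematic review"}),
            ),
            DocumentRecord(
                pmid=103,
                title="Blood pressure variability",
                abstract="No indexing yet for this recent record.",
                mesh_headings=(),
                journal="Another Journal",
                pub_date=dt.date(2021, 1, 2),
                filters=frozenset(),
            ),
        ]
    )


@pytest.fixture(scope="session")
def table1_rows():
    return load_table1()
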