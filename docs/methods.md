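# Methods

## The comparison

For each systematic review (SR) with a published PubMed query, three
query arms are defined:

* **V1** — the query as formatted by PubMed's automatic term mapping
  (ATM): a mix of MeSH-tagged and free-text-tagged terms.
* **V2** — free-text only: every `[MeSH Terms]`/`[Mesh:NoExp]`/`[Majr]`
  tag is replaced by `[Title/Abstract]`, except for the 14 MeSH check
  tags ("80 and over", adolescent, adult, aged, animals, child, female,
  humans, infant, male, middle aged, newborn, preschool, young adult),
  which keep their MeSH tag so they continue to act as population and
  species filters.
* **V3** — MeSH only: every `[Title/Abstract]`/`[Title]`/`[Text Word]`/
  `[All Fields]` tag becomes `[MeSH Terms]`; MeSH-tagged terms that the
  thesaurus cannot resolve are then deleted, since the search engine
  ignores them. Deletion follows prune semantics: under AND the sibling
  survives (`A AND bad → A`), under binary NOT `A NOT bad → A` and
  `bad NOT A → ∅`. The alternative empty-set propagation
  (`A AND bad → ∅`) is available behind the `deletion="empty_set"` flag
  for sensitivity analysis. A query whose every content term is deleted
  is *nonviable* and returns zero items.

Whether the 14-term whitelist also applies in the free-text→MeSH
direction is genuinely open; the default rewrites whitelist terms like
any other free-text term (the whitelist's purpose — keeping filters
functional — only arises in the MeSH→free-text direction), and
`preserve_whitelist=True` switches the behaviour.

Each arm is scored against the gold standard (GS; the articles the SR's
authors actually included): sensitivity Se = TP/|GS| (0 when |GS| = 0),
PPV = TP/retrieved (0 when nothing is retrieved), F1 = harmonic mean
(0 when Se + PPV = 0). Ratios follow fixed conventions: the
found-by-V1/found-by-V2 ratio treats 0/0 as 1 and x/0 as +∞; reading
cost (results screened per GS item found) is +∞ when no GS item was
found.

## Query parsing

PubMed's dialect is flat: AND/OR/NOT associate left to right at equal
precedence, parentheses override, NOT is binary set difference (a
leading NOT is a parse error). A term is a run of words or one quoted
phrase, with an optional trailing bracketed tag; common tag spellings
(`[Mesh]`, `[mh]`, `[tiab]`, `[tw]`, `[sb]`, …) normalize to one
canonical spelling per tag class, and unknown tags are errors rather
than silent `[All Fields]` fallbacks, to surface dialect drift. A
colon-separated date pair tagged `[Date - Publication]` becomes a date
range; partially specified dates resolve to the first day of the month
or year. Untagged terms carry an `[All Fields]` tag plus an "untagged"
flag; ATM emulation replaces each such term with
`OR(term[MeSH Terms], term[All Fields])` when the vocabulary resolves it
(and plain `[All Fields]` otherwise). This two-branch expansion is
deliberately minimal — the NLM's full translation tables are out of
scope, and the emulation exists so untagged synthetic queries are
well defined.

Out of scope: proximity operators, truncation (`*`), multi-part history
syntax (`#1 AND #2`), and subset semantics beyond literal filter
matching.

## Local retrieval

The engine evaluates a query tree under set semantics over a corpus of
MEDLINE-like records (PMID, title, abstract, MeSH headings with
major-topic flags, journal, publication date, filter strings). Field
semantics: `[Title/Abstract]` and `[Text Word]` do case-insensitive
contiguous token-phrase matching (tokens split on non-alphanumerics, no
stemming, no British/American normalization — reproducible and
conservative); MeSH tags resolve the term to a descriptor and test the
record's headings against its explosion (every descriptor whose dotted
tree number extends one of the target's; `[Mesh:NoExp]` requires the
exact descriptor, `[Majr]` additionally the major flag); `[All Fields]`
is the union of text, MeSH, and journal equality; `[Journal]` is
full-title equality (no abbreviation table); `[Filter]`/`[pt]` test
membership in the record's filter set. Records with unparseable dates
keep a sentinel and fail all date filters.

PubMed's "Best Match" ranking is irreproducible; when the 10,000-result
extraction cap bites, results are ordered by a deterministic surrogate
(number of distinct query terms matched, descending; then PMID
ascending). This is a documented divergence — it matters only for
capped queries, and GS items are counted only within the retained list,
deliberately replicating the extraction constraint of the original
analysis. The corpus schema omits author/affiliation fields, so
`[All Fields]` is narrower than PubMed's.

## Aggregation

Per-version summaries report median and quartiles using the
linear-interpolation order-statistic convention (R type 7) — the
published IQR bounds (657.50, 36.50, …) are midpoints of adjacent order
statistics for n = 59, which pins the convention. Proportions are
reported on the 0–100 scale. The reading-cost column excludes reviews
whose query returned zero items (nonviable rewrites) and keeps
found-nothing reviews as +∞ entries in the ranks; this is the only
convention that reproduces all nine published reading-cost cells.

The headline screening arithmetic mirrors the published computation:
per-version means of items and GS-found are each rounded to 2 decimals
first, then differenced (3493.14 − 2672.85 = 820.29 extra records
screened; 27.59 − 24.97 = 2.62 extra relevant papers), and the
screening cost per additional relevant paper is the quotient of the
rounded differences (313.09).

### Pooled odds ratios

Per review, 2×2 tables are built for sensitivity
(TP, FN | TP_ref, FN_ref) and PPV (TP, FP | TP_ref, FP_ref); 0.5 is
added to every cell of any table containing a zero; log odds ratios and
variances come from the corrected cells. Between-review variance τ² is
estimated by REML (bounded scalar maximization of the restricted
likelihood; DerSimonian–Laird closed form selectable). Two pooling
weights are exposed:

* `unweighted` (default): the pooled log OR is the arithmetic mean of
  the per-review log ORs, with variance (mean(vᵢ) + τ²)/k;
* `inverse_variance`: classical weights 1/(vᵢ + τ²).

The unweighted scheme is the default because it is the scheme that
reproduces the published pooled estimates to every printed digit
(sensitivity 0.547, CI 0.383–0.780 → printed 0.55, 0.38–0.78; PPV
1.257, CI 1.026–1.540 → printed 1.26, 1.03–1.54, V2 vs V1, all 59
reviews, REML); inverse-variance weighting gives 0.68 and 1.28 instead
and is reported as a sensitivity check. The implementation was verified
against an independent R `metafor` run (`rma(..., weighted=FALSE)`),
whose outputs are frozen into the test suite; a closed-form
DerSimonian–Laird hand computation provides a second, library-free
oracle. τ² agreement with metafor is asserted at 1e-5, the precision of
metafor's own Fisher-scoring convergence.

The V3-vs-V1 pooled values published alongside (0.31 for sensitivity,
3.11 for PPV) do **not** reproduce from the shipped counts under these
conventions (all-59: 0.10/3.19; excluding the 11 nonviable rewrites:
0.17/1.68); their inclusion rules live in supplementary material not
available here, so `forest_data` reports them under the same conventions
as V2-vs-V1 without claiming agreement.

## Known inconsistencies in the shipped table

The shipped per-review table is a faithful transcription of the
published one, and it is internally inconsistent in two places: for
reviews 32479176 and 31727627 the published sensitivity column
disagrees with found/GS computed from their own published counts
(e.g. 28/29 = 0.966 printed as 1.000; 127/132 = 0.962 printed as
0.985), propagating to two F-scores — 8 of the 531 metric cells in
total. The published corpus-wide totals (Σ items = 206,095,
Σ found = 1628) confirm the counts, not the metric column. Similarly,
four summary-table quantiles sit on rounding midpoints (e.g. recomputed
2.852 printed as 2.8) that no quantile convention or rounding rule
reproduces from the printed counts. The strict acceptance tests for
those two tables are therefore expected to fail on exactly those cells;
companion tests pin the discrepancy sets so that any new mismatch still
fails loudly. `verify_table1` reports the 8 metric cells at the default
0.0005 tolerance.

Also not implemented as a reproducible quantity: the published
"V1 provided 8.49% more of the GS's items than V2" (and the 35.55%,
27.06% analogues) — no formula consistent with the printed totals
yields those percentages (1628/1473 = 1.105).

## Synthetic worlds

`SyntheticSpec` describes a world: a rooted tree of condition
descriptors (branching 3 by default) each with 3 single-token synonyms
as entry terms, plus a "humans" check-tag descriptor; 400 records of
which 40 are gold (about one target condition, a child of the tree
root); distractor records are about other conditions. Gold records
surface each synonym in templated title/abstract sentences with
probability `p_text` = 0.9 (whole-word insertion, so tokenized phrase
matching is exact), are MeSH-indexed with probability `p_index` = 0.8
(incomplete indexing stands in for indexing lag), and, when indexed,
carry a finer-grained heading — a child of the target, as indexers
prefer the most specific descriptor — with probability
`p_broader` = 0.15, which the query's target term only recovers through
explosion. Distractors leak a target synonym with probability 0.02 so
precision is not degenerate at 1. The V1 query is
`OR(target[MeSH Terms], synonym_i[Title/Abstract] …) AND
humans[MeSH Terms]`.

Because V1 is the union of the pure arms' clauses, retrieval(V1) ⊇
retrieval(V2) and ⊇ retrieval(V3) exactly, per replicate — the
structural form of the finding that mixed queries maximize recall.
Randomness comes from one seeded generator; sweep replicates use
substream seeds `seed + replicate`. What the generator does *not*
emulate: realistic abstract language, ATM translation tables,
entry-term ambiguity, author/affiliation fields, and PubMed-scale
corpus sizes — so passing tests demonstrate the pipeline's mechanics
and orderings (dominance, indexing monotonicity, explosion recovery),
not real-world effect sizes.

## Numerical and degenerate-input choices

* Quantiles: type 7 everywhere, with +∞ entries ordered after all
  finite values; a quantile landing between a finite value and +∞ is
  +∞.
* Zero denominators: Se/PPV/F1 are 0 by convention (matching the
  published table's 0.000 rows); odds-ratio tables that are all-zero,
  or contain zeros while the correction is disabled, are non-estimable
  and excluded from pooling; pooling requires ≥ 2 estimable tables.
* REML: bounded scalar optimization on τ² ∈ [0, max(10·DL + 1,
  10·var(y) + 1)], absolute tolerance 1e-10; τ̂² clipped at 0.
* Wald CIs for proportions are clipped to [0, 1].
* Parser errors carry the offending character position; serialization
  quotes any term that would not survive a reparse (embedded operator
  words, brackets, colons).
* Determinism: fixed spec + seed produce byte-identical corpora and
  artifacts; study runs are deterministic end to end.

## Problem sizes

The test suite's property checks use corpora of ≤ 50 documents and
query trees of ≤ 15 nodes (500 random cases for the retrieval oracle,
500 generated trees for the parse/serialize round trip) and a
3-point × 20-replicate sweep at the default 400-document world — sizes
chosen so the full pipeline, including the Monte-Carlo sweep, runs in
well under a minute while still exercising explosion, capping, and all
boolean forms.
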