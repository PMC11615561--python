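"""Aggregation across reviews: per-version summaries, headline statistics,
gold-ratio distributions, and random-effects pooling of log odds ratios.

The per-review count table (one row per systematic review: result counts,
gold-standard size, gold items found by each query version, and the
published 3-decimal metrics) ships with the package and is the input to
every summary.

Pooling model: per-review log odds ratios ``y_i`` with within-review
variances ``v_i`` from the 2x2 cell reciprocals (after a 0.5-if-any-zero
continuity correction), between-review variance ``tau^2`` estimated by
REML (DerSimonian-Laird selectable), and a Wald 95% CI.  Two weighting
schemes are exposed: the classical inverse-variance weights
``1/(v_i + tau^2)`` and the unweighted arithmetic mean of the ``y_i``
(whose variance is ``(mean(v_i) + tau^2)/k``).  The unweighted scheme is
the default because it is the one that reproduces the published pooled
estimates; the inverse-variance scheme is reported alongside as a
sensitivity check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .evaluation_metrics import (
    CorrectionRule,
    EvalRecord,
    ORRecord,
    corrected_2x2,
    gs_ratio,
    odds_ratio_ppv,
    odds_ratio_sensitivity,
)

__all__ = [
    "Table1Row",
    "PooledResult",
    "load_table1",
    "packaged_table1_path",
    "verify_table1",
    "summarize_versions",
    "headline_stats",
    "build_tables",
    "pool_log_odds_ratios",
    "forest_data",
]

VERSIONS = ("v1", "v2", "v3")


@dataclass(frozen=True)
class Table1Row:
    sr_pmid: int
    items_v1: int
    items_v2: int
    items_v3: int
    gs_size: int
    found_v1: int
    found_v2: int
    found_v3: int
    printed: dict  # (metric, version) -> published 3-decimal value

    def eval_record(self, version: str) -> EvalRecord:
        return EvalRecord(
            sr_id=str(self.sr_pmid),
            version=version.upper(),
            items=getattr(self, f"items_{version}"),
            gs_size=self.gs_size,
            gs_found=getattr(self, f"found_{version}"),
        )


def packaged_table1_path() -> Path:
    """Location of the shipped per-review count table."""
    return Path(resources.files("mesh_query_lab") / "data" / "table1.csv")


def load_table1(path: Optional[str | Path] = None) -> list[Table1Row]:
    """Load and validate the 59-review count table (shipped copy by default).

    Raises ``ValueError`` naming the row for any count inconsistency
    (found > items or found > gold-standard size) and for a row count
    other than 59 when reading the shipped fixture.
    """
    src = Path(path) if path is not None else packaged_table1_path()
    df = pd.read_csv(src)
    required = ["sr_pmid", "gs_size"]
    for v in VERSIONS:
        required += [f"items_{v}", f"found_{v}", f"se_{v}", f"ppv_{v}", f"f1_{v}"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{src.name}: missing columns {missing}")
    rows = []
    for _, r in df.iterrows():
        for v in VERSIONS:
            if r[f"found_{v}"] > min(r[f"items_{v}"], r["gs_size"]):
                raise ValueError(
                    f"row {int(r['sr_pmid'])}: found_{v}={int(r[f'found_{v}'])} "
                    f"exceeds min(items_{v}, gs_size)"
                )
        rows.append(
            Table1Row(
                sr_pmid=int(r["sr_pmid"]),
                items_v1=int(r["items_v1"]),
                items_v2=int(r["items_v2"]),
                items_v3=int(r["items_v3"]),
                gs_size=int(r["gs_size"]),
                found_v1=int(r["found_v1"]),
                found_v2=int(r["found_v2"]),
                found_v3=int(r["found_v3"]),
                printed={
                    (m, v): float(r[f"{m}_{v}"])
                    for m in ("se", "ppv", "f1")
                    for v in VERSIONS
                },
            )
        )
    if path is None and len(rows) != 59:
        raise ValueError(f"shipped table must have 59 rows, found {len(rows)}")
    return rows


def verify_table1(rows: Sequence[Table1Row], tolerance: float = 0.0005) -> list[dict]:
    """Recompute Se/PPV/F1 from the counts and report every cell that
    differs from the published 3-decimal value by more than ``tolerance``.

    The shipped table is internally inconsistent for two reviews (their
    published sensitivity column does not equal found/gs_size from their
    own published counts), so the report is non-empty on the shipped data;
    see the methods note.
    """
    report = []
    for row in rows:
        for v in VERSIONS:
            rec = row.eval_record(v)
            for metric, value in (("se", rec.se), ("ppv", rec.ppv), ("f1", rec.f1)):
                printed = row.printed[(metric, v)]
                if abs(value - printed) > tolerance + 1e-12:
                    report.append(
                        {
                            "sr_pmid": row.sr_pmid,
                            "version": v,
                            "metric": metric,
                            "recomputed": value,
                            "printed": printed,
                        }
                    )
    return report


def _quantiles(values: Sequence[float], percent: bool = False) -> dict:
    """Median and quartiles with the linear-interpolation ("type 7")
    order-statistic convention, tolerating +inf entries."""
    arr = np.sort(np.asarray(values, dtype=float))
    scale = 100.0 if percent else 1.0

    def q(p: float) -> float:
        h = p * (len(arr) - 1)
        lo = int(math.floor(h))
        hi = int(math.ceil(h))
        if arr[lo] == arr[hi] or math.isinf(arr[lo]):
            return float(arr[lo]) * scale
        return float(arr[lo] + (h - lo) * (arr[hi] - arr[lo])) * scale

    return {"median": q(0.5), "q1": q(0.25), "q3": q(0.75)}


def summarize_versions(rows: Sequence[Table1Row]) -> pd.DataFrame:
    """Per-version medians and IQRs of Se/PPV/F1 (0-100 scale), result
    counts, gold items found, and reading cost.

    Reading cost is results-per-gold-item-found: reviews whose query
    returned zero items (nonviable rewrites) are excluded from that
    column; reviews that retrieved items but found no gold item enter as
    +infinity, which the order-statistic quantiles handle.
    """
    out = []
    for v in VERSIONS:
        items = [getattr(r, f"items_{v}") for r in rows]
        found = [getattr(r, f"found_{v}") for r in rows]
        recs = [r.eval_record(v) for r in rows]
        rc = [
            it / f if f else math.inf
            for it, f in zip(items, found)
            if it > 0
        ]
        row = {"version": v.upper()}
        for metric, vals, pct in (
            ("se", [rec.se for rec in recs], True),
            ("ppv", [rec.ppv for rec in recs], True),
            ("f1", [rec.f1 for rec in recs], True),
            ("items", items, False),
            ("gs_found", found, False),
            ("reading_cost", rc, False),
        ):
            qs = _quantiles(vals, percent=pct)
            for k, val in qs.items():
                row[f"{metric}_{k}"] = val
        row["reading_cost_n"] = len(rc)
        out.append(row)
    return pd.DataFrame(out).set_index("version")


def headline_stats(rows: Sequence[Table1Row]) -> dict:
    """Corpus-wide totals and the headline screening-cost arithmetic.

    The published per-review means are differences of per-version means
    each first rounded to 2 decimals; the screening cost per additional
    relevant paper is the quotient of those rounded differences.
    """
    n = len(rows)
    totals = {
        f"total_items_{v}": sum(getattr(r, f"items_{v}") for r in rows)
        for v in VERSIONS
    }
    totals.update(
        {
            f"total_found_{v}": sum(getattr(r, f"found_{v}") for r in rows)
            for v in VERSIONS
        }
    )
    mean_items_v1 = round(totals["total_items_v1"] / n, 2)
    mean_items_v2 = round(totals["total_items_v2"] / n, 2)
    mean_found_v1 = round(totals["total_found_v1"] / n, 2)
    mean_found_v2 = round(totals["total_found_v2"] / n, 2)
    extra_screened = round(mean_items_v1 - mean_items_v2, 2)
    extra_relevant = round(mean_found_v1 - mean_found_v2, 2)
    ratios = [gs_ratio(r.found_v1, r.found_v2) for r in rows]
    return {
        **totals,
        "n_reviews": n,
        "mean_additional_screened_per_sr": extra_screened,
        "mean_additional_relevant_per_sr": extra_relevant,
        "screening_cost_per_additional_relevant": (
            round(extra_screened / extra_relevant, 2) if extra_relevant else math.inf
        ),
        "impacted_reviews": sum(1 for r in rows if r.found_v1 > r.found_v2),
        "ratio_at_most_1": sum(1 for x in ratios if math.isfinite(x) and x <= 1.0),
        "ratio_at_most_1_05": sum(1 for x in ratios if math.isfinite(x) and x <= 1.05),
        "v3_zero_result_reviews": sum(1 for r in rows if r.items_v3 == 0),
    }


# ---------------------------------------------------------------------------
# Random-effects pooling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PooledResult:
    comparison: str
    measure: str
    pooled_or: float
    ci95: tuple[float, float]
    tau2: float
    k: int
    estimator: str
    weighting: str
    log_or: float
    se_log_or: float

    def __post_init__(self):
        if not (self.ci95[0] <= self.pooled_or <= self.ci95[1]):
            raise ValueError("pooled estimate outside its own CI")


def build_tables(
    rows: Sequence[Table1Row],
    comparison: Literal["v2_vs_v1", "v3_vs_v1"],
    measure: Literal["sensitivity", "ppv"],
) -> list[tuple[int, int, int, int]]:
    """Per-review 2x2 tables (a, b, c, d) with odds a/b in the numerator
    arm and c/d in the reference (V1) arm.

    sensitivity: a = gold found by the variant, b = gold missed;
    ppv: a = gold found, b = other items retrieved.
    """
    variant = comparison.split("_")[0]
    tables = []
    for r in rows:
        fa = getattr(r, f"found_{variant}")
        f1 = r.found_v1
        if measure == "sensitivity":
            tables.append((fa, r.gs_size - fa, f1, r.gs_size - f1))
        else:
            ia = getattr(r, f"items_{variant}")
            tables.append((fa, ia - fa, f1, r.items_v1 - f1))
    return tables


def _log_ors(
    tables: Iterable[tuple[float, float, float, float]],
    correction: CorrectionRule,
) -> tuple[np.ndarray, np.ndarray]:
    ys, vs = [], []
    for a, b, c, d in tables:
        if a == b == c == d == 0:
            continue  # no information at all
        (a2, b2, c2, d2), _ = corrected_2x2(a, b, c, d, correction)
        if 0 in (a2, b2, c2, d2):
            continue  # correction disabled and a zero cell remains
        ys.append(math.log((a2 / b2) / (c2 / d2)))
        vs.append(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    return np.asarray(ys), np.asarray(vs)


def _tau2_dl(y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    mu = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu) ** 2))
    k = len(y)
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    return max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0


def _tau2_reml(y: np.ndarray, v: np.ndarray) -> float:
    """Maximize the restricted log-likelihood of the additive model."""

    def neg_restricted_ll(tau2: float) -> float:
        wi = 1.0 / (v + tau2)
        mu = np.sum(wi * y) / np.sum(wi)
        return 0.5 * (
            float(np.sum(np.log(v + tau2)))
            + math.log(float(np.sum(wi)))
            + float(np.sum(wi * (y - mu) ** 2))
        )

    hi = max(_tau2_dl(y, v) * 10 + 1.0, 10.0 * float(np.var(y)) + 1.0)
    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(0.0, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(max(0.0, res.x))


def pool_log_odds_ratios(
    tables: Sequence[tuple[int, int, int, int]],
    estimator: Literal["REML", "DL"] = "REML",
    *,
    weighting: Literal["unweighted", "inverse_variance"] = "unweighted",
    correction: CorrectionRule = "if_any_zero",
    level: float = 0.95,
    comparison: str = "",
    measure: str = "",
) -> PooledResult:
    """Random-effects pooled odds ratio over per-review 2x2 tables.

    ``tau^2`` is estimated by REML (default) or DerSimonian-Laird on the
    inverse-variance likelihood; the pooled mean is the plain average of
    the log odds ratios under ``weighting="unweighted"`` (default) or the
    ``1/(v_i + tau^2)``-weighted mean under ``"inverse_variance"``.
    Requires at least two estimable tables after zero-cell handling.
    """
    y, v = _log_ors(tables, correction)
    k = len(y)
    if k < 2:
        raise ValueError(f"need >= 2 estimable tables, got {k}")
    tau2 = _tau2_reml(y, v) if estimator == "REML" else _tau2_dl(y, v)
    if weighting == "unweighted":
        mu = float(np.mean(y))
        se = math.sqrt((float(np.mean(v)) + tau2) / k)
    else:
        w = 1.0 / (v + tau2)
        mu = float(np.sum(w * y) / np.sum(w))
        se = math.sqrt(1.0 / float(np.sum(w)))
    z = stats.norm.ppf(0.5 + level / 2)
    return PooledResult(
        comparison=comparison,
        measure=measure,
        pooled_or=math.exp(mu),
        ci95=(math.exp(mu - z * se), math.exp(mu + z * se)),
        tau2=tau2,
        k=k,
        estimator=estimator,
        weighting=weighting,
        log_or=mu,
        se_log_or=se,
    )


def forest_data(
    rows: Sequence[Table1Row],
    comparison: Literal["v2_vs_v1", "v3_vs_v1"] = "v2_vs_v1",
    measure: Literal["sensitivity", "ppv"] = "sensitivity",
    estimator: Literal["REML", "DL"] = "REML",
    weighting: Literal["unweighted", "inverse_variance"] = "unweighted",
    correction: CorrectionRule = "if_any_zero",
) -> tuple[list[ORRecord], PooledResult]:
    """Per-review odds-ratio records plus the pooled row (forest-plot data)."""
    variant = comparison.split("_")[0].upper()
    fn = odds_ratio_sensitivity if measure == "sensitivity" else odds_ratio_ppv
    records = []
    for r in rows:
        rec = fn(r.eval_record(comparison.split("_")[0]), r.eval_record("v1"),
                 correction)
        if rec.estimable:
            records.append(rec)
    pooled = pool_log_odds_ratios(
        build_tables(rows, comparison, measure),
        estimator=estimator,
        weighting=weighting,
        correction=correction,
        comparison=f"{variant} vs V1",
        measure=measure,
    )
    return records, pooled


def forest_frame(records: Sequence[ORRecord], pooled: PooledResult) -> pd.DataFrame:
    """Serializable CSV layout: one row per review plus the pooled row."""
    z = stats.norm.ppf(0.975)
    data = [
        {
            "sr_id": rec.sr_id,
            "or": rec.or_value,
            "ci_low": math.exp(rec.log_or - z * rec.se_log_or),
            "ci_high": math.exp(rec.log_or + z * rec.se_log_or),
            "corrected": rec.corrected,
            "pooled": False,
        }
        for rec in records
    ]
    data.append(
        {
            "sr_id": f"pooled ({pooled.estimator}, {pooled.weighting}, k={pooled.k})",
            "or": pooled.pooled_or,
            "ci_low": pooled.ci95[0],
            "ci_high": pooled.ci95[1],
            "corrected": False,
            "pooled": True,
        }
    )
    return pd.DataFrame(data)
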