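"""Scoring of retrieval results against a gold standard.

For a review with gold standard GS and a query returning ``items`` results
of which ``gs_found`` are in GS:

* sensitivity (recall)  Se  = gs_found / |GS|
* positive predictive value (precision)  PPV = gs_found / items
* F1 = harmonic mean of Se and PPV

Between two query versions on the same gold standard, performance is
compared by odds ratios: odds of sensitivity TP/FN, odds of PPV TP/FP,
with a continuity correction for zero cells.  ``gs_ratio`` and
``reading_cost`` follow the division conventions of the source analysis
(0/0 -> 1, x/0 -> infinity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

from scipy import stats

__all__ = [
    "EvalRecord",
    "ORRecord",
    "score",
    "odds_ratio_ppv",
    "odds_ratio_sensitivity",
    "gs_ratio",
    "reading_cost",
    "wald_ci",
    "corrected_2x2",
]

CorrectionRule = Literal["if_any_zero", "none", "always"]


@dataclass(frozen=True)
class EvalRecord:
    """Per-(review, query-version) confusion counts and derived metrics."""

    sr_id: str
    version: str  # "V1" | "V2" | "V3"
    items: int
    gs_size: int
    gs_found: int

    def __post_init__(self):
        if not (0 <= self.gs_found <= min(self.items, self.gs_size)):
            raise ValueError(
                f"{self.sr_id} {self.version}: gs_found={self.gs_found} exceeds "
                f"min(items={self.items}, gs_size={self.gs_size})"
            )

    @property
    def fp(self) -> int:
        return self.items - self.gs_found

    @property
    def fn(self) -> int:
        return self.gs_size - self.gs_found

    @property
    def se(self) -> float:
        return self.gs_found / self.gs_size if self.gs_size else 0.0

    @property
    def ppv(self) -> float:
        return self.gs_found / self.items if self.items else 0.0

    @property
    def f1(self) -> float:
        s, p = self.se, self.ppv
        return 2 * s * p / (s + p) if s + p else 0.0


def score(
    retrieved: frozenset[int] | set[int],
    gold: frozenset[int] | set[int],
    items: Optional[int] = None,
    *,
    sr_id: str = "",
    version: str = "",
) -> EvalRecord:
    """Score a retrieved PMID list against the gold standard.

    ``items`` defaults to ``len(retrieved)``; pass the capped total when a
    query exceeded the extraction cap (gold items are then counted only
    within the retained list, replicating the extraction constraint).
    """
    gs_found = len(set(retrieved) & set(gold))
    return EvalRecord(
        sr_id=sr_id,
        version=version,
        items=len(retrieved) if items is None else items,
        gs_size=len(gold),
        gs_found=gs_found,
    )


@dataclass(frozen=True)
class ORRecord:
    sr_id: str
    comparison: str  # e.g. "V2 vs V1"
    measure: str  # "sensitivity" | "ppv"
    or_value: float
    log_or: float
    se_log_or: float
    corrected: bool
    estimable: bool = True


def corrected_2x2(
    a: float, b: float, c: float, d: float, correction: CorrectionRule
) -> tuple[tuple[float, float, float, float], bool]:
    """Apply the continuity rule: add 0.5 to every cell of a table that
    contains a zero (default), never, or always."""
    cells = (a, b, c, d)
    fire = correction == "always" or (
        correction == "if_any_zero" and any(x == 0 for x in cells)
    )
    if fire:
        return tuple(x + 0.5 for x in cells), True
    return cells, False


def _odds_ratio(
    sr_id: str,
    comparison: str,
    measure: str,
    a: int,
    b: int,
    c: int,
    d: int,
    correction: CorrectionRule,
) -> ORRecord:
    if a == b == c == d == 0 or correction == "none" and 0 in (a, b, c, d):
        # degenerate: no information in one or both arms
        return ORRecord(
            sr_id, comparison, measure, math.nan, math.nan, math.nan,
            corrected=False, estimable=False,
        )
    (a2, b2, c2, d2), corrected = corrected_2x2(a, b, c, d, correction)
    log_or = math.log((a2 / b2) / (c2 / d2))
    se = math.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    return ORRecord(sr_id, comparison, measure, math.exp(log_or), log_or, se, corrected)


def odds_ratio_ppv(
    rec_a: EvalRecord,
    rec_b: EvalRecord,
    correction: CorrectionRule = "if_any_zero",
) -> ORRecord:
    """OR of the PPV odds (TP/FP) of ``rec_a`` relative to ``rec_b``."""
    if rec_a.sr_id != rec_b.sr_id or rec_a.gs_size != rec_b.gs_size:
        raise ValueError("odds ratios compare versions of the same review")
    return _odds_ratio(
        rec_a.sr_id,
        f"{rec_a.version} vs {rec_b.version}",
        "ppv",
        rec_a.gs_found,
        rec_a.fp,
        rec_b.gs_found,
        rec_b.fp,
        correction,
    )


def odds_ratio_sensitivity(
    rec_a: EvalRecord,
    rec_b: EvalRecord,
    correction: CorrectionRule = "if_any_zero",
) -> ORRecord:
    """OR of the sensitivity odds (TP/FN) of ``rec_a`` relative to ``rec_b``."""
    if rec_a.sr_id != rec_b.sr_id or rec_a.gs_size != rec_b.gs_size:
        raise ValueError("odds ratios compare versions of the same review")
    if rec_a.gs_size == 0:
        return ORRecord(
            rec_a.sr_id,
            f"{rec_a.version} vs {rec_b.version}",
            "sensitivity",
            math.nan, math.nan, math.nan,
            corrected=False, estimable=False,
        )
    return _odds_ratio(
        rec_a.sr_id,
        f"{rec_a.version} vs {rec_b.version}",
        "sensitivity",
        rec_a.gs_found,
        rec_a.fn,
        rec_b.gs_found,
        rec_b.fn,
        correction,
    )


def gs_ratio(found_v1: int, found_v2: int) -> float:
    """Ratio of gold items found by V1 to those found by V2.

    Conventions: 0/0 -> 1 (neither query found anything, no change);
    x/0 with x > 0 -> +infinity.
    """
    if found_v1 < 0 or found_v2 < 0:
        raise ValueError("counts must be nonnegative")
    if found_v2 == 0:
        return 1.0 if found_v1 == 0 else math.inf
    return found_v1 / found_v2


def reading_cost(items: int, gs_found: int) -> float:
    """Results screened per gold item found; infinity when none was found."""
    if items < 0 or gs_found < 0:
        raise ValueError("counts must be nonnegative")
    if gs_found == 0:
        return math.inf
    return items / gs_found


def wald_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wald CI of a proportion, clipped to [0, 1]."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    p = successes / n
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(p * (1 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))
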