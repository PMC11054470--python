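"""Multi-criteria bonus/penalty rubric for prioritizing repurposing candidates.

Each drug's curated annotation is scored against a transparent point table
covering efficacy (immunomodulation trials, number of network genes
targeted), practicality (topical application, global availability,
orderability, practical issues), safety (grade 3–5 adverse-event risk,
unclear direction of effect), registration (ATC code) and annual pricing.
The rubric is data, not code: every point value lives in
:class:`RubricConfig`, and the pricing criteria can be disabled wholesale for
a cost-blind secondary analysis. The shortlist is all drugs with a strictly
positive total.

Scoring conventions: skin-specific immunomodulating efficacy (+2) subsumes
the general immunomodulation bonus (+1) — the larger applies, they never
stack; the very-low (+2) and low (+1) price bonuses are mutually exclusive
bands; "practical issues" (−1) and "severe practical issues" (−2) are
mutually exclusive with the worst applying. With the default points a total
lies in [−8, +7] (pricing enabled) or [−7, +5] (pricing disabled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence

from .types import DrugAnnotation, PracticalIssue, PriceBand, ScoreBreakdown

logger = logging.getLogger(__name__)

__all__ = [
    "RubricConfig",
    "RankedList",
    "SecondaryAnalysis",
    "price_band_from_annual_cost",
    "score_drug",
    "rank",
    "secondary_analysis",
]

#: Default criterion points.
DEFAULT_POINTS: Dict[str, int] = {
    "immunomod_general": 1,
    "immunomod_skin": 2,
    "network_targets_gt3": 1,
    "topical": 1,
    "who_essential": 1,
    "price_low": 1,
    "price_very_low": 2,
    "no_atc": -2,
    "not_orderable": -1,
    "unclear_direction": -1,
    "grade3to5_risk": -1,
    "practical_issue": -1,
    "practical_issue_severe": -2,
    "price_unavailable_or_very_high": -1,
}

#: Criteria zeroed out when pricing is disabled.
PRICING_CRITERIA = ("price_low", "price_very_low", "price_unavailable_or_very_high")


@dataclass
class RubricConfig:
    """Point values and pricing bands of the ranking rubric."""

    points: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_POINTS))
    pricing_enabled: bool = True
    #: EUR/year band edges: < very_low_lt is VERY_LOW; [very_low_lt, low_le]
    #: LOW; (low_le, very_high_gt] MID; > very_high_gt VERY_HIGH.
    very_low_lt: float = 50.0
    low_le: float = 500.0
    very_high_gt: float = 20000.0

    def __post_init__(self) -> None:
        unknown = set(self.points) - set(DEFAULT_POINTS)
        if unknown:
            raise ValueError(f"unknown rubric criteria: {sorted(unknown)}")
        for name, value in self.points.items():
            if int(value) != value:
                raise ValueError(f"criterion {name} has non-integer points")
        if not (self.very_low_lt < self.low_le < self.very_high_gt):
            raise ValueError("price band edges must be increasing")

    def without_pricing(self) -> "RubricConfig":
        return replace(self, points=dict(self.points), pricing_enabled=False)


def price_band_from_annual_cost(annual_eur: float, config: RubricConfig = None) -> PriceBand:
    """Classify an annual cost (EUR/year) into a rubric price band."""
    cfg = config or RubricConfig()
    if annual_eur < cfg.very_low_lt:
        return PriceBand.VERY_LOW
    if annual_eur <= cfg.low_le:
        return PriceBand.LOW
    if annual_eur <= cfg.very_high_gt:
        return PriceBand.MID
    return PriceBand.VERY_HIGH


def score_drug(annotation: DrugAnnotation, config: RubricConfig = None) -> ScoreBreakdown:
    """Apply the rubric to one drug and return an audited breakdown."""
    cfg = config or RubricConfig()
    pts = cfg.points
    applied: List = []

    if annotation.immunomod_skin:
        applied.append(("immunomod_skin", pts["immunomod_skin"]))
    elif annotation.immunomod_general:
        applied.append(("immunomod_general", pts["immunomod_general"]))
    if annotation.n_network_targets > 3:
        applied.append(("network_targets_gt3", pts["network_targets_gt3"]))
    if annotation.topical_possible:
        applied.append(("topical", pts["topical"]))
    if annotation.who_essential:
        applied.append(("who_essential", pts["who_essential"]))
    if cfg.pricing_enabled:
        if annotation.price_band is PriceBand.VERY_LOW:
            applied.append(("price_very_low", pts["price_very_low"]))
        elif annotation.price_band is PriceBand.LOW:
            applied.append(("price_low", pts["price_low"]))
        elif annotation.price_band in (PriceBand.VERY_HIGH, PriceBand.UNAVAILABLE):
            applied.append(
                ("price_unavailable_or_very_high", pts["price_unavailable_or_very_high"])
            )
    if not annotation.has_atc:
        applied.append(("no_atc", pts["no_atc"]))
    if not annotation.orderable:
        applied.append(("not_orderable", pts["not_orderable"]))
    if not annotation.direction_clear:
        applied.append(("unclear_direction", pts["unclear_direction"]))
    if annotation.grade3to5_risk:
        applied.append(("grade3to5_risk", pts["grade3to5_risk"]))
    if annotation.practical_issue is PracticalIssue.SEVERE:
        applied.append(("practical_issue_severe", pts["practical_issue_severe"]))
    elif annotation.practical_issue is PracticalIssue.ISSUE:
        applied.append(("practical_issue", pts["practical_issue"]))

    return ScoreBreakdown(
        drug=annotation.drug,
        applied=tuple(applied),
        total=sum(p for _, p in applied),
    )


@dataclass
class RankedList:
    breakdowns: List[ScoreBreakdown]  # ordered by total desc, then drug name

    @property
    def shortlist(self) -> List[ScoreBreakdown]:
        """Drugs with a strictly positive total."""
        return [b for b in self.breakdowns if b.total > 0]

    def total(self, drug: str) -> int:
        for b in self.breakdowns:
            if b.drug == drug:
                return b.total
        raise KeyError(drug)


def rank(annotations: Sequence[DrugAnnotation], config: RubricConfig = None) -> RankedList:
    """Score every annotated drug and order by total (desc), then name."""
    if not annotations:
        raise ValueError("no annotations supplied")
    seen = set()
    for ann in annotations:
        if ann.drug in seen:
            raise ValueError(f"duplicate drug annotation: {ann.drug!r}")
        seen.add(ann.drug)
    breakdowns = [score_drug(ann, config) for ann in annotations]
    breakdowns.sort(key=lambda b: (-b.total, b.drug))
    return RankedList(breakdowns=breakdowns)


@dataclass
class SecondaryAnalysis:
    primary: RankedList
    no_pricing: RankedList
    deltas: Dict[str, int]  # drug -> (no-pricing total − primary total)
    dropped_from_shortlist: List[str]


def secondary_analysis(
    annotations: Sequence[DrugAnnotation], config: RubricConfig = None
) -> SecondaryAnalysis:
    """Re-rank with pricing criteria disabled and report what changes.

    Reports per-drug score deltas and the drugs that leave the (total > 0)
    shortlist once cost considerations are removed.
    """
    cfg = config or RubricConfig()
    primary = rank(annotations, cfg)
    no_pricing = rank(annotations, cfg.without_pricing())
    deltas = {
        b.drug: no_pricing.total(b.drug) - b.total for b in primary.breakdowns
    }
    shortlist_before = {b.drug for b in primary.shortlist}
    shortlist_after = {b.drug for b in no_pricing.shortlist}
    dropped = sorted(shortlist_before - shortlist_after)
    if dropped:
        logger.info("no-pricing analysis drops %d drug(s) from the shortlist", len(dropped))
    return SecondaryAnalysis(
        primary=primary,
        no_pricing=no_pricing,
        deltas=deltas,
        dropped_from_shortlist=dropped,
    )
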