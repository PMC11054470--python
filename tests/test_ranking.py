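"""The bonus/penalty ranking rubric and the no-pricing secondary analysis."""

import itertools

import pytest

from vhenet.ranking import (
    DEFAULT_POINTS,
    PRICING_CRITERIA,
    RubricConfig,
    price_band_from_annual_cost,
    rank,
    score_drug,
    secondary_analysis,
)
from vhenet.types import DrugAnnotation, PracticalIssue, PriceBand


def _all_annotations(drug="D"):
    """Exhaustive enumeration of every annotation combination.

    n_network_targets is represented by its two behaviour classes (<=3, >3).
    """
    bools = (False, True)
    for combo in itertools.product(
        bools,  # immunomod_general
        bools,  # immunomod_skin
        (0, 5),  # n_network_targets
        bools,  # topical_possible
        bools,  # who_essential
        tuple(PriceBand),
        bools,  # has_atc
        bools,  # orderable
        bools,  # direction_clear
        bools,  # grade3to5_risk
        tuple(PracticalIssue),
    ):
        yield DrugAnnotation(
            drug,
            immunomod_general=combo[0],
            immunomod_skin=combo[1],
            n_network_targets=combo[2],
            topical_possible=combo[3],
            who_essential=combo[4],
            price_band=combo[5],
            has_atc=combo[6],
            orderable=combo[7],
            direction_clear=combo[8],
            grade3to5_risk=combo[9],
            practical_issue=combo[10],
        )


class TestScoreDrug:
    @pytest.mark.parametrize(
        "overrides,expected",
        [
            ({"immunomod_skin": True}, 2),
            ({"immunomod_general": True}, 1),
            ({"immunomod_general": True, "immunomod_skin": True}, 2),  # no stacking
            ({"n_network_targets": 5}, 1),
            ({"n_network_targets": 3}, 0),  # strictly more than 3
            ({"topical_possible": True}, 1),
            ({"who_essential": True}, 1),
            ({"price_band": PriceBand.VERY_LOW}, 2),
            ({"price_band": PriceBand.LOW}, 1),
            ({"price_band": PriceBand.VERY_HIGH}, -1),
            ({"price_band": PriceBand.UNAVAILABLE}, -1),
            ({"has_atc": False}, -2),
            ({"orderable": False}, -1),
            ({"direction_clear": False}, -1),
            ({"grade3to5_risk": True}, -1),
            ({"practical_issue": PracticalIssue.ISSUE}, -1),
            ({"practical_issue": PracticalIssue.SEVERE}, -2),
            ({}, 0),
        ],
    )
    def test_single_criterion_points(self, overrides, expected):
        breakdown = score_drug(DrugAnnotation.neutral("D", **overrides))
        assert breakdown.total == expected

    def test_total_always_sum_of_applied(self):
        for ann in _all_annotations():
            b = score_drug(ann)
            assert b.total == sum(p for _, p in b.applied)

    def test_exhaustive_bounds_with_and_without_pricing(self):
        with_pricing = [score_drug(a).total for a in _all_annotations()]
        cfg = RubricConfig(pricing_enabled=False)
        without = [score_drug(a, cfg).total for a in _all_annotations()]
        assert min(with_pricing) == -8 and max(with_pricing) == 7
        assert min(without) == -7 and max(without) == 5

    def test_bonus_monotone_penalty_antitone(self):
        base = DrugAnnotation.neutral("D")
        t0 = score_drug(base).total
        for field, value, sign in [
            ("immunomod_general", True, +1),
            ("immunomod_skin", True, +1),
            ("n_network_targets", 5, +1),
            ("topical_possible", True, +1),
            ("who_essential", True, +1),
            ("has_atc", False, -1),
            ("orderable", False, -1),
            ("direction_clear", False, -1),
            ("grade3to5_risk", True, -1),
            ("practical_issue", PracticalIssue.SEVERE, -1),
        ]:
            t = score_drug(DrugAnnotation.neutral("D", **{field: value})).total
            assert (t - t0) * sign > 0

    def test_no_pricing_equals_zeroed_price_points(self):
        cfg = RubricConfig()
        masked = RubricConfig(
            points={
                k: (0 if k in PRICING_CRITERIA else v) for k, v in DEFAULT_POINTS.items()
            }
        )
        no_pricing = cfg.without_pricing()
        for ann in _all_annotations():
            assert score_drug(ann, no_pricing).total == score_drug(ann, masked).total

    def test_price_band_classification(self):
        assert price_band_from_annual_cost(10) is PriceBand.VERY_LOW
        assert price_band_from_annual_cost(50) is PriceBand.LOW
        assert price_band_from_annual_cost(500) is PriceBand.LOW
        assert price_band_from_annual_cost(500.01) is PriceBand.MID
        assert price_band_from_annual_cost(20000) is PriceBand.MID
        assert price_band_from_annual_cost(20001) is PriceBand.VERY_HIGH


class TestRank:
    def test_shortlist_strictly_positive(self):
        anns = [
            DrugAnnotation.neutral("Good", immunomod_skin=True, topical_possible=True),
            DrugAnnotation.neutral("Bad", orderable=False),
            DrugAnnotation.neutral("Zero"),
        ]
        ranked = rank(anns)
        assert [b.drug for b in ranked.shortlist] == ["Good"]

    def test_ordering_total_desc_then_name(self):
        anns = [
            DrugAnnotation.neutral("B", who_essential=True),
            DrugAnnotation.neutral("A", topical_possible=True),
            DrugAnnotation.neutral("C", immunomod_skin=True),
        ]
        assert [b.drug for b in rank(anns).breakdowns] == ["C", "A", "B"]

    def test_duplicate_drug_raises(self):
        with pytest.raises(ValueError, match="duplicate"):
            rank([DrugAnnotation.neutral("D"), DrugAnnotation.neutral("D")])

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            rank([])


class TestReconstructedShortlist:
    def test_totals_match_published_scores(self):
        from vhenet.datasets import load_candidate_ranking, reconstructed_annotations

        ranked = rank(reconstructed_annotations())
        published = dict(
            zip(load_candidate_ranking()["drug"], load_candidate_ranking()["score"])
        )
        assert len(published) == 46
        for b in ranked.breakdowns:
            assert b.total == published[b.drug], b.drug
        # every published candidate has score > 0, so all stay on the shortlist
        assert len(ranked.shortlist) == len(published)


class TestSecondaryAnalysis:
    def test_pricing_only_drug_drops_from_shortlist(self):
        # a very-low-price-only candidate scores 2, then 0 without pricing
        irbesartan = DrugAnnotation.neutral("Irbesartan", price_band=PriceBand.VERY_LOW)
        analysis = secondary_analysis([irbesartan])
        assert analysis.primary.total("Irbesartan") == 2
        assert analysis.no_pricing.total("Irbesartan") == 0
        assert analysis.dropped_from_shortlist == ["Irbesartan"]

    def test_no_pricing_contribution_identical_totals(self):
        ann = DrugAnnotation.neutral("D", immunomod_skin=True)
        analysis = secondary_analysis([ann])
        assert analysis.deltas == {"D": 0}

    def test_pricing_penalty_rises_but_stays_off_shortlist(self):
        ann = DrugAnnotation.neutral("D", price_band=PriceBand.VERY_HIGH)
        analysis = secondary_analysis([ann])
        assert analysis.primary.total("D") == -1
        assert analysis.no_pricing.total("D") == 0
        assert analysis.no_pricing.shortlist == []
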