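"""Hypergeometric over-representation, BH FDR behaviour and the
skin-expression sensitivity comparison."""

import numpy as np
import pytest

from conftest import brute_force_hypergeom_tail
from vhenet.enrichment import (
    compare_enrichments,
    enrich,
    hypergeom_p,
    sensitivity_filter,
    significant,
)
from vhenet.types import AnnotationCollection


class TestHypergeomP:
    def test_k_zero_is_one(self):
        assert hypergeom_p(0, 4, 3, 10) == pytest.approx(1.0)

    def test_full_overlap_closed_form(self):
        # C(4,3)*C(6,0)/C(10,3) = 4/120
        assert hypergeom_p(3, 4, 3, 10) == pytest.approx(4 / 120)

    def test_degenerate_everything(self):
        assert hypergeom_p(5, 5, 5, 5) == pytest.approx(1.0)

    def test_bounds_violation_raises(self):
        with pytest.raises(ValueError):
            hypergeom_p(4, 3, 3, 10)
        with pytest.raises(ValueError):
            hypergeom_p(1, 11, 3, 10)

    @pytest.mark.parametrize(
        "k,K,n,N",
        [
            (k, K, n, N)
            for N in (5, 8, 12)
            for K in (2, N // 2)
            for n in (2, N // 2)
            for k in range(0, min(K, n) + 1)
        ],
    )
    def test_matches_exhaustive_enumeration(self, k, K, n, N):
        assert hypergeom_p(k, K, n, N) == pytest.approx(
            brute_force_hypergeom_tail(k, K, n, N), abs=1e-12
        )


def _random_collection(rng, universe, n_sets=20, min_size=8, max_size=30):
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(min_size, max_size + 1))
        members = rng.choice(universe, size=size, replace=False)
        sets[f"SET{i:03d}"] = frozenset(members.tolist())
    return AnnotationCollection("random", sets)


class TestEnrich:
    def test_planted_set_attains_minimum_q(self):
        rng = np.random.default_rng(42)
        universe = [f"U{i:04d}" for i in range(1000)]
        query = [f"U{i:04d}" for i in range(20)]
        planted = frozenset(query[:15]) | frozenset(universe[500:505])
        collection = _random_collection(rng, np.asarray(universe))
        collection.sets["PLANTED"] = planted
        results = enrich(query, collection, universe)
        assert results[0].set_name == "PLANTED"
        assert results[0].q_value < 0.05
        assert results[0].overlap_k == 15

    def test_disjoint_query_yields_nothing_significant(self):
        collection = AnnotationCollection("c", {"S": {"A", "B"}})
        results = enrich(["X", "Y"], collection, ["A", "B", "X", "Y"])
        assert results == []

    def test_alpha_one_marks_all_tested_sets(self):
        collection = AnnotationCollection("c", {"S1": {"A"}, "S2": {"B"}})
        results = enrich(["A", "B"], collection, ["A", "B", "C"])
        assert len(significant(results, alpha=1.0)) == len(results) == 2

    def test_query_outside_universe_dropped(self):
        collection = AnnotationCollection("c", {"S": {"A", "B"}})
        r_with = enrich(["A", "ZZZ"], collection, ["A", "B", "C"])
        r_without = enrich(["A"], collection, ["A", "B", "C"])
        assert r_with == r_without

    def test_empty_universe_raises(self):
        collection = AnnotationCollection("c", {"S": {"A"}})
        with pytest.raises(ValueError):
            enrich(["A"], collection, [])

    def test_invariant_to_set_order(self):
        universe = [f"U{i}" for i in range(50)]
        s1 = {"S1": set(universe[:10]), "S2": set(universe[5:20]), "S3": set(universe[30:40])}
        c1 = AnnotationCollection("c", s1)
        c2 = AnnotationCollection("c", dict(reversed(list(s1.items()))))
        q = universe[:8]
        assert enrich(q, c1, universe) == enrich(q, c2, universe)

    def test_bh_q_monotone_in_sorted_p(self):
        rng = np.random.default_rng(7)
        universe = np.asarray([f"U{i:03d}" for i in range(200)])
        collection = _random_collection(rng, universe)
        query = rng.choice(universe, size=15, replace=False).tolist()
        results = enrich(query, collection, universe.tolist())
        ordered = sorted(results, key=lambda r: r.p_value)
        qs = [r.q_value for r in ordered]
        assert qs == sorted(qs)
        assert all(r.q_value >= r.p_value for r in results)

    def test_null_simulation_controls_fdr(self):
        # all sets random => every rejection is false; the empirical FDR over
        # replicates must sit within a binomial-style envelope of alpha
        rng = np.random.default_rng(1234)
        universe = np.asarray([f"U{i:03d}" for i in range(200)])
        alpha = 0.05
        n_reps = 400
        fdp = []
        for _ in range(n_reps):
            collection = _random_collection(rng, universe, n_sets=15)
            query = rng.choice(universe, size=15, replace=False).tolist()
            results = enrich(query, collection, universe.tolist(), alpha)
            n_rej = len(significant(results, alpha))
            fdp.append(1.0 if n_rej > 0 else 0.0)
        empirical_fdr = float(np.mean(fdp))
        # 3-sigma binomial envelope around alpha
        envelope = 3 * np.sqrt(alpha * (1 - alpha) / n_reps)
        assert empirical_fdr <= alpha + envelope


class TestSensitivityFilter:
    def test_strict_threshold(self):
        scores = {"A": 3.0, "B": 2.5, "C": 1.0}
        assert sensitivity_filter(["A", "B", "C"], scores, 2.5) == ["A"]

    def test_all_above_is_identity(self):
        scores = {"A": 3.0, "B": 4.0}
        assert sensitivity_filter(["B", "A"], scores) == ["A", "B"]

    def test_missing_scores_treated_below(self):
        assert sensitivity_filter(["A", "B"], {"A": 5.0}) == ["A"]


class TestCompareEnrichments:
    def _results(self, names, q=0.01):
        collection = AnnotationCollection("c", {n: {"A"} for n in names})
        return enrich(["A"], collection, ["A", "B"], alpha=1.0)

    def test_identical_lists_fraction_one(self):
        res = self._results(["S1", "S2"])
        cmp = compare_enrichments(res, res, alpha=1.0)
        assert cmp.fraction_repeated == 1.0
        assert cmp.top_term_preserved_per_category == {"c": True}

    def test_empty_filtered_fraction_zero(self):
        res = self._results(["S1", "S2"])
        cmp = compare_enrichments(res, [], alpha=1.0)
        assert cmp.fraction_repeated == 0.0
        assert cmp.n_significant_filtered == 0

    def test_constructed_84_percent_overlap(self):
        # 42 of 50 significant terms recur after filtering
        full = self._results([f"S{i:02d}" for i in range(50)])
        filtered = self._results([f"S{i:02d}" for i in range(42)])
        cmp = compare_enrichments(full, filtered, alpha=1.0)
        assert cmp.n_significant_full == 50
        assert cmp.n_repeated == 42
        assert cmp.fraction_repeated == pytest.approx(0.84)
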