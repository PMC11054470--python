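"""Target mapping, signature reversal, coverage and candidate merging."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_max_coverage, make_network
from vhenet.datasets import TOP_REVERSAL_DRUGS, candidate_gene_sets, reversal_fixture
from vhenet.repurposing import (
    Provenance,
    ReversalProfile,
    combination_coverage,
    greedy_max_coverage,
    map_targets,
    merge_candidates,
    reversal_profile,
    snp_lookup,
)
from vhenet.types import (
    DEGRecord,
    Direction,
    DrugEffectRow,
    DrugEffectTable,
    EffectDirection,
    EffectKind,
    SNPAssociationTable,
)


def _profile(sets):
    return ReversalProfile(
        reversed_by={d: frozenset(g) for d, g in sets.items()}, justification={}
    )


class TestMapTargets:
    def test_restricted_to_network_genes(self):
        network = make_network([("X", "W")])
        table = DrugEffectTable(
            [
                DrugEffectRow("D", "X", EffectKind.TARGET, EffectDirection.UNKNOWN),
                DrugEffectRow("D", "Y", EffectKind.TARGET, EffectDirection.UNKNOWN),
            ]
        )
        tm = map_targets(network, table)
        assert tm.targets == {"D": frozenset({"X"})}

    def test_no_overlap_gives_empty_map(self):
        network = make_network([("X", "W")])
        table = DrugEffectTable(
            [DrugEffectRow("D", "Z", EffectKind.TARGET, EffectDirection.UNKNOWN)]
        )
        assert map_targets(network, table).n_drugs == 0

    def test_calcitriol_fixture_targets(self):
        degs, table = reversal_fixture()
        network = make_network(
            [], isolated=[d.gene for d in degs]
        )
        tm = map_targets(network, table)
        assert tm.targets["Calcitriol"] == frozenset(
            {"BIRC3", "C1S", "S100A8", "SERPINB3", "SNTB1", "TNC"}
        )
        assert len(tm.targets["Calcitriol"]) == 6


class TestReversalProfile:
    def test_opposite_direction_counts(self):
        degs = [DEGRecord("G", Direction.UP)]
        table = DrugEffectTable(
            [DrugEffectRow("D", "G", EffectKind.EXPRESSION_EFFECT, EffectDirection.DECREASE)]
        )
        assert reversal_profile(degs, table).genes("D") == frozenset({"G"})

    def test_same_direction_drug_dropped(self):
        degs = [DEGRecord("G", Direction.UP)]
        table = DrugEffectTable(
            [DrugEffectRow("D", "G", EffectKind.EXPRESSION_EFFECT, EffectDirection.INCREASE)]
        )
        assert "D" not in reversal_profile(degs, table).drugs

    def test_unknown_direction_never_counts(self):
        degs = [DEGRecord("G", Direction.UP)]
        table = DrugEffectTable(
            [DrugEffectRow("D", "G", EffectKind.EXPRESSION_EFFECT, EffectDirection.UNKNOWN)]
        )
        assert reversal_profile(degs, table).drugs == frozenset()

    @pytest.mark.parametrize("drug", TOP_REVERSAL_DRUGS)
    def test_fixture_reversal_counts_are_eleven(self, drug):
        degs, table = reversal_fixture()
        profile = reversal_profile(degs, table)
        assert len(profile.genes(drug)) == 11

    def test_antisymmetry_under_global_flip(self):
        degs, table = reversal_fixture()
        flipped_degs = [DEGRecord(d.gene, d.direction.opposite) for d in degs]
        flip = {
            EffectDirection.INCREASE: EffectDirection.DECREASE,
            EffectDirection.DECREASE: EffectDirection.INCREASE,
            EffectDirection.UNKNOWN: EffectDirection.UNKNOWN,
        }
        flipped_table = DrugEffectTable(
            [
                DrugEffectRow(r.drug, r.gene, r.kind, flip[r.direction])
                for r in table.rows
            ]
        )
        assert (
            reversal_profile(degs, table).reversed_by
            == reversal_profile(flipped_degs, flipped_table).reversed_by
        )

    @pytest.mark.parametrize("m", [1, 5, 11])
    def test_planted_reversal_recovered_exactly(self, m):
        degs = [
            DEGRecord(f"G{i:02d}", Direction.UP if i % 2 else Direction.DOWN)
            for i in range(20)
        ]
        opposite = {Direction.UP: EffectDirection.DECREASE, Direction.DOWN: EffectDirection.INCREASE}
        same = {Direction.UP: EffectDirection.INCREASE, Direction.DOWN: EffectDirection.DECREASE}
        rows = [
            DrugEffectRow("PLANTED", degs[i].gene, EffectKind.EXPRESSION_EFFECT, opposite[degs[i].direction])
            for i in range(m)
        ]
        # decoy rows that must not leak in: same-direction + off-list genes
        rows += [
            DrugEffectRow("PLANTED", degs[i].gene, EffectKind.EXPRESSION_EFFECT, same[degs[i].direction])
            for i in range(m, min(m + 3, 20))
        ]
        rows.append(
            DrugEffectRow("PLANTED", "OFFLIST", EffectKind.EXPRESSION_EFFECT, EffectDirection.DECREASE)
        )
        profile = reversal_profile(degs, DrugEffectTable(rows))
        assert profile.genes("PLANTED") == frozenset(d.gene for d in degs[:m])


class TestCombinationCoverage:
    def test_top_three_fixture_union_is_23(self):
        degs, table = reversal_fixture()
        profile = reversal_profile(degs, table)
        union, size = combination_coverage(profile, list(TOP_REVERSAL_DRUGS))
        assert size == 23

    def test_pair_union_and_intersection(self):
        degs, table = reversal_fixture()
        profile = reversal_profile(degs, table)
        _, size = combination_coverage(profile, ["Tretinoin", "Cyclosporine"])
        assert size == 17
        inter = profile.genes("Tretinoin") & profile.genes("Cyclosporine")
        assert inter == frozenset({"LAPTM5", "LYZ", "S100A8", "S100A9", "TNC"})

    def test_single_drug_idempotent(self):
        profile = _profile({"D": {"a", "b"}})
        union, size = combination_coverage(profile, ["D"])
        assert union == frozenset({"A", "B"}) or union == frozenset({"a", "b"})
        assert size == 2

    def test_unknown_drug_named_in_error(self):
        profile = _profile({"D": {"a"}})
        with pytest.raises(KeyError, match="NOPE"):
            combination_coverage(profile, ["NOPE"])

    def test_union_dominates_each_member(self):
        profile = _profile({"D1": {"a", "b"}, "D2": {"b", "c", "d"}})
        _, size = combination_coverage(profile, ["D1", "D2"])
        assert size >= max(len(profile.genes(d)) for d in ("D1", "D2"))


class TestGreedyMaxCoverage:
    def test_enumerated_pair_instance(self):
        profile = _profile({"D1": {"a", "b"}, "D2": {"b", "c"}, "D3": {"c"}})
        assert greedy_max_coverage(profile, 2) == ["D1", "D2"]

    def test_k_one_is_argmax_by_size(self):
        profile = _profile({"D1": {"a"}, "D2": {"b", "c"}})
        assert greedy_max_coverage(profile, 1) == ["D2"]

    def test_k_exceeding_drugs_returns_all_useful(self):
        profile = _profile({"D1": {"a"}, "D2": {"b"}})
        assert set(greedy_max_coverage(profile, 10)) == {"D1", "D2"}

    @pytest.mark.parametrize("seed", range(6))
    def test_greedy_within_1_minus_1_over_e_of_optimum(self, seed):
        import random

        rng = random.Random(seed)
        genes = [f"g{i}" for i in range(12)]
        sets = {
            f"D{i}": frozenset(rng.sample(genes, rng.randint(1, 6))) for i in range(8)
        }
        profile = _profile(sets)
        for k in (2, 3):
            picked = greedy_max_coverage(profile, k)
            covered = len(set().union(*(profile.genes(d) for d in picked)))
            optimum = brute_force_max_coverage(sets, k)
            assert covered >= (1 - 1 / 2.718281828459045) * optimum


class TestMergeCandidates:
    def _target_map(self, drugs):
        from vhenet.repurposing import DrugTargetMap

        return DrugTargetMap(
            targets={d: frozenset({"X"}) for d in drugs},
            n_drugs=len(drugs),
            n_main_genes_hit=1 if drugs else 0,
            n_linker_genes_hit=0,
        )

    def test_disjoint_sources(self):
        merged = merge_candidates(self._target_map(["D1"]), _profile({"D2": {"g"}}))
        assert merged.provenance == {"D1": Provenance.TARGET, "D2": Provenance.REVERSAL}

    def test_shared_drug_tagged_both_counted_once(self):
        merged = merge_candidates(self._target_map(["D"]), _profile({"D": {"g"}}))
        assert merged.provenance == {"D": Provenance.BOTH}
        assert len(merged.drugs) == 1

    def test_counts_mirror_union_arithmetic(self):
        # 67 target drugs and 60 reversal drugs sharing 4 -> 123 unique
        targets = [f"T{i:02d}" for i in range(67)]
        reversals = [f"R{i:02d}" for i in range(56)] + targets[:4]
        merged = merge_candidates(
            self._target_map(targets), _profile({d: {"g"} for d in reversals})
        )
        assert len(merged.drugs) == 123
        assert len(merged.with_provenance(Provenance.BOTH)) == 4


class TestSnpLookup:
    def test_empty_pharmacogenomic_table(self):
        snps = SNPAssociationTable([("rs1", 1e-9)])
        assert snp_lookup(snps, []) == []

    def test_significant_snp_matches_drug(self):
        snps = SNPAssociationTable([("rs1", 1e-9), ("rs2", 0.5)])
        assert snp_lookup(snps, [("rs1", "D"), ("rs2", "E")]) == ["D"]

    def test_boundary_p_excluded(self):
        snps = SNPAssociationTable([("rs1", 5e-8)])
        assert snp_lookup(snps, [("rs1", "D")]) == []
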