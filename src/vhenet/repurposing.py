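"""Drug–gene mapping, transcriptomic signature reversal, combination coverage
and candidate merging.

A drug *reverses* a DEG when its expression effect on that gene opposes the
disease direction (disease UP matched by drug DECREASE, disease DOWN by drug
INCREASE); unknown effect directions never count. Candidates arise from two
routes — physically targeting a network gene, or reversing at least one DEG —
and are merged with provenance tags. A greedy maximum-coverage selector
generalizes hand-picking the top drugs by individual reversal count to
combinations that jointly reverse the most DEGs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Sequence, Tuple

from .types import (
    DEGRecord,
    Direction,
    DrugEffectTable,
    EffectDirection,
    EffectKind,
    GeneNetwork,
    NodeRole,
    SNPAssociationTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DrugTargetMap",
    "ReversalProfile",
    "Provenance",
    "CandidateList",
    "map_targets",
    "reversal_profile",
    "combination_coverage",
    "greedy_max_coverage",
    "merge_candidates",
    "snp_lookup",
]

#: Opposition rule for signature reversal.
_REVERSES = {
    (Direction.UP, EffectDirection.DECREASE),
    (Direction.DOWN, EffectDirection.INCREASE),
}


@dataclass
class DrugTargetMap:
    targets: Dict[str, frozenset]  # drug -> network genes physically targeted
    n_drugs: int
    n_main_genes_hit: int
    n_linker_genes_hit: int

    def __post_init__(self) -> None:
        if self.n_drugs != len(self.targets):
            raise ValueError("n_drugs inconsistent with target map")


@dataclass
class ReversalProfile:
    reversed_by: Dict[str, frozenset]  # drug -> DEGs reversed
    justification: Dict[Tuple[str, str], Tuple[Direction, EffectDirection]]

    def genes(self, drug: str) -> frozenset:
        return self.reversed_by[drug]

    @property
    def drugs(self) -> frozenset:
        return frozenset(self.reversed_by)


class Provenance(str, Enum):
    TARGET = "TARGET"
    REVERSAL = "REVERSAL"
    BOTH = "BOTH"


@dataclass
class CandidateList:
    provenance: Dict[str, Provenance]

    @property
    def drugs(self) -> frozenset:
        return frozenset(self.provenance)

    def with_provenance(self, tag: Provenance) -> List[str]:
        return sorted(d for d, p in self.provenance.items() if p is tag)

    def ordered(self) -> List[Tuple[str, Provenance]]:
        order = {Provenance.BOTH: 0, Provenance.TARGET: 1, Provenance.REVERSAL: 2}
        return sorted(self.provenance.items(), key=lambda kv: (order[kv[1]], kv[0]))


def map_targets(network: GeneNetwork, drug_table: DrugEffectTable) -> DrugTargetMap:
    """Restrict physical drug targets to network genes.

    Drugs with no network target are dropped. The summary partitions hit
    genes into main (DEG/QTL seed) vs linker genes.
    """
    targets: Dict[str, set] = {}
    for row in drug_table.of_kind(EffectKind.TARGET):
        if row.gene in network.nodes:
            targets.setdefault(row.drug, set()).add(row.gene)
    hit = set().union(*targets.values()) if targets else set()
    linkers = network.genes_with_role(NodeRole.LINKER)
    return DrugTargetMap(
        targets={d: frozenset(g) for d, g in targets.items()},
        n_drugs=len(targets),
        n_main_genes_hit=len(hit - linkers),
        n_linker_genes_hit=len(hit & linkers),
    )


def reversal_profile(degs: Sequence[DEGRecord], drug_table: DrugEffectTable) -> ReversalProfile:
    """Per-drug sets of DEGs whose expression the drug moves back to normal."""
    disease = {rec.gene: rec.direction for rec in degs}
    reversed_by: Dict[str, set] = {}
    justification = {}
    for row in drug_table.of_kind(EffectKind.EXPRESSION_EFFECT):
        if row.gene not in disease:
            continue
        if (disease[row.gene], row.direction) in _REVERSES:
            reversed_by.setdefault(row.drug, set()).add(row.gene)
            justification[(row.drug, row.gene)] = (disease[row.gene], row.direction)
    return ReversalProfile(
        reversed_by={d: frozenset(g) for d, g in reversed_by.items()},
        justification=justification,
    )


def combination_coverage(profile: ReversalProfile, drugs: Sequence[str]) -> Tuple[frozenset, int]:
    """Union of the listed drugs' reversal sets and its size."""
    union: set = set()
    for drug in drugs:
        if drug not in profile.reversed_by:
            raise KeyError(f"drug not in reversal profile: {drug!r}")
        union |= profile.reversed_by[drug]
    return frozenset(union), len(union)


def greedy_max_coverage(profile: ReversalProfile, k: int) -> List[str]:
    """Greedy maximum-coverage selection of up to ``k`` drugs.

    Repeatedly picks the drug with the largest marginal coverage; ties go to
    the larger total reversal set, then lexicographically. Guarantees the
    classic (1 − 1/e) approximation of the optimal k-drug coverage.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    remaining = dict(profile.reversed_by)
    covered: set = set()
    picked: List[str] = []
    while remaining and len(picked) < k:
        best = min(
            remaining,
            key=lambda d: (-len(remaining[d] - covered), -len(remaining[d]), d),
        )
        if not remaining[best] - covered:
            break
        picked.append(best)
        covered |= remaining.pop(best)
    return picked


def merge_candidates(target_map: DrugTargetMap, profile: ReversalProfile) -> CandidateList:
    """Union of target-route and reversal-route drugs with provenance tags."""
    provenance = {}
    for drug in target_map.targets:
        provenance[drug] = Provenance.TARGET
    for drug in profile.reversed_by:
        provenance[drug] = (
            Provenance.BOTH if drug in provenance else Provenance.REVERSAL
        )
    logger.info(
        "merged %d target drug(s) and %d reversal drug(s) into %d unique candidate(s)",
        target_map.n_drugs,
        len(profile.reversed_by),
        len(provenance),
    )
    return CandidateList(provenance=provenance)


def snp_lookup(
    snps: SNPAssociationTable,
    pharmacogenomic_table: Iterable[Tuple[str, str]],
    threshold: float = 5e-8,
) -> List[str]:
    """Drugs with a pharmacogenomic link to a genome-wide significant SNP.

    Significance is strict (p < threshold); the pharmacogenomic table holds
    (variant, drug) pairs. Returns unique drugs sorted lexicographically.
    """
    hits = set(snps.genome_wide_significant(threshold))
    drugs = {str(drug) for variant, drug in pharmacogenomic_table if str(variant) in hits}
    return sorted(drugs)
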