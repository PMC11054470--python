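"""Seeded synthetic-data generators for every input the pipeline consumes.

The generators target the pipeline's combinatorial structure, not realistic
expression magnitudes: a scale-free (preferential-attachment) interactome
over a synthetic ``G####`` gene namespace, DEG/QTL seed lists with a
configurable fraction of seeds absent from the interactome, tissue-expression
scores with a fixed fraction above the 2.5 filter threshold, drug tables with
*planted* reversal structure (drugs constructed to reverse known DEG subsets,
plus aggravating and off-target decoys), annotation collections with one
planted enriched set, and rubric annotation profiles with known scores.

The default specification mirrors the study's shape constants: 52 DEGs +
3 QTL genes with 9 seeds lacking interaction data, 47 of 78 network genes
above the skin-expression threshold, three planted drugs each reversing 11
DEGs with a 3-drug union of 23. Every generator is a pure function of its
spec (including the seed), so identical specs yield identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import networkx as nx
import numpy as np

from .types import (
    AnnotationCollection,
    DEGRecord,
    Direction,
    DrugAnnotation,
    DrugEffectRow,
    DrugEffectTable,
    EffectDirection,
    EffectKind,
    Interactome,
    PriceBand,
    PracticalIssue,
)

__all__ = [
    "SynthesisSpec",
    "gen_interactome",
    "gen_disease_inputs",
    "gen_expression_scores",
    "gen_drug_tables",
    "gen_annotation_collection",
    "gen_rubric_annotations",
]

#: Default planted reversal windows over DEG-list indices: three drugs of 11
#: genes each whose pairwise overlaps give a 3-drug union of exactly 23.
_DEFAULT_PLANTED = {
    "SYNREV-A": tuple(range(0, 11)),
    "SYNREV-B": tuple(range(6, 17)),
    "SYNREV-C": tuple(range(12, 23)),
}


@dataclass
class SynthesisSpec:
    """All knobs of the synthetic study, with study-shaped defaults."""

    seed: int = 0
    interactome_n: int = 500
    attachment_m: int = 2
    n_degs: int = 52
    n_qtls: int = 3
    n_isolated_seeds: int = 9
    score_threshold: float = 2.5
    score_above_fraction: float = 47 / 78
    planted_reversal: Dict[str, Tuple[int, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_PLANTED)
    )
    n_decoy_drugs: int = 10
    n_target_drugs: int = 8
    annotation_n_sets: int = 30
    planted_set_size: int = 20
    planted_overlap: int = 15

    def __post_init__(self) -> None:
        if self.interactome_n < self.attachment_m + 1:
            raise ValueError("interactome_n must exceed attachment_m")
        if self.n_isolated_seeds > self.n_degs + self.n_qtls:
            raise ValueError("more isolated seeds than seeds")
        if self.n_degs + self.n_qtls > self.interactome_n:
            raise ValueError("seed count exceeds interactome size")
        for drug, idx in self.planted_reversal.items():
            if max(idx, default=-1) >= self.n_degs:
                raise ValueError(f"planted indices for {drug} exceed the DEG list")
        if self.planted_overlap > min(self.planted_set_size, self.n_degs):
            raise ValueError("planted overlap infeasible")

    def rng(self, stream: int) -> np.random.Generator:
        """An independent deterministic stream per generator."""
        return np.random.default_rng([self.seed, stream])


def _symbol(i: int) -> str:
    return f"G{i:04d}"


def gen_interactome(spec: SynthesisSpec) -> Interactome:
    """Scale-free reference interactome via preferential attachment.

    Yields exactly ``m·(n−m)`` edges over symbols ``G0001…``; identical specs
    yield identical edge sets.
    """
    g = nx.barabasi_albert_graph(
        spec.interactome_n, spec.attachment_m, seed=int(spec.rng(1).integers(2**31))
    )
    return Interactome((_symbol(u + 1), _symbol(v + 1)) for u, v in g.edges)


def gen_disease_inputs(
    spec: SynthesisSpec, interactome: Interactome
) -> Tuple[List[DEGRecord], List[str], Dict[str, float]]:
    """DEG table, QTL gene list and tissue-expression scores.

    ``n_isolated_seeds`` of the DEGs use symbols beyond the interactome range
    (no interaction data at all); directions are drawn 50/50 up/down. Scores
    cover interactome ∪ isolated genes with the configured fraction strictly
    above the threshold.
    """
    rng = spec.rng(2)
    nodes = sorted(interactome.nodes)
    n_connected = spec.n_degs + spec.n_qtls - spec.n_isolated_seeds
    chosen = [nodes[i] for i in rng.choice(len(nodes), size=n_connected, replace=False)]
    isolated = [_symbol(spec.interactome_n + 1 + i) for i in range(spec.n_isolated_seeds)]

    deg_genes = sorted(chosen[: spec.n_degs - spec.n_isolated_seeds] + isolated)
    qtl_genes = sorted(chosen[spec.n_degs - spec.n_isolated_seeds :])
    flips = rng.integers(0, 2, size=len(deg_genes))
    degs = [
        DEGRecord(g, Direction.UP if f else Direction.DOWN)
        for g, f in zip(deg_genes, flips)
    ]

    score_genes = sorted(set(nodes) | set(isolated))
    scores = gen_expression_scores(
        score_genes,
        n_above=round(spec.score_above_fraction * len(score_genes)),
        threshold=spec.score_threshold,
        rng=spec.rng(3),
    )
    return degs, qtl_genes, scores


def gen_expression_scores(
    genes: Sequence[str],
    n_above: int,
    threshold: float = 2.5,
    rng: np.random.Generator = None,
) -> Dict[str, float]:
    """Scores with exactly ``n_above`` genes strictly above the threshold."""
    if n_above > len(genes):
        raise ValueError("n_above exceeds gene count")
    rng = rng if rng is not None else np.random.default_rng(0)
    genes = sorted(genes)
    above = set(rng.choice(len(genes), size=n_above, replace=False).tolist())
    scores = {}
    for i, g in enumerate(genes):
        if i in above:
            scores[g] = float(threshold + 0.1 + 2.0 * rng.random())
        else:
            scores[g] = float(max(0.0, threshold - 0.1 - 2.0 * rng.random()))
    return scores


def gen_drug_tables(spec: SynthesisSpec, degs: Sequence[DEGRecord]) -> DrugEffectTable:
    """Drug→gene table with planted reversal structure and decoys.

    Planted drugs get expression-effect rows exactly opposing their chosen
    DEGs; decoy drugs get small reversal sets (1–5 genes), same-direction
    (aggravating) rows and off-list rows; a disjoint drug subset gets
    physical-target rows, some hitting more than three genes.
    """
    if any(len(idx) > len(degs) for idx in spec.planted_reversal.values()):
        raise ValueError("planted count exceeds DEG list")
    rng = spec.rng(4)
    opposite = {
        Direction.UP: EffectDirection.DECREASE,
        Direction.DOWN: EffectDirection.INCREASE,
    }
    same = {
        Direction.UP: EffectDirection.INCREASE,
        Direction.DOWN: EffectDirection.DECREASE,
    }
    rows: List[DrugEffectRow] = []
    for drug in sorted(spec.planted_reversal):
        for i in spec.planted_reversal[drug]:
            rec = degs[i]
            rows.append(
                DrugEffectRow(drug, rec.gene, EffectKind.EXPRESSION_EFFECT, opposite[rec.direction])
            )
    max_decoy_reversal = max(
        1, min(5, min((len(v) for v in spec.planted_reversal.values()), default=5) - 1)
    )
    for d in range(spec.n_decoy_drugs):
        drug = f"SYNDECOY-{d + 1:02d}"
        n_rev = int(rng.integers(1, max_decoy_reversal + 1))
        picks = rng.choice(len(degs), size=min(len(degs), n_rev + 3), replace=False)
        for j, i in enumerate(picks):
            rec = degs[int(i)]
            direction = opposite[rec.direction] if j < n_rev else same[rec.direction]
            rows.append(DrugEffectRow(drug, rec.gene, EffectKind.EXPRESSION_EFFECT, direction))
        rows.append(
            DrugEffectRow(drug, f"G{8000 + d:04d}", EffectKind.EXPRESSION_EFFECT, EffectDirection.DECREASE)
        )
    for d in range(spec.n_target_drugs):
        drug = f"SYNTGT-{d + 1:02d}"
        n_targets = int(rng.integers(1, 7))
        picks = rng.choice(len(degs), size=n_targets, replace=False)
        for i in picks:
            rows.append(
                DrugEffectRow(drug, degs[int(i)].gene, EffectKind.TARGET, EffectDirection.UNKNOWN)
            )
    return DrugEffectTable(rows)


def gen_annotation_collection(
    spec: SynthesisSpec,
    universe: Sequence[str],
    query_genes: Sequence[str],
) -> AnnotationCollection:
    """Random gene sets plus one set planted to be enriched in the query.

    The planted set (``SYN_PLANTED``) holds ``planted_overlap`` query genes
    and ``planted_set_size − planted_overlap`` background genes; the other
    ``annotation_n_sets`` sets are uniform draws from the universe.
    """
    rng = spec.rng(5)
    universe = sorted(set(universe))
    query = sorted(set(query_genes) & set(universe))
    if spec.planted_overlap > len(query):
        raise ValueError("planted overlap exceeds query genes inside the universe")
    background = sorted(set(universe) - set(query))
    planted = set(
        np.asarray(query)[rng.choice(len(query), size=spec.planted_overlap, replace=False)]
    ) | set(
        np.asarray(background)[
            rng.choice(
                len(background),
                size=spec.planted_set_size - spec.planted_overlap,
                replace=False,
            )
        ]
    )
    sets = {"SYN_PLANTED": frozenset(str(g) for g in planted)}
    for i in range(spec.annotation_n_sets):
        size = int(rng.integers(10, 51))
        members = np.asarray(universe)[rng.choice(len(universe), size=size, replace=False)]
        sets[f"SYN_SET_{i + 1:03d}"] = frozenset(str(g) for g in members)
    return AnnotationCollection("synthetic_pathways", sets)


def gen_rubric_annotations(spec: SynthesisSpec) -> List[DrugAnnotation]:
    """A deterministic panel of annotation profiles spanning the rubric.

    Includes an all-neutral drug, a pricing-only drug (positive score solely
    from the very-low-price bonus, which a no-pricing re-analysis drops to
    zero), a maximal-bonus and a maximal-penalty profile, plus seeded random
    profiles.
    """
    rng = spec.rng(6)
    panel = [
        DrugAnnotation.neutral("SYNDRUG-NEUTRAL"),
        DrugAnnotation.neutral("SYNDRUG-PRICING-ONLY", price_band=PriceBand.VERY_LOW),
        DrugAnnotation.neutral(
            "SYNDRUG-BEST",
            immunomod_skin=True,
            n_network_targets=5,
            topical_possible=True,
            who_essential=True,
            price_band=PriceBand.VERY_LOW,
        ),
        DrugAnnotation.neutral(
            "SYNDRUG-WORST",
            price_band=PriceBand.UNAVAILABLE,
            has_atc=False,
            orderable=False,
            direction_clear=False,
            grade3to5_risk=True,
            practical_issue=PracticalIssue.SEVERE,
        ),
    ]
    bands = list(PriceBand)
    issues = list(PracticalIssue)
    for i in range(8):
        panel.append(
            DrugAnnotation.neutral(
                f"SYNDRUG-{i + 1:02d}",
                immunomod_general=bool(rng.integers(2)),
                immunomod_skin=bool(rng.integers(2)),
                n_network_targets=int(rng.integers(0, 8)),
                topical_possible=bool(rng.integers(2)),
                who_essential=bool(rng.integers(2)),
                price_band=bands[int(rng.integers(len(bands)))],
                has_atc=bool(rng.integers(2)),
                orderable=bool(rng.integers(2)),
                direction_clear=bool(rng.integers(2)),
                grade3to5_risk=bool(rng.integers(2)),
                practical_issue=issues[int(rng.integers(len(issues)))],
            )
        )
    return panel
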