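"""End-to-end pipeline orchestration: assemble → topology → cluster →
enrich (four query tiers) → repurpose → rank, with a JSON run manifest.

Each stage writes its artifacts (TSV/JSON) into the output directory; any
stage failure aborts with the stage name, leaving earlier artifacts intact.
Re-running with identical config and inputs is byte-identical for every
TSV/JSON artifact (the wall-clock timestamp is confined to the manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

from . import __version__
from . import io as vio
from .assembly import assemble_network, find_linkers, seeds_from_lists
from .clustering import spectral_partition
from .enrichment import compare_enrichments, enrich, sensitivity_filter, significant
from .ranking import RubricConfig, secondary_analysis
from .repurposing import (
    combination_coverage,
    greedy_max_coverage,
    map_targets,
    merge_candidates,
    reversal_profile,
    snp_lookup,
)
from .topology import compute_centralities, fit_power_law
from .types import EffectKind

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths to all inputs plus the pipeline's thresholds."""

    degs_path: str
    qtls_path: str
    interactome_path: str
    out_dir: str
    interactome_format: str = "SIF"
    gmt_paths: List[str] = field(default_factory=list)
    scores_path: Optional[str] = None
    drug_table_path: Optional[str] = None
    snps_path: Optional[str] = None
    pgx_path: Optional[str] = None
    annotations_path: Optional[str] = None
    hub_fraction: float = 0.10
    alpha: float = 0.05
    skin_threshold: float = 2.5
    gwas_threshold: float = 5e-8
    max_path_len: int = 3
    pricing_enabled: bool = True
    enrichment_universe: str = "collection"  # or a path to a gene list
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.hub_fraction <= 1):
            raise ValueError("hub_fraction out of (0, 1]")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha out of (0, 1]")
        if self.gwas_threshold <= 0 or self.gwas_threshold >= 1:
            raise ValueError("gwas_threshold out of (0, 1)")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_json(payload, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _enrichment_rows(results) -> List[str]:
    header = (
        "category\tset_name\toverlap_k\tset_size_K\tquery_size_n\tuniverse_N"
        "\tp_value\tq_value\toverlap_genes"
    )
    lines = [header]
    for r in results:
        lines.append(
            f"{r.category}\t{r.set_name}\t{r.overlap_k}\t{r.set_size_K}"
            f"\t{r.query_size_n}\t{r.universe_N}\t{r.p_value:.6g}\t{r.q_value:.6g}"
            f"\t{';'.join(r.overlap_genes)}"
        )
    return lines


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "vhenet",
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    started = time.time()

    def stage(name):
        def wrap(fn):
            try:
                counts = fn()
            except Exception as exc:  # abort with stage name, keep artifacts
                raise PipelineError(name, exc) from exc
            manifest["stages"][name] = counts
            logger.info("stage %s: %s", name, counts)

        return wrap

    state: dict = {}

    @stage("assemble")
    def _assemble():
        degs = vio.read_deg_table(config.degs_path)
        qtls = vio.read_gene_list(config.qtls_path)
        interactome = vio.read_edge_list(config.interactome_path, config.interactome_format)
        seeds = seeds_from_lists([d.gene for d in degs], qtls)
        search = find_linkers(seeds, interactome, config.max_path_len)
        network = assemble_network(seeds, search.linkers, interactome)
        state.update(degs=degs, qtls=qtls, network=network, search=search)
        vio.write_network_json(network, out / "network.json")
        vio.write_network_node_table(network, out / "network_nodes.tsv")
        vio.write_edge_list(network, out / "network_edges.sif", "SIF")
        return {
            "n_degs": len(degs),
            "n_qtls": len(qtls),
            "n_linkers": len(search.linkers),
            "n_nodes": network.graph.number_of_nodes(),
            "n_edges": network.graph.number_of_edges(),
            "n_isolated_seeds": len(search.isolated_seeds),
        }

    @stage("topology")
    def _topology():
        report = compute_centralities(state["network"], config.hub_fraction)
        state["report"] = report
        with open(out / "topology.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene\trole\tdegree\tbetweenness\tis_hub\n")
            for g in sorted(report.node_degree):
                fh.write(
                    f"{g}\t{state['network'].roles[g].value}\t{report.node_degree[g]}"
                    f"\t{report.node_betweenness[g]:.6g}\t{str(g in report.hub_nodes).lower()}\n"
                )
        counts = {"n_hub_nodes": len(report.hub_nodes), "n_hub_edges": len(report.hub_edges)}
        try:
            fit = fit_power_law(report)
            counts["power_law_exponent"] = round(fit.exponent, 4)
            counts["power_law_r_squared"] = round(fit.r_squared, 4)
        except ValueError:
            counts["power_law_exponent"] = None
        return counts

    @stage("cluster")
    def _cluster():
        modules = spectral_partition(state["network"])
        state["modules"] = modules
        with open(out / "modules.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene\tmodule_id\n")
            for g in sorted(modules.assignment):
                fh.write(f"{g}\t{modules.assignment[g]}\n")
        _write_json(
            {"modularity_q": modules.modularity_q, "module_sizes": modules.sizes},
            out / "modules_summary.json",
        )
        return {"n_modules": modules.n_modules, "modularity_q": round(modules.modularity_q, 4)}

    @stage("enrich")
    def _enrich():
        if not config.gmt_paths:
            return {"skipped": True}
        collections = [vio.read_gmt(p) for p in config.gmt_paths]
        network = state["network"]
        deg_genes = sorted(d.gene for d in state["degs"])
        tiers = {
            "degs": deg_genes,
            "qtls": sorted(state["qtls"]),
            "network": sorted(network.nodes),
        }
        for module_id in range(state["modules"].n_modules):
            tiers[f"module_{module_id}"] = state["modules"].members(module_id)
        n_sig = {}
        all_lines: Dict[str, List[str]] = {}
        full_network_results = []
        for tier, query in tiers.items():
            for coll in collections:
                universe = (
                    sorted(coll.all_genes)
                    if config.enrichment_universe == "collection"
                    else vio.read_gene_list(config.enrichment_universe)
                )
                results = enrich(query, coll, universe, config.alpha)
                if tier == "network":
                    full_network_results.extend(results)
                lines = all_lines.setdefault(tier, _enrichment_rows([])[:1])
                lines.extend(_enrichment_rows(results)[1:])
                n_sig[tier] = n_sig.get(tier, 0) + len(significant(results, config.alpha))
        for tier, lines in all_lines.items():
            (out / f"enrichment_{tier}.tsv").write_text(
                "\n".join(lines) + "\n", encoding="utf-8"
            )
        counts = {"n_significant": n_sig}
        # Skin-expression sensitivity re-analysis of the whole-network tier.
        if config.scores_path:
            scores = vio.read_expression_scores(config.scores_path)
            kept = sensitivity_filter(state["network"].nodes, scores, config.skin_threshold)
            filtered_results = []
            for coll in collections:
                universe = (
                    sorted(coll.all_genes)
                    if config.enrichment_universe == "collection"
                    else vio.read_gene_list(config.enrichment_universe)
                )
                filtered_results.extend(enrich(kept, coll, universe, config.alpha))
            comparison = compare_enrichments(full_network_results, filtered_results, config.alpha)
            _write_json(
                {
                    "n_genes_kept": len(kept),
                    "n_significant_full": comparison.n_significant_full,
                    "n_significant_filtered": comparison.n_significant_filtered,
                    "n_repeated": comparison.n_repeated,
                    "fraction_repeated": comparison.fraction_repeated,
                    "top_term_preserved_per_category": comparison.top_term_preserved_per_category,
                },
                out / "enrichment_sensitivity.json",
            )
            counts["sensitivity_n_kept"] = len(kept)
            counts["sensitivity_fraction_repeated"] = round(comparison.fraction_repeated, 4)
        return counts

    @stage("repurpose")
    def _repurpose():
        if not config.drug_table_path:
            return {"skipped": True}
        drug_table = vio.read_drug_effect_table(config.drug_table_path)
        network = state["network"]
        degs = state["degs"]
        target_map = map_targets(network, drug_table)
        profile = reversal_profile(degs, drug_table)
        candidates = merge_candidates(target_map, profile)
        state["candidates"] = candidates
        top3 = sorted(
            profile.reversed_by, key=lambda d: (-len(profile.reversed_by[d]), d)
        )[:3]
        _, union_size = combination_coverage(profile, top3) if top3 else (frozenset(), 0)
        greedy3 = greedy_max_coverage(profile, 3) if profile.reversed_by else []
        with open(out / "candidates.tsv", "w", encoding="utf-8") as fh:
            fh.write("drug\tprovenance\tn_targets\tn_reversed\n")
            for drug, prov in candidates.ordered():
                fh.write(
                    f"{drug}\t{prov.value}\t{len(target_map.targets.get(drug, ()))}"
                    f"\t{len(profile.reversed_by.get(drug, ()))}\n"
                )
        # Reversal matrix: drugs x DEGs.
        deg_genes = sorted(d.gene for d in degs)
        with open(out / "reversal_matrix.tsv", "w", encoding="utf-8") as fh:
            fh.write("drug\t" + "\t".join(deg_genes) + "\n")
            effects = {
                (r.drug, r.gene): r.direction
                for r in drug_table.of_kind(EffectKind.EXPRESSION_EFFECT)
            }
            disease = {d.gene: d.direction for d in degs}
            for drug in sorted(profile.reversed_by):
                cells = []
                for g in deg_genes:
                    if g in profile.reversed_by[drug]:
                        cells.append("reverses")
                    elif (drug, g) in effects and effects[(drug, g)] != (
                        None
                    ) and effects[(drug, g)].value != "unknown" and g in disease:
                        cells.append("aggravates")
                    else:
                        cells.append("none")
                fh.write(drug + "\t" + "\t".join(cells) + "\n")
        counts = {
            "n_target_drugs": target_map.n_drugs,
            "n_main_genes_hit": target_map.n_main_genes_hit,
            "n_linker_genes_hit": target_map.n_linker_genes_hit,
            "n_reversal_drugs": len(profile.reversed_by),
            "n_candidates": len(candidates.drugs),
            "top3_by_count": top3,
            "top3_union_coverage": union_size,
            "greedy3": greedy3,
        }
        if config.snps_path and config.pgx_path:
            snps = vio.read_snp_table(config.snps_path)
            pgx_df = vio._read_tsv(config.pgx_path, ["variant", "drug"])
            drugs = snp_lookup(
                snps,
                list(zip(pgx_df["variant"], pgx_df["drug"])),
                config.gwas_threshold,
            )
            counts["pharmacogenomic_drugs"] = drugs
        return counts

    @stage("rank")
    def _rank():
        if not config.annotations_path:
            return {"skipped": True}
        annotations = vio.read_annotation_table(config.annotations_path)
        rubric = RubricConfig(pricing_enabled=config.pricing_enabled)
        analysis = secondary_analysis(annotations, rubric)
        with open(out / "ranking.tsv", "w", encoding="utf-8") as fh:
            fh.write("drug\tscore\tscore_no_pricing\tin_shortlist\n")
            for b in analysis.primary.breakdowns:
                fh.write(
                    f"{b.drug}\t{b.total}\t{analysis.no_pricing.total(b.drug)}"
                    f"\t{str(b.total > 0).lower()}\n"
                )
        _write_json(
            {
                b.drug: {"applied": list(map(list, b.applied)), "total": b.total}
                for b in analysis.primary.breakdowns
            },
            out / "ranking_audit.json",
        )
        return {
            "n_ranked": len(analysis.primary.breakdowns),
            "n_shortlist": len(analysis.primary.shortlist),
            "dropped_without_pricing": analysis.dropped_from_shortlist,
        }

    manifest["runtime_seconds"] = round(time.time() - started, 3)
    _write_json(manifest, out / "manifest.json")
    return manifest
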