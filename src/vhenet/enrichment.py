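"""Over-representation analysis with Benjamini–Hochberg FDR control.

The test statistic is the one-sided (upper-tail) hypergeometric probability —
Fisher's exact upper tail — the default of the standard enrichment tools this
pipeline mirrors. BH correction is applied within each functional category
separately, over all tested sets (sets with zero overlap enter the correction
at p = 1). A skin-expression sensitivity filter (score strictly > 2.5 by
default) supports re-running the analysis on highly expressed network genes
and comparing which significant terms persist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import AnnotationCollection, normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "SensitivityComparison",
    "hypergeom_p",
    "enrich",
    "sensitivity_filter",
    "compare_enrichments",
]


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    set_name: str
    overlap_k: int
    set_size_K: int
    query_size_n: int
    universe_N: int
    p_value: float
    q_value: float
    overlap_genes: tuple

    def __post_init__(self) -> None:
        if self.overlap_k > min(self.set_size_K, self.query_size_n):
            raise ValueError("overlap exceeds set or query size")
        if self.q_value < self.p_value - 1e-12:
            raise ValueError("q-value below p-value")


@dataclass
class SensitivityComparison:
    n_significant_full: int
    n_significant_filtered: int
    n_repeated: int
    fraction_repeated: float
    top_term_preserved_per_category: Dict[str, bool]


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts annotated genes in a draw of ``n`` from a universe of ``N``
    containing ``K`` annotated genes.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query_genes: Iterable[str],
    collection: AnnotationCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> List[EnrichmentResult]:
    """Test every set in the collection for over-representation of the query.

    Query genes outside the universe are dropped with a logged count;
    annotation sets are intersected with the universe. Results cover sets with
    overlap >= 1, sorted by (q, p, set name); significance is q < alpha.
    """
    universe_set = {normalize_symbol(g) for g in universe}
    if not universe_set:
        raise ValueError("empty universe")
    query = {normalize_symbol(g) for g in query_genes}
    dropped = query - universe_set
    if dropped:
        logger.info("dropped %d query gene(s) outside the universe", len(dropped))
    query &= universe_set

    names = sorted(collection.sets)
    p_values = []
    details = []
    for name in names:
        members = collection.sets[name] & universe_set
        overlap = sorted(query & members)
        p = (
            hypergeom_p(len(overlap), len(members), len(query), len(universe_set))
            if members
            else 1.0
        )
        p_values.append(p)
        details.append((name, members, overlap, p))
    if not names:
        return []
    _, q_values, _, _ = multipletests(p_values, method="fdr_bh")

    results = []
    for (name, members, overlap, p), q in zip(details, q_values):
        if not overlap:
            continue
        results.append(
            EnrichmentResult(
                category=collection.category,
                set_name=name,
                overlap_k=len(overlap),
                set_size_K=len(members),
                query_size_n=len(query),
                universe_N=len(universe_set),
                p_value=float(p),
                q_value=float(max(q, p)),
                overlap_genes=tuple(overlap),
            )
        )
    results.sort(key=lambda r: (r.q_value, r.p_value, r.set_name))
    return results


def significant(results: Iterable[EnrichmentResult], alpha: float = 0.05) -> List[EnrichmentResult]:
    return [r for r in results if r.q_value < alpha]


def sensitivity_filter(
    network_genes: Iterable[str],
    scores: Mapping[str, float],
    threshold: float = 2.5,
) -> List[str]:
    """Genes with tissue-expression score strictly above the threshold.

    Genes missing from the score table are treated as below threshold and
    logged.
    """
    genes = sorted({normalize_symbol(g) for g in network_genes})
    scores = {normalize_symbol(g): v for g, v in scores.items()}
    missing = [g for g in genes if g not in scores]
    if missing:
        logger.info("%d gene(s) without expression score treated as below threshold", len(missing))
    return [g for g in genes if scores.get(g, float("-inf")) > threshold]


def compare_enrichments(
    full_results: Sequence[EnrichmentResult],
    filtered_results: Sequence[EnrichmentResult],
    alpha: float = 0.05,
) -> SensitivityComparison:
    """Which significant terms of the full analysis recur after filtering.

    A term is identified by its (category, set name) pair; per category, the
    comparison also reports whether the full analysis's most significant term
    is still significant after filtering.
    """
    sig_full = significant(full_results, alpha)
    sig_filtered = significant(filtered_results, alpha)
    keys_full = {(r.category, r.set_name) for r in sig_full}
    keys_filtered = {(r.category, r.set_name) for r in sig_filtered}
    repeated = keys_full & keys_filtered

    top_preserved = {}
    by_category: Dict[str, List[EnrichmentResult]] = {}
    for r in sig_full:
        by_category.setdefault(r.category, []).append(r)
    for category, results in by_category.items():
        top = min(results, key=lambda r: (r.q_value, r.p_value, r.set_name))
        top_preserved[category] = (category, top.set_name) in keys_filtered

    n_full = len(keys_full)
    return SensitivityComparison(
        n_significant_full=n_full,
        n_significant_filtered=len(keys_filtered),
        n_repeated=len(repeated),
        fraction_repeated=(len(repeated) / n_full) if n_full else 0.0,
        top_term_preserved_per_category=top_preserved,
    )
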