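# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `vhenet`. It describes what the code computes; every number
quoted here is produced by the package's own tests, scripts or CLI.

## Problem setting

Vesicular hand eczema (VHE) is an inflammatory skin disease with few
effective systemic therapies. The pipeline searches for repurposing
candidates by combining two molecular layers — a directed DEG list from a
lesional-vs-healthy skin transcriptome comparison, and QTL genes modulated
by a GWAS risk locus — into a disease gene network, characterizing that
network, and matching approved drugs against it through two routes: physical
drug–gene targets and transcriptomic signature reversal.

## Network assembly

Seeds are the union of DEG and QTL gene lists (a gene in both layers keeps
origin DEG and is counted once). Gene identity is the upper-cased HGNC-style
symbol; no alias resolution is attempted, which keeps the pipeline free of
external ID-mapping services but means inputs must already use consistent
symbols.

The reference interactome is an undirected simple graph read from SIF or
two-column TSV; direction/type labels are retained for display only, and all
topology is computed on the undirected graph. Self-loops are dropped with a
logged count.

**Linker search.** The minimal-connector problem is a Steiner-tree variant,
so an exact solution is exponential; we use a deterministic greedy
approximation:

1. Candidate linkers are non-seed genes within `max_path_len` (default 3)
   interactome hops of at least two seeds.
2. Repeatedly add the candidate that merges the largest number of currently
   distinct seed components (ties: smaller interactome degree, then
   lexicographic order).
3. When no single candidate merges two components but several components
   remain, add the interior genes of a shortest interactome path between two
   components (deterministic BFS order). Without this fallback, seed pairs
   whose only connections pass through two or more consecutive non-seed
   genes could never be joined.
4. Prune: drop any chosen linker whose removal leaves the component count
   unchanged, until the set is setwise-minimal.

Seeds absent from the interactome are reported as isolated and retained in
the assembled network as degree-0 nodes with their seed role; linker genes
are by construction connected. On toy instances the greedy linker count is
checked against a brute-force minimum (all non-seed subsets up to size 4)
and stays within a factor of two of it.

## Topology

Degree is exact. Node and edge betweenness are computed from all-pairs
shortest paths on the undirected simple graph, *unnormalized* (each
unordered node pair contributes one unit, split over its shortest paths), so
values on small graphs equal hand-enumerated path counts; the test suite
checks equality against an explicit path-enumeration oracle on random graphs
up to 9 nodes and exhaustively on all 4-node graphs. Connected components
are handled naturally by the path counting; isolated nodes score 0.

Hubs are the top `hub_fraction` (default 0.10) of nodes by degree and edges
by betweenness, with floor rounding and a minimum of one, ties at the cutoff
broken lexicographically after score. On a 78-node network the floor rule
yields 7 hub genes.

The degree-distribution diagnostic fits log(count) against log(degree) by
least squares over distinct positive degrees and reports exponent = −slope
and r². This is a deliberately simple, pluggable diagnostic for the
qualitative "scale-free" claim, not a maximum-likelihood tail fit; it
requires at least three distinct degrees and raises on (near-)regular
graphs.

## Module clustering

Modules are found with Newman's leading-eigenvector spectral method:
recursive bisection of node groups by the sign pattern of the leading
eigenvector of the generalized modularity matrix
B(g)_ij = A_ij − k_i k_j/2m − δ_ij Σ_{l∈g}(A_il − k_i k_l/2m), keeping a
bisection only if it raises Q by more than 1e-10. Each bisection is followed
by the method's fine-tuning stage — a greedy, deterministic single-node
sweep flipping the node whose side change most increases s^T B s until no
flip helps. Plain sign splitting without this sweep can sever a single
attachment node from an otherwise clean community (observed on a ring of
three 5-cliques, where it costs ≈ 0.08 in Q and a spurious fourth module),
so the sweep is part of the default path rather than an option.

Determinism: nodes are processed in lexicographic order, the eigenvector
sign is fixed by making the entry of the lexicographically smallest group
member non-negative, and initial groups are the connected components (the
modularity matrix carries no signal across components). Isolated nodes carry
no modularity signal and share one dedicated module. On graphs small enough
for exhaustive partition search the returned Q is within 0.05 of the global
optimum (test-enforced).

## Enrichment

Over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k) for X ~ Hypergeom(N, K, n) — the documented default of the
standard enrichment plugins this pipeline mirrors. The universe is
configurable and defaults to all genes of the collection's category, because
no background is canonical and the choice changes p-values materially; query
genes outside the universe are dropped with a logged count.

BH FDR is applied per category over *all* tested sets (zero-overlap sets
enter at p = 1), and results report only sets with overlap ≥ 1, sorted by
(q, p, name). Whether a study-wide correction should instead span categories
is genuinely open; per-category was chosen to mirror how the standard tools
report their term counts, and the scope is confined to one function should a
global variant be needed.

The sensitivity analysis re-runs enrichment on network genes with skin
expression score strictly above 2.5 (strict ">", per the underlying
definition of above-average expression; genes without a score count as below
threshold) and reports the fraction of significant terms that recur plus
whether each category's top term is preserved.

## Drug repurposing

A drug *reverses* a DEG iff its expression effect direction opposes the
disease direction (UP↔DECREASE, DOWN↔INCREASE). UNKNOWN directions never
count — the ranking rubric penalizes unclear directions instead of guessing.
Conflicting increase/decrease reports for the same (drug, gene) collapse to
UNKNOWN with a logged count. Free-text effect vocabulary ("up-regulates",
"represses expression", …) is normalized through a packaged dictionary.

Combination coverage is the plain set union of the selected drugs' reversal
sets. Two selectors are exposed: the fixed recipe (top-k drugs by individual
reversal count), and a greedy maximum-coverage selector (largest marginal
gain; ties to larger total set, then name) carrying the classic (1 − 1/e)
approximation guarantee, test-verified against brute force on small
instances.

Candidates from the target route and the reversal route are merged with
provenance tags (TARGET / REVERSAL / BOTH); the pharmacogenomic lookup joins
genome-wide significant SNPs (strict p < 5 × 10⁻⁸) against a
variant→drug table.

## Ranking rubric

Every criterion's points live in `RubricConfig`, so the rubric is data, not
code. Defaults: immunomodulating efficacy in inflammatory/auto-immune
disease +1, in *skin* disease +2 (mutually exclusive, larger applies — a
skin trial implies the general case, and stacking to +3 would exceed any
published score pattern); > 3 network targets +1; topical application
possible +1; WHO essential medicine +1; price bands very-low (< 50 EUR/yr)
+2, low (50–500, both edges inclusive-low by convention) +1,
very-high (> 20 000) or unavailable −1; no ATC code −2; not orderable −1;
unclear direction −1; 0.1–1 % grade 3–5 adverse-event risk −1; practical
issues −1 or severe practical issues −2 (mutually exclusive, worst applies).

With these defaults the total lies in [−8, +7] (pricing enabled) or
[−7, +5] (disabled), verified by exhaustive enumeration of all annotation
combinations. The shortlist is all drugs with total strictly > 0. The
secondary analysis re-ranks with the three pricing criteria disabled and
reports score deltas and shortlist departures; it is provably identical to
zeroing the pricing points (criterion-masking equivalence is test-enforced).

## Synthetic data

The generators emulate the *shape* of the study's inputs, not biological
realism: no expression magnitudes, no LD structure, no literature curation.
Defaults mirror the study's constants — 52 DEGs + 3 QTL genes with 9 seeds
lacking interaction data; 47/78 of scored genes above the 2.5 threshold;
three planted drugs each reversing 11 DEGs with a three-drug union of 23
(index windows 0–10, 6–16, 12–22); a planted annotation set with 15/20
query overlap against a universe of 500. The interactome is a
preferential-attachment graph (n = 500, m = 2 by default, hence
m·(n−m) edges) over a synthetic `G####` namespace kept disjoint from real
symbols so fixtures cannot silently mix with study data.

Passing tests on these generators demonstrates that the pipeline recovers
planted combinatorial structure under the study's shape constants; it does
not validate the biological conclusions, which depend on curated database
snapshots that are inputs, not computations, here.

## Packaged fixtures

`vhenet/data/candidate_ranking.tsv` holds the published 46-candidate
shortlist (score, medicine group, network gene lists). The DEG fixture
(`vhe_degs_reconstructed.tsv`) is flagged as a *reconstruction*: 23 symbols
recoverable from the three strongest reversal drugs' gene lists, 5 published
isolated input genes, and 24 synthetic `G####` placeholders; directions are
assigned, not published. The drug-effect fixture is derived at load time
from those two tables (each reversal drug's effects set exactly opposite the
fixture DEG directions), which guarantees internal consistency and
reproduces the published coverage arithmetic: 11/11/11 individual reversal
counts, pairwise union 17 with a 5-gene intersection, three-drug union 23.

## Problem sizes and numerical choices

Brute-force oracles bound their instances: betweenness ≤ 9 nodes,
hypergeometric enumeration N ≤ 12, exhaustive modularity ≤ 8 nodes,
coverage ≤ 9 sets, linker search ≤ 4 linkers. Null-FDR simulation uses
1000 replicates with 15 sets over a 200-gene universe; planted-recovery
checks run 100 seeds at reduced sizes (interactome 120–150 nodes). These
sizes make the full suite run in seconds while keeping every oracle exact.

Spectral bisections require ΔQ > 1e-10; eigenvectors come from a dense
symmetric eigensolver, appropriate for networks of this scale (tens to
hundreds of nodes). Betweenness ties, hub cutoffs, greedy selections and
output orderings all have explicit deterministic tie-breaks, and pipeline
artifacts are byte-identical across reruns (wall-clock time appears only in
the manifest).

## Known limitations

- The linker heuristic is not guaranteed minimal (the exact problem is
  NP-hard); it is deterministic and empirically within 2× of brute force on
  small instances.
- The power-law diagnostic is a regression on a log histogram — adequate
  for a qualitative scale-free check, biased as an estimator of the true
  tail exponent.
- Per-category FDR does not control the study-wide error rate across
  categories.
- The rubric encodes curated judgments (trial status, prices, formulary
  fields) as inputs; the package scores them but cannot audit their
  correctness.
- Real interactome snapshots, drug databases and annotation collections are
  not bundled; published counts that depend on those snapshots (unique
  candidate totals, significant-term counts, module compositions, named
  hubs) are therefore covered by property-based guarantees rather than value
  reproduction.
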