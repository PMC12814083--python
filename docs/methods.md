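# Methods

## Scope and model

`kgora` re-prioritizes targets predicted by a knowledge-graph model using
the structure of each prediction's evidence subgraph. The package does not
train or apply graph embeddings, path encoders, or attention scoring; the
upstream neural path score is replaced by a deterministic stand-in (the
product of edge weights along a path), isolated behind `score_path` so an
alternative scorer can be plugged in. Everything downstream of the path
scores — subgraph assembly, enrichment, filtering, contact analysis — is
implemented in full.

## Graph and paths

A knowledge graph is a set of typed nodes (`disease`, `gene`, `compound`,
`pathway_or_GO`) and typed edges with weights in [0, 1] (missing weights
default to 1.0). Metapath enumeration walks the graph treating edges as
*undirected* — relations such as `interacts_with` carry no meaningful
direction here — while each edge keeps its written (source, relation,
target) orientation in the output. Only simple paths (no repeated node) are
admitted, a conservative reading of "exclude redundant paths". Duplicate
node sequences arising from parallel edges collapse to the best-scoring
edge combination. Ordering is deterministic everywhere: score descending,
then lexicographic node-id sequence.

A target's subgraph is the union of its retained paths (top-m by score, or
score ≥ threshold). Its **gene set excludes the target gene itself** by
default: a target that is itself a curated gene must not enrich its own
subgraph. `include_target` / `self_count` flags restore inclusion for
sensitivity analyses.

## Ranking and overlap

`select_top` keeps the k highest-scoring predictions per query (or
⌈fraction·m⌉), breaking boundary ties by target id ascending, and re-ranks
1..k. When both modes are configured, top-k wins. `aggregate_queries`
computes the exact union and per-multiplicity counts of the selected sets.
Percentages are **truncated** (not rounded) to one decimal, via integer
arithmetic — e.g. 1376/2527 reports as 54.4%. Truncation is a deliberate,
documented convention; rounding conventions differ across published
reports, and the choice matters exactly at the last printed digit.

## Enrichment

The background universe is the union of gene sets over the selected
subgraphs that contain at least one curated gene; only those subgraphs are
tested, and the BH family is exactly the tested set. Conventions, all
configurable:

- **n** (curated count in the test) defaults to |curated ∩ background|,
  which keeps the hypergeometric draw inside the background universe; the
  all-curated convention is available (`n_convention="all_curated"`).
- **K** counts subgraph genes *within* the background
  (sampling-without-replacement coherence); the raw subgraph gene count is
  reported alongside (`K_raw`).
- Retention is strict: q < alpha (default 0.05, not ≤) and k ≥ min_overlap
  (default 3).
- Targets predicted by several queries are merged (gene-set union) before
  testing so each target is tested once; `merge_mode="per_query"` keeps
  per-(target, query) subgraphs instead.

The tail probability is computed in log-space from log-gamma binomial
coefficients with a log-sum-exp over at most min(K, n) − k + 1 terms,
clipped to [0, 1]. Boundary cases are exact: k ≤ max(0, n − (N − K))
returns 1.0; k > min(K, n) returns 0.0. Against exact rational enumeration
the implementation agrees to 1e-12 over the full N ≤ 12 grid, and to ~1e-9
relative against an independent library implementation at larger sizes.
BH adjustment is the textbook step-up, q(i) = min over j ≥ i of p(j)·m/j,
clipped at 1 and returned in input order.

## Novelty filter

Rules are data: an ordered list of named predicates over a per-gene
annotation record (boolean flags; a `known_association_sources` tag column
folds into the `known_association` flag). A candidate is excluded by the
first matching rule. The retained set is order-invariant (exclusion is a
union of predicates); only the attribution changes with order. Genes absent
from the annotation table count as unannotated (all flags false) with a
warning, rather than erroring — the table is expected to cover flagged
genes, not the genome.

## Synthetic generators

All generators are pure functions of (config, seed), via
`numpy.random.default_rng`.

- **Graph**: per-relation Bernoulli edge densities over the admissible node
  pairs (disease–gene, gene–gene, gene–pathway, compound–gene), weights
  uniform on [0.2, 1]; every disease node is guaranteed ≥ 1 gene edge.
- **Subgraph collections**: each curated gene enters a planted target's
  gene set with probability p1 = 0.6 and a non-planted one's with
  p0 = 0.05, independently per gene (the simplest alternative matching the
  hypergeometric test); non-curated genes are uniform fill to a size drawn
  from 15–25 over a 400-gene universe. The universe and size range satisfy
  a coherence constraint: mean size / universe = 20/400 = 0.05 = p0, so
  non-planted subgraphs include curated genes at exactly the background
  rate and are genuinely null. Defaults: 200 targets, 20 planted, 14
  curated genes.
- **Null collections** (`generate_null_subgraphs`): gene sets drawn
  uniformly without replacement from a fixed universe — the exact null of
  the test, used for retention-rate calibration.
- **Predictions**: standard-normal scores per query, planted targets
  shifted by `score_shift` (default 3.0, large enough that planted targets
  reliably enter a per-query top-50 of 200).
- **Annotations**: disjoint flag blocks of requested sizes, remainder
  all-false.
- **Complexes**: two chains of single-letter residues with 1–4 heavy atoms
  jittered around uniform residue centres in a 25 Å box — synthetic
  geometry producing a realistic mix of contacting and distant residue
  pairs for oracle tests.

What the generators do *not* emulate: realistic graph topology or scale,
correlated curated-gene co-occurrence (genes enter subgraphs
independently), dependence between a target's score and its subgraph
content, or protein-like stereochemistry. Passing tests therefore
demonstrate correctness of the statistics and plumbing under the declared
sampling model, not performance on real knowledge-graph output.

## Validation sizes

Null calibration runs 2000 collections of 30 subgraphs (universe 300,
sizes 8–20) and checks the pooled retention rate at alpha = 0.05,
min_overlap = 1 against 0.05 + 3·SE; observed rates are far below the
bound because discrete hypergeometric p-values are conservative. Planted
recovery pools 20 collections at the default conditions and requires
sensitivity ≥ 0.8 (observed ≈ 1.0) and false-discovery proportion ≤
0.05 + 3·SE. These sizes keep the full suite under a minute while leaving
Monte-Carlo error well below the margins tested.

## Structure contacts

Heavy atoms are all non-hydrogen/non-deuterium atoms, identified from the
element field with an atom-name fallback. Waters are dropped on load;
alternate locations resolve to highest occupancy, then altloc label order;
multi-model files use model 1 unless another index is requested. Residues
are keyed by (chain, author residue number, insertion code), 1-based as in
the file. The contact cutoff is **inclusive**: a pair at exactly 4.0 Å is
a contact. Distances are plain Euclidean minima over all heavy-atom pairs;
contact maps, density profiles, and catalytic-distance tables are verified
against brute-force all-pairs computation and are rigid-motion invariant to
1e-9. PDB only (no mmCIF) in this version.

## Degenerate inputs and numerical notes

- Empty prediction tables, empty subgraph collections, empty retention
  sets, and a curated set disjoint from all subgraphs raise typed errors
  rather than returning empty results — each terminates the analysis for a
  scientifically meaningful reason.
- BH on an empty vector returns an empty vector; a single p-value is its
  own q-value.
- All output orderings (paths, enrichment rows, candidate lists) are total
  and deterministic, so reruns with the same config and seed are
  byte-identical; output tables carry the config hash and seed.

## Known limitations

- The edge-weight product is a stand-in, not a model of path importance;
  conclusions about *which* paths matter on real platform output require
  the original scorer.
- The Bernoulli planting model cannot represent correlated curated-gene
  modules; power estimates under correlation would differ.
- The novelty filter is only as good as its annotation table; the package
  deliberately performs no live database or literature queries.
- With `n_convention="all_curated"` and curated genes missing from the
  background, the test is conservative (the tail sums over impossible
  overlaps); the default convention avoids this.
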