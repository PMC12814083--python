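"""Seeded generators for study-scale synthetic inputs.

The pipeline's real inputs — a proprietary multi-source knowledge graph,
neural association scores, and curated annotation databases — are emulated
here by pure functions of (config, seed):

* a typed knowledge graph with disease/gene/compound/pathway nodes and the
  four relation families the evidence subgraphs use;
* per-target subgraph gene sets with *planted* enrichment: each curated gene
  enters a planted target's gene set with probability ``p1`` and a
  non-planted target's with probability ``p0`` (independent Bernoulli draws,
  the simplest alternative matching the hypergeometric test), the remainder
  filled uniformly from a fixed gene universe;
* prediction scores with a configurable mean shift for planted targets;
* annotation-flag fixtures with disjoint flag blocks of requested sizes;
* random two-chain protein complexes for the contact-analysis oracle tests.

Defaults are the conditions the analysis is validated under: 200 targets of
which 20 are planted, a 14-gene curated set, p1 = 0.6 vs p0 = 0.05, and
subgraph gene counts of 15-25 over a 400-gene universe.  The universe and
size range are chosen so the mean subgraph size over the universe equals
p0 (20/400 = 0.05): non-planted subgraphs then include curated genes at
exactly the background rate, i.e. they are genuinely null rather than
weakly enriched, which is what ``p0`` is meant to encode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import Residue, StructureModel
from .kg import EntityNode, KnowledgeGraph, Subgraph, TypedEdge, write_subgraphs
from .novelty import FLAG_COLUMNS


class ConfigError(ValueError):
    """A generator configuration is infeasible."""


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    # graph generation
    n_diseases: int = 3
    n_genes: int = 120
    n_compounds: int = 30
    n_pathways: int = 25
    edge_density: dict[str, float] = field(
        default_factory=lambda: {
            "associated_with": 0.08,   # disease - gene
            "interacts_with": 0.03,    # gene - gene
            "participates_in": 0.05,   # gene - pathway
            "targets": 0.04,           # compound - gene
        }
    )
    # subgraph collection
    n_targets: int = 200
    n_planted: int = 20
    curated_size: int = 14
    p1: float = 0.6
    p0: float = 0.05
    gene_universe: int = 400
    subgraph_size_range: tuple[int, int] = (15, 25)
    # predictions
    queries: tuple[str, ...] = ("DQ1", "DQ2", "DQ3")
    score_shift: float = 3.0

    def __post_init__(self) -> None:
        for p in (self.p0, self.p1):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"inclusion probability out of [0,1]: {p}")
        if self.n_planted > self.n_targets:
            raise ConfigError("n_planted exceeds n_targets")
        if self.curated_size > self.gene_universe:
            raise ConfigError("curated_size exceeds gene universe")
        lo, hi = self.subgraph_size_range
        if not (0 < lo <= hi):
            raise ConfigError(f"bad subgraph size range {self.subgraph_size_range}")
        for rel, dens in self.edge_density.items():
            if not 0.0 <= dens <= 1.0:
                raise ConfigError(f"edge density for {rel!r} out of [0,1]: {dens}")
        if min(self.n_diseases, self.n_genes, self.n_compounds, self.n_pathways) < 1:
            raise ConfigError("node counts must be positive")


@dataclass(frozen=True)
class GroundTruth:
    planted_target_ids: frozenset[str]
    curated_gene_ids: frozenset[str]
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "planted_target_ids": sorted(self.planted_target_ids),
                    "curated_gene_ids": sorted(self.curated_gene_ids),
                    "params": self.params,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def _ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def generate_graph(config: SynthConfig = SynthConfig()) -> KnowledgeGraph:
    """Random typed graph with the four relation families.

    Each relation's density is the Bernoulli probability of each admissible
    node pair carrying an edge; edge weights are uniform on [0.2, 1].  Every
    disease node is guaranteed at least one gene association so queries are
    connected.
    """
    rng = np.random.default_rng(config.seed)
    diseases = _ids("D", config.n_diseases)
    genes = _ids("G", config.n_genes)
    compounds = _ids("C", config.n_compounds)
    pathways = _ids("P", config.n_pathways)
    nodes = (
        [EntityNode(i, "disease", f"disease {i}") for i in diseases]
        + [EntityNode(i, "gene", f"gene {i}") for i in genes]
        + [EntityNode(i, "compound", f"compound {i}") for i in compounds]
        + [EntityNode(i, "pathway_or_GO", f"pathway {i}") for i in pathways]
    )

    def weight() -> float:
        return float(np.round(rng.uniform(0.2, 1.0), 6))

    edges: list[TypedEdge] = []
    pair_families = [
        ("associated_with", diseases, genes),
        ("interacts_with", genes, genes),
        ("participates_in", genes, pathways),
        ("targets", compounds, genes),
    ]
    for relation, left, right in pair_families:
        density = config.edge_density.get(relation, 0.0)
        for i, u in enumerate(left):
            for j, v in enumerate(right):
                if u == v or (relation == "interacts_with" and j <= i):
                    continue
                if rng.random() < density:
                    edges.append(TypedEdge(u, relation, v, weight()))
    # connectivity guarantee for query nodes
    linked = {e.source for e in edges if e.relation == "associated_with"}
    for d in diseases:
        if d not in linked and config.edge_density.get("associated_with", 0.0) > 0:
            g = genes[int(rng.integers(len(genes)))]
            edges.append(TypedEdge(d, "associated_with", g, weight()))
    return KnowledgeGraph(nodes, edges)


def generate_subgraph_collection(
    config: SynthConfig = SynthConfig(),
) -> tuple[list[Subgraph], GroundTruth]:
    """Per-target gene sets with planted curated-gene enrichment.

    Targets are gene entities distinct from the background universe; the
    first ``n_planted`` (by shuffled order) are the planted set.  Curated
    genes enter via independent Bernoulli(p1/p0) draws; non-curated genes are
    a uniform sample topping the set up to its drawn size.
    """
    rng = np.random.default_rng(config.seed)
    universe = np.array(_ids("G", config.gene_universe))
    curated = frozenset(rng.choice(universe, size=config.curated_size, replace=False))
    non_curated = np.array(sorted(set(universe) - curated))
    targets = _ids("T", config.n_targets)
    planted = frozenset(rng.choice(targets, size=config.n_planted, replace=False))
    lo, hi = config.subgraph_size_range
    curated_arr = np.array(sorted(curated))

    subgraphs = []
    query_id = config.queries[0]
    for target in targets:
        p = config.p1 if target in planted else config.p0
        included = curated_arr[rng.random(len(curated_arr)) < p]
        size = int(rng.integers(lo, hi + 1))
        n_fill = max(0, size - len(included))
        fill = rng.choice(non_curated, size=min(n_fill, len(non_curated)), replace=False)
        gene_set = frozenset(included) | frozenset(fill)
        subgraphs.append(
            Subgraph(
                target_id=target,
                query_id=query_id,
                node_ids=frozenset({query_id, target}) | gene_set,
                edge_refs=frozenset(),
                gene_set=gene_set,
            )
        )
    truth = GroundTruth(
        planted_target_ids=planted,
        curated_gene_ids=curated,
        params={
            "seed": config.seed,
            "n_targets": config.n_targets,
            "n_planted": config.n_planted,
            "curated_size": config.curated_size,
            "p1": config.p1,
            "p0": config.p0,
            "gene_universe": config.gene_universe,
            "subgraph_size_range": list(config.subgraph_size_range),
        },
    )
    return subgraphs, truth


def generate_null_subgraphs(
    n_targets: int,
    universe_size: int,
    size_range: tuple[int, int],
    seed: int,
    query_id: str = "DQ1",
) -> list[Subgraph]:
    """Gene sets drawn uniformly without replacement from a fixed universe.

    This is the exact null of the hypergeometric test (no planted structure),
    used for retention-rate calibration.
    """
    rng = np.random.default_rng(seed)
    universe = np.array(_ids("G", universe_size))
    lo, hi = size_range
    if not (0 < lo <= hi <= universe_size):
        raise ConfigError("size range infeasible for universe")
    out = []
    for target in _ids("T", n_targets):
        size = int(rng.integers(lo, hi + 1))
        gene_set = frozenset(rng.choice(universe, size=size, replace=False))
        out.append(
            Subgraph(
                target_id=target,
                query_id=query_id,
                node_ids=frozenset({query_id, target}) | gene_set,
                edge_refs=frozenset(),
                gene_set=gene_set,
            )
        )
    return out


def generate_predictions(
    config: SynthConfig,
    ground_truth: GroundTruth,
) -> pd.DataFrame:
    """Per-query association scores: N(0,1) baseline, planted shifted up.

    Noise is independent across queries, so per-query rankings differ while
    planted targets stay near the top whenever ``score_shift`` is large.
    """
    rng = np.random.default_rng(config.seed + 1)
    targets = _ids("T", config.n_targets)
    planted = ground_truth.planted_target_ids
    rows = []
    for query in config.queries:
        base = rng.standard_normal(len(targets))
        for target, score in zip(targets, base):
            if target in planted:
                score += config.score_shift
            rows.append({"query_id": query, "target_id": target, "score": float(score)})
    return pd.DataFrame(rows, columns=["query_id", "target_id", "score"])


def generate_annotation_fixture(
    n_candidates: int,
    counts_per_rule: dict[str, int],
    seed: int = 0,
    candidate_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Disjoint flag blocks of requested sizes; remainder all-false.

    Returns a table indexed by gene_id with one boolean column per flag in
    :data:`kgora.novelty.FLAG_COLUMNS` (rule names must be among them).
    """
    total = sum(counts_per_rule.values())
    if total > n_candidates:
        raise ConfigError(
            f"requested {total} flagged candidates but only {n_candidates} exist"
        )
    unknown = set(counts_per_rule) - set(FLAG_COLUMNS)
    if unknown:
        raise ConfigError(f"unknown flag column(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    if candidate_ids is None:
        candidate_ids = _ids("T", n_candidates)
    elif len(candidate_ids) != n_candidates:
        raise ConfigError("candidate_ids length must equal n_candidates")
    order = rng.permutation(n_candidates)
    table = pd.DataFrame(
        False, index=pd.Index(candidate_ids, name="gene_id"), columns=list(FLAG_COLUMNS)
    )
    pos = 0
    for rule in FLAG_COLUMNS:
        count = counts_per_rule.get(rule, 0)
        chosen = [candidate_ids[i] for i in order[pos : pos + count]]
        table.loc[chosen, rule] = True
        pos += count
    return table


def generate_complex(
    n_res_a: int,
    n_res_b: int,
    seed: int = 0,
    atoms_per_residue: tuple[int, int] = (1, 4),
    box: float = 25.0,
) -> StructureModel:
    """Random two-chain complex (chains A, B) with heavy atoms in a box.

    Residue centres are uniform in a cube of side ``box`` Å with atoms
    jittered around them, so nearby residues across chains produce contacts
    at typical cutoffs.  Purely synthetic geometry for oracle testing.
    """
    rng = np.random.default_rng(seed)
    lo, hi = atoms_per_residue

    def make_chain(n: int) -> tuple[Residue, ...]:
        residues = []
        for i in range(1, n + 1):
            center = rng.uniform(0, box, size=3)
            n_atoms = int(rng.integers(lo, hi + 1))
            coords = np.round(center + rng.normal(scale=1.0, size=(n_atoms, 3)), 3)
            residues.append(
                Residue(
                    number=i,
                    icode="",
                    name="GLY",
                    atom_names=tuple(f"C{j}" if j else "CA" for j in range(n_atoms)),
                    coords=coords,
                )
            )
        return tuple(residues)

    return StructureModel(chains={"A": make_chain(n_res_a), "B": make_chain(n_res_b)})


def write_fixture_set(config: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full synthetic input bundle and return the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "nodes": outdir / "nodes.tsv",
        "edges": outdir / "edges.tsv",
        "predictions": outdir / "predictions.tsv",
        "subgraphs": outdir / "subgraphs.jsonl",
        "curated": outdir / "curated.gmt",
        "annotations": outdir / "annotations.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    graph = generate_graph(config)
    graph.write(paths["nodes"], paths["edges"])
    subgraphs, truth = generate_subgraph_collection(config)
    write_subgraphs(subgraphs, paths["subgraphs"])
    predictions = generate_predictions(config, truth)
    predictions.to_csv(paths["predictions"], sep="\t", index=False)
    with open(paths["curated"], "w") as fh:
        fh.write(
            "curated_disease_genes\tsynthetic curated set\t"
            + "\t".join(sorted(truth.curated_gene_ids))
            + "\n"
        )
    annotations = generate_annotation_fixture(
        config.n_targets,
        {"known_association": 15, "drug_dev_activity": 7, "prior_disease_link": 47}
        if config.n_targets >= 74
        else {},
        seed=config.seed + 2,
        candidate_ids=_ids("T", config.n_targets),
    )
    annotations.reset_index().to_csv(paths["annotations"], sep="\t", index=False)
    truth.to_json(paths["ground_truth"])
    return paths
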