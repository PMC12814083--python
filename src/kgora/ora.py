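"""Subgraph-level over-representation analysis with a graph-derived background.

Each predicted target carries an evidence subgraph whose gene members can be
tested for over-representation of a small curated disease gene set.  The
background universe is not the whole genome but the union of genes appearing
in the qualifying subgraphs themselves (those of the top-selected targets
that contain at least one curated gene) — so the test asks whether a
subgraph is enriched relative to the gene content of its peer subgraphs.

For a subgraph holding K background genes, with n curated genes among the N
background genes, the probability of observing at least k curated genes is
the upper hypergeometric tail

    P(X >= k) = sum_{i=k}^{min(K,n)} C(K,i) C(N-K, n-i) / C(N,n),

computed here in log-space from log-gamma binomial coefficients.  P-values
are corrected across the tested family with the Benjamini-Hochberg step-up,
and a subgraph is retained when q < alpha (strict) and k >= min_overlap.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .kg import Subgraph


class EmptyBackgroundError(ValueError):
    """No subgraph contains any curated gene; the analysis cannot proceed."""


@dataclass(frozen=True)
class CuratedGeneSet:
    """Expert-curated reference genes defining disease-relevant context."""

    name: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("curated gene set must be non-empty")

    @classmethod
    def from_gmt(cls, path: str | Path) -> "CuratedGeneSet":
        """First record of a GMT file: name <tab> description <tab> genes..."""
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError("GMT record needs name, description, >=1 gene")
                return cls(name=fields[0], gene_ids=frozenset(fields[2:]))
        raise ValueError(f"no GMT record found in {path}")

    @classmethod
    def from_list(cls, path: str | Path, name: str = "curated") -> "CuratedGeneSet":
        with open(path) as fh:
            genes = frozenset(g.strip() for g in fh if g.strip())
        return cls(name=name, gene_ids=genes)


@dataclass(frozen=True)
class BackgroundSet:
    gene_ids: frozenset[str]
    source_subgraph_ids: tuple[str, ...]


@dataclass(frozen=True)
class OraConfig:
    """Thresholds and conventions for the enrichment run.

    ``n_convention`` controls the curated-set size n entering the test:
    ``curated_in_background`` (default) uses |curated ∩ background|, which
    keeps the hypergeometric draw inside the background universe;
    ``all_curated`` uses the full curated set size.  ``self_count`` adds the
    target gene itself to its subgraph gene set before testing.
    """

    alpha: float = 0.05
    min_overlap: int = 3
    n_convention: str = "curated_in_background"
    self_count: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.n_convention not in ("curated_in_background", "all_curated"):
            raise ValueError(f"unknown n_convention {self.n_convention!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-target enrichment record.

    K is the subgraph gene count within the background (``K_raw`` the raw
    subgraph gene count), k the overlap with the curated set, n the curated
    count used in the test, N the background size.
    """

    target_id: str
    K: int
    k: int
    n: int
    N: int
    p_value: float
    q_value: float
    overlap_gene_ids: frozenset[str] = field(default_factory=frozenset)
    retained: bool = False
    K_raw: int = 0


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) of Hypergeometric(N, K, n), in log-space.

    X counts curated genes among the K subgraph genes when n of the N
    background genes are curated.  Exact at the boundaries: k <= 0 (or a k
    every draw must reach) gives 1.0, k > min(K, n) gives 0.0.
    """
    if k < 0 or K < 0 or n < 0 or N < 0:
        raise ValueError("hypergeometric parameters must be non-negative")
    if K > N or n > N:
        raise ValueError(f"need K <= N and n <= N, got k={k}, K={K}, n={n}, N={N}")
    hi = min(K, n)
    lo_forced = max(0, n - (N - K))  # minimum overlap any draw can have
    if k <= lo_forced:
        return 1.0
    if k > hi:
        return 0.0
    i = np.arange(k, hi + 1)
    log_terms = (
        _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    )
    # log-sum-exp over at most hi-k+1 terms
    m = log_terms.max()
    tail = float(np.exp(m) * np.exp(log_terms - m).sum())
    return min(max(tail, 0.0), 1.0)


def _log_comb(a, b):
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def build_background(
    subgraphs: Sequence[Subgraph],
    curated: CuratedGeneSet,
    *,
    self_count: bool = False,
) -> BackgroundSet:
    """Union of gene sets over subgraphs containing >= 1 curated gene."""
    genes: set[str] = set()
    sources: list[str] = []
    for sg in subgraphs:
        gene_set = _effective_genes(sg, self_count)
        if gene_set & curated.gene_ids:
            genes |= gene_set
            sources.append(sg.target_id)
    if not sources:
        raise EmptyBackgroundError(
            "no subgraph contains a curated gene; background is empty"
        )
    return BackgroundSet(gene_ids=frozenset(genes), source_subgraph_ids=tuple(sources))


def _effective_genes(sg: Subgraph, self_count: bool) -> frozenset[str]:
    if self_count:
        return sg.gene_set | {sg.target_id}
    return sg.gene_set


def run_subgraph_ora(
    subgraphs: Sequence[Subgraph],
    curated: CuratedGeneSet,
    config: OraConfig = OraConfig(),
    background: BackgroundSet | None = None,
) -> list[EnrichmentResult]:
    """Test every subgraph containing >= 1 curated gene against the background.

    The background defaults to the union of gene sets over the qualifying
    subgraphs themselves; a precomputed :class:`BackgroundSet` (e.g. built
    from a wider subgraph collection) may be supplied instead.  The FDR
    family is exactly the tested subgraphs.  Results are sorted by
    (q ascending, target_id ascending).
    """
    if not subgraphs:
        raise ValueError("empty subgraph collection")
    if background is None:
        background = build_background(subgraphs, curated, self_count=config.self_count)
    bg = background.gene_ids
    N = len(bg)
    if config.n_convention == "curated_in_background":
        n = len(curated.gene_ids & bg)
    else:
        n = len(curated.gene_ids)

    tested: list[tuple[Subgraph, frozenset[str], frozenset[str]]] = []
    for sg in subgraphs:
        genes = _effective_genes(sg, config.self_count)
        overlap = genes & curated.gene_ids
        if overlap:
            tested.append((sg, genes, frozenset(overlap)))

    p_values = []
    for sg, genes, overlap in tested:
        K = len(genes & bg)
        p_values.append(hypergeom_tail(len(overlap), K, n, N))
    q_values = bh_adjust(p_values)

    results = []
    for (sg, genes, overlap), p, q in zip(tested, p_values, q_values):
        k = len(overlap)
        retained = bool(q < config.alpha and k >= config.min_overlap)
        results.append(
            EnrichmentResult(
                target_id=sg.target_id,
                K=len(genes & bg),
                k=k,
                n=n,
                N=N,
                p_value=float(p),
                q_value=float(q),
                overlap_gene_ids=overlap,
                retained=retained,
                K_raw=len(genes),
            )
        )
    results.sort(key=lambda r: (r.q_value, r.target_id))
    return results


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "target_id": r.target_id,
            "K": r.K,
            "k": r.k,
            "n": r.n,
            "N": r.N,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "overlap_genes": ";".join(sorted(r.overlap_gene_ids)),
            "retained": r.retained,
            "K_raw": r.K_raw,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "target_id", "K", "k", "n", "N",
            "p_value", "q_value", "overlap_genes", "retained", "K_raw",
        ],
    )


def write_results(
    results: Sequence[EnrichmentResult],
    path: str | Path,
    config: OraConfig | None = None,
) -> None:
    """TSV of per-target results; config echo as a JSON sidecar if given."""
    frame = results_to_frame(results)
    frame.to_csv(path, sep="\t", index=False)
    if config is not None:
        import json

        meta = {
            "alpha": config.alpha,
            "min_overlap": config.min_overlap,
            "n_convention": config.n_convention,
            "self_count": config.self_count,
            "n_tested": len(results),
            "n_retained": int(frame["retained"].sum()) if len(frame) else 0,
        }
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
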