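"""Full-analysis orchestration: rank -> restrict -> ORA -> novelty filter -> report.

Stages mirror the target-discovery workflow: per-query top-k selection of
predicted targets, multi-query union accounting, merging of per-query
evidence subgraphs per target, subgraph-level over-representation analysis
against the curated gene set, and the ordered novelty/safety exclusion
chain.  Every output table carries the config hash and seed so any reported
number can be recomputed from the persisted intermediates.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .kg import Subgraph, read_subgraphs
from .novelty import (
    DEFAULT_RULES,
    FilterRule,
    apply_filter_chain,
    decisions_to_frame,
    load_annotations,
    summarize_exclusions,
)
from .ora import CuratedGeneSet, OraConfig, results_to_frame, run_subgraph_ora
from .ranking import VennSummary, aggregate_queries, load_predictions, select_top

logger = logging.getLogger("kgora")


class ConfigValidationError(ValueError):
    """The run configuration is malformed or contradictory."""


_KNOWN_KEYS = {
    "predictions", "subgraphs", "curated", "annotations",
    "queries", "top_k", "top_fraction", "alpha", "min_overlap",
    "n_convention", "self_count", "merge_mode", "seed", "outdir",
    "filter_rules",
}


@dataclass(frozen=True)
class RunConfig:
    predictions: str
    subgraphs: str
    curated: str
    annotations: str
    outdir: str
    queries: tuple[str, ...]
    top_k: int | None = 1500
    top_fraction: float | None = None
    alpha: float = 0.05
    min_overlap: int = 3
    n_convention: str = "curated_in_background"
    self_count: bool = False
    merge_mode: str = "union"  # or "per_query"
    seed: int = 0
    filter_rules: tuple[str, ...] = tuple(r.name for r in DEFAULT_RULES)

    def ora_config(self) -> OraConfig:
        return OraConfig(
            alpha=self.alpha,
            min_overlap=self.min_overlap,
            n_convention=self.n_convention,
            self_count=self.self_count,
        )

    def config_hash(self) -> str:
        # outdir is excluded: where results land does not change what they are
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def validate_config(raw: dict) -> RunConfig:
    """Fill defaults, reject unknown keys and out-of-range values."""
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigValidationError(f"unknown config key(s): {sorted(unknown)}")
    for required in ("predictions", "subgraphs", "curated", "annotations", "outdir"):
        if required not in raw:
            raise ConfigValidationError(f"missing required config key {required!r}")
    queries = tuple(raw.get("queries", ()))
    if not queries:
        raise ConfigValidationError("config must list at least one query id")
    alpha = float(raw.get("alpha", 0.05))
    if not 0.0 < alpha < 1.0:
        raise ConfigValidationError(f"alpha must be in (0,1), got {alpha}")
    min_overlap = int(raw.get("min_overlap", 3))
    if min_overlap < 1:
        raise ConfigValidationError("min_overlap must be >= 1")
    top_k = raw.get("top_k")
    top_fraction = raw.get("top_fraction")
    if top_k is not None and top_fraction is not None:
        logger.warning("both top_k and top_fraction set; top_k takes precedence")
        top_fraction = None
    if top_k is None and top_fraction is None:
        top_k = 1500
    if top_fraction is not None and not 0.0 < float(top_fraction) <= 1.0:
        raise ConfigValidationError("top_fraction must be in (0,1]")
    if top_k is not None and int(top_k) < 1:
        raise ConfigValidationError("top_k must be >= 1")
    merge_mode = raw.get("merge_mode", "union")
    if merge_mode not in ("union", "per_query"):
        raise ConfigValidationError(f"unknown merge_mode {merge_mode!r}")
    n_convention = raw.get("n_convention", "curated_in_background")
    if n_convention not in ("curated_in_background", "all_curated"):
        raise ConfigValidationError(f"unknown n_convention {n_convention!r}")
    return RunConfig(
        predictions=str(raw["predictions"]),
        subgraphs=str(raw["subgraphs"]),
        curated=str(raw["curated"]),
        annotations=str(raw["annotations"]),
        outdir=str(raw["outdir"]),
        queries=tuple(str(q) for q in queries),
        top_k=int(top_k) if top_k is not None else None,
        top_fraction=float(top_fraction) if top_fraction is not None else None,
        alpha=alpha,
        min_overlap=min_overlap,
        n_convention=n_convention,
        self_count=bool(raw.get("self_count", False)),
        merge_mode=merge_mode,
        seed=int(raw.get("seed", 0)),
        filter_rules=tuple(raw.get("filter_rules", (r.name for r in DEFAULT_RULES))),
    )


def load_config(path: str | Path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigValidationError("config document must be a mapping")
    return validate_config(raw)


@dataclass
class RunReport:
    venn: VennSummary
    enrichment: pd.DataFrame
    decisions: pd.DataFrame
    final_candidates: list[str]
    exclusion_summary: dict[str, int]
    config: RunConfig
    stage_seconds: dict[str, float] = field(default_factory=dict)
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": asdict(self.config),
            "config_hash": self.config.config_hash(),
            "venn": self.venn.to_dict(),
            "n_tested": int(len(self.enrichment)),
            "n_ora_retained": int(self.enrichment["retained"].sum())
            if len(self.enrichment)
            else 0,
            "exclusion_summary": self.exclusion_summary,
            "final_candidates": list(self.final_candidates),
            "stage_seconds": self.stage_seconds,
        }


def merge_subgraphs_per_target(subgraphs: list[Subgraph]) -> list[Subgraph]:
    """Union per-query subgraphs of the same target so it is tested once."""
    merged: dict[str, Subgraph] = {}
    for sg in subgraphs:
        prev = merged.get(sg.target_id)
        if prev is None:
            merged[sg.target_id] = sg
        else:
            merged[sg.target_id] = Subgraph(
                target_id=sg.target_id,
                query_id=prev.query_id if prev.query_id == sg.query_id else "merged",
                node_ids=prev.node_ids | sg.node_ids,
                edge_refs=prev.edge_refs | sg.edge_refs,
                gene_set=prev.gene_set | sg.gene_set,
            )
    return [merged[t] for t in sorted(merged)]


def _stamp(frame: pd.DataFrame, path: Path, config: RunConfig) -> None:
    """Write a TSV with a provenance comment header."""
    with open(path, "w") as fh:
        fh.write(f"# kgora {__version__} config_hash={config.config_hash()} seed={config.seed}\n")
        frame.to_csv(fh, sep="\t", index=False)


def run_all(config: RunConfig) -> RunReport:
    """Execute every stage and persist all intermediate and final tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name: str):
        logger.info("=== stage: %s ===", name)
        return _StageTimer(name, timings)

    try:
        with stage("rank"):
            predictions = load_predictions(config.predictions)
            predictions = predictions[predictions["query_id"].isin(config.queries)]
            if predictions.empty:
                raise ConfigValidationError(
                    f"no predictions for queries {list(config.queries)}"
                )
            if config.top_k is not None:
                selected = select_top(predictions, "top_k", config.top_k)
            else:
                selected = select_top(predictions, "top_fraction", config.top_fraction)
            _stamp(selected, outdir / "selected.tsv", config)
            per_query_sets = {
                q: set(g["target_id"])
                for q, g in selected.groupby("query_id", sort=True)
            }
            venn = aggregate_queries(per_query_sets)
            venn.to_json(outdir / "venn.json")
            selected_targets = set(selected["target_id"])

        with stage("restrict"):
            all_subgraphs = read_subgraphs(config.subgraphs)
            restricted = [sg for sg in all_subgraphs if sg.target_id in selected_targets]
            if config.merge_mode == "union":
                restricted = merge_subgraphs_per_target(restricted)

        with stage("ora"):
            curated = _load_curated(config.curated)
            results = run_subgraph_ora(restricted, curated, config.ora_config())
            enrichment = results_to_frame(results)
            _stamp(enrichment, outdir / "enrichment.tsv", config)
            retained_targets = [r.target_id for r in results if r.retained]

        with stage("novelty"):
            annotations = load_annotations(config.annotations)
            rules = _select_rules(config.filter_rules)
            if retained_targets:
                decisions = apply_filter_chain(retained_targets, annotations, rules)
            else:
                decisions = []
            decision_frame = decisions_to_frame(decisions)
            _stamp(decision_frame, outdir / "decisions.tsv", config)
            summary = summarize_exclusions(decisions)
            final = sorted(d.gene_id for d in decisions if d.retained)

        report = RunReport(
            venn=venn,
            enrichment=enrichment,
            decisions=decision_frame,
            final_candidates=final,
            exclusion_summary=summary,
            config=config,
            stage_seconds=timings,
        )
        with open(outdir / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        return report
    except Exception:
        logger.exception("pipeline aborted")
        raise


class _StageTimer:
    def __init__(self, name: str, sink: dict[str, float]):
        self.name, self.sink = name, sink

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.sink[self.name] = round(time.perf_counter() - self.t0, 4)
        return False


def _load_curated(path: str) -> CuratedGeneSet:
    if str(path).endswith(".gmt"):
        return CuratedGeneSet.from_gmt(path)
    return CuratedGeneSet.from_list(path)


def _select_rules(names: tuple[str, ...]) -> list[FilterRule]:
    by_name = {r.name: r for r in DEFAULT_RULES}
    rules = []
    for name in names:
        if name not in by_name:
            raise ConfigValidationError(f"unknown filter rule {name!r}")
        rules.append(by_name[name])
    return rules
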