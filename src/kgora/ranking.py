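"""Per-query top-k/top-fraction target selection and multi-query overlap accounting.

A disease can be queried under several closely related terms (e.g. three
ontology terms for one clinical entity); each query yields its own ranked
target list.  This module selects the head of each per-query ranking and
summarizes how the selected sets overlap — the union size, how many targets
recur in two or more query sets, and how many are shared by all queries.

Percentages are truncated (not rounded) to one decimal place, computed with
integer arithmetic; this convention is deliberate and documented because it
affects reported one-decimal figures at the margin.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path

import pandas as pd


class EmptyInputError(ValueError):
    """The prediction table has no rows."""


PREDICTION_COLUMNS = ("query_id", "target_id", "score")


def load_predictions(path: str | Path) -> pd.DataFrame:
    """Read a prediction TSV with columns query_id, target_id, score."""
    df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "target_id": str})
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"prediction table missing columns: {missing}")
    return df


def select_top(
    predictions: pd.DataFrame,
    mode: str = "top_k",
    value: float = 1500,
) -> pd.DataFrame:
    """Select the highest-scoring predictions per query.

    ``mode='top_k'`` keeps ``value`` predictions per query; ``mode='top_fraction'``
    keeps ceil(value * m) where m is the per-query prediction count.  Ties at
    the selection boundary are broken by target_id ascending, and the output
    carries a dense per-query ``rank`` column 1..k.
    """
    if len(predictions) == 0:
        raise EmptyInputError("empty prediction table")
    if mode not in ("top_k", "top_fraction"):
        raise ValueError(f"unknown selection mode {mode!r}")
    if value <= 0:
        raise ValueError("selection value must be positive")
    if mode == "top_fraction" and value > 1:
        raise ValueError("top_fraction value must be in (0, 1]")

    out = []
    for query_id, group in predictions.groupby("query_id", sort=True):
        m = len(group)
        k = int(value) if mode == "top_k" else math.ceil(value * m)
        k = min(k, m)
        chosen = group.sort_values(
            ["score", "target_id"], ascending=[False, True], kind="mergesort"
        ).head(k)
        chosen = chosen.assign(rank=range(1, len(chosen) + 1))
        out.append(chosen)
    return pd.concat(out, ignore_index=True)


@dataclass(frozen=True)
class VennSummary:
    """Exact multi-set overlap accounting across query target sets."""

    per_query_sizes: dict[str, int]
    union_size: int
    multiplicity_counts: dict[int, int]  # m -> #targets in exactly m query sets
    pct_multi: float  # % of union present in >= 2 sets (truncated, 1 dp)
    pct_all: float    # % of union present in all sets (truncated, 1 dp)

    def to_dict(self) -> dict:
        return {
            "per_query_sizes": dict(self.per_query_sizes),
            "union_size": self.union_size,
            "multiplicity_counts": {str(k): v for k, v in self.multiplicity_counts.items()},
            "pct_multi": self.pct_multi,
            "pct_all": self.pct_all,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_table(self) -> str:
        lines = ["query\tn_targets"]
        for q in sorted(self.per_query_sizes):
            lines.append(f"{q}\t{self.per_query_sizes[q]}")
        lines.append(f"union\t{self.union_size}")
        for m in sorted(self.multiplicity_counts):
            lines.append(f"in_exactly_{m}_sets\t{self.multiplicity_counts[m]}")
        lines.append(f"pct_in_multiple_sets\t{self.pct_multi}")
        lines.append(f"pct_in_all_sets\t{self.pct_all}")
        return "\n".join(lines)


def _truncate_pct(numerator: int, denominator: int) -> float:
    """Percentage truncated to one decimal via integer arithmetic."""
    if denominator == 0:
        return 0.0
    return (1000 * numerator // denominator) / 10


def aggregate_queries(per_query_target_sets: Mapping[str, set[str]]) -> VennSummary:
    """Union and per-multiplicity counts over per-query target sets."""
    if not per_query_target_sets:
        raise EmptyInputError("need at least one query set")
    n_queries = len(per_query_target_sets)
    membership: Counter[str] = Counter()
    for targets in per_query_target_sets.values():
        membership.update(set(targets))
    union_size = len(membership)
    multiplicity_counts = dict(Counter(membership.values()))
    n_multi = sum(c for m, c in multiplicity_counts.items() if m >= 2)
    n_all = multiplicity_counts.get(n_queries, 0)
    return VennSummary(
        per_query_sizes={q: len(s) for q, s in per_query_target_sets.items()},
        union_size=union_size,
        multiplicity_counts=multiplicity_counts,
        pct_multi=_truncate_pct(n_multi, union_size),
        pct_all=_truncate_pct(n_all, union_size),
    )
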