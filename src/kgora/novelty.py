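"""Ordered novelty/safety exclusion chain for prioritized targets.

Candidates that survive enrichment are screened against annotation flags:
known disease association (from curation databases), existing drug-development
activity, prior literature links to the disease, oncogenic/toxicity concerns,
and absence of any literature.  Rules are data, not code — an ordered list of
named predicates over a per-gene annotation record — so the exclusion audit
trail is reproducible.  A candidate is excluded by the FIRST matching rule;
the retained set is invariant to rule order, only the attribution changes.
"""

from __future__ import annotations

import warnings
from collections.abc import Callable, Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

#: canonical flag columns; unknown genes default to all-false
FLAG_COLUMNS = (
    "known_association",
    "drug_dev_activity",
    "prior_disease_link",
    "toxicity_or_oncogenic",
    "no_literature",
)


@dataclass(frozen=True)
class FilterRule:
    """Named predicate over an annotation record; ``flag`` is a column name
    or a callable record -> bool."""

    name: str
    flag: str | Callable[[Mapping[str, object]], bool]

    def matches(self, record: Mapping[str, object]) -> bool:
        if callable(self.flag):
            return bool(self.flag(record))
        return bool(record.get(self.flag, False))


DEFAULT_RULES: tuple[FilterRule, ...] = (
    FilterRule("known_association", "known_association"),
    FilterRule("drug_dev_activity", "drug_dev_activity"),
    FilterRule("prior_disease_link", "prior_disease_link"),
    FilterRule("toxicity_or_oncogenic", "toxicity_or_oncogenic"),
    FilterRule("no_literature", "no_literature"),
)


@dataclass(frozen=True)
class NoveltyDecision:
    gene_id: str
    retained: bool
    excluded_by: str = ""


_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n", ""}


def _as_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"cannot interpret flag value {value!r} as boolean")


def load_annotations(path: str | Path) -> pd.DataFrame:
    """Annotation TSV: gene_id plus one column per flag.

    A ``known_association_sources`` column (semicolon-joined source tags)
    is folded into the boolean ``known_association`` flag.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "gene_id" not in df.columns:
        raise ValueError("annotation table missing 'gene_id' column")
    out = pd.DataFrame({"gene_id": df["gene_id"]})
    for col in df.columns:
        if col == "gene_id":
            continue
        if col == "known_association_sources":
            derived = df[col].str.strip() != ""
            out["known_association"] = (
                out.get("known_association", False) | derived
            )
        else:
            out[col] = df[col].map(_as_bool)
    return out.set_index("gene_id", drop=True)


def apply_filter_chain(
    candidate_ids: Sequence[str],
    annotations: pd.DataFrame,
    rules: Sequence[FilterRule] = DEFAULT_RULES,
) -> list[NoveltyDecision]:
    """Evaluate candidates against ordered rules; first match excludes.

    ``annotations`` is indexed by gene_id (see :func:`load_annotations`).
    Genes absent from the table are treated as unannotated (all flags false)
    with a warning.
    """
    if len(set(candidate_ids)) != len(candidate_ids):
        raise ValueError("duplicate candidate ids")
    if not candidate_ids:
        raise ValueError("candidate list is empty")
    names = [r.name for r in rules]
    if len(set(names)) != len(names):
        raise ValueError("rule names must be unique")

    missing = [g for g in candidate_ids if g not in annotations.index]
    if missing:
        warnings.warn(
            f"{len(missing)} candidate(s) absent from annotation table, "
            f"treated as unannotated: {missing[:5]}{'...' if len(missing) > 5 else ''}",
            stacklevel=2,
        )
    decisions = []
    for gene_id in candidate_ids:
        if gene_id in annotations.index:
            record = annotations.loc[gene_id].to_dict()
        else:
            record = {}
        excluded_by = ""
        for rule in rules:
            if rule.matches(record):
                excluded_by = rule.name
                break
        decisions.append(
            NoveltyDecision(gene_id=gene_id, retained=excluded_by == "", excluded_by=excluded_by)
        )
    return decisions


def summarize_exclusions(decisions: Iterable[NoveltyDecision]) -> dict[str, int]:
    """Counts per excluding rule plus the retained count; sums to |candidates|."""
    summary: dict[str, int] = {"retained": 0}
    for d in decisions:
        if d.retained:
            summary["retained"] += 1
        else:
            summary[d.excluded_by] = summary.get(d.excluded_by, 0) + 1
    return summary


def decisions_to_frame(decisions: Iterable[NoveltyDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [(d.gene_id, d.retained, d.excluded_by) for d in decisions],
        columns=["gene_id", "retained", "excluded_by"],
    )
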