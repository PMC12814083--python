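"""Ordered novelty/safety filtering of enrichment-prioritized candidates.

Candidates that pass enrichment are screened against annotation flags in a
fixed order: known disease association, existing drug-development activity,
then expert literature review (prior disease links, toxicity, or no
literature at all).  The fixture mirrors a 74-candidate screen in which the
three stages remove 15, 7 and 47 candidates respectively.
"""

from kgora.novelty import apply_filter_chain, summarize_exclusions
from kgora.synthetic import generate_annotation_fixture

annotations = generate_annotation_fixture(
    74,
    {"known_association": 15, "drug_dev_activity": 7, "prior_disease_link": 47},
    seed=0,
)
decisions = apply_filter_chain(list(annotations.index), annotations)
summary = summarize_exclusions(decisions)

for rule, count in sorted(summary.items()):
    print(f"{rule:24s} {count}")
survivors = [d.gene_id for d in decisions if d.retained]
print()
print(
    f"Of 74 candidates, {summary['known_association']} had known disease "
    f"associations, {summary['drug_dev_activity']} had drug programs, and "
    f"{summary['prior_disease_link']} fell to expert review, leaving "
    f"{len(survivors)} high-novelty candidates: {', '.join(survivors)}."
)
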