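"""Subgraph-level over-representation analysis with planted enrichment.

Each predicted target carries an evidence subgraph (a gene set); we test
whether a 14-gene curated disease set is over-represented in each subgraph,
using the union of qualifying subgraphs as the background universe.
Twenty of the 200 synthetic targets are 'planted': their subgraphs include
curated genes with probability 0.6 instead of the background rate 0.05.
"""

from kgora.ora import CuratedGeneSet, results_to_frame, run_subgraph_ora
from kgora.synthetic import SynthConfig, generate_subgraph_collection

subgraphs, truth = generate_subgraph_collection(SynthConfig(seed=1))
curated = CuratedGeneSet("curated_disease_genes", truth.curated_gene_ids)

results = run_subgraph_ora(subgraphs, curated)
frame = results_to_frame(results)
retained = frame[frame["retained"]]

print(frame.head(8).to_string(index=False))
print()
planted_hits = set(retained["target_id"]) & truth.planted_target_ids
print(
    f"Tested {len(frame)} subgraphs (those holding >=1 curated gene) against "
    f"a background of N={frame['N'].iloc[0]} genes with n={frame['n'].iloc[0]} "
    f"curated genes inside it.  {len(retained)} subgraphs pass FDR < 0.05 "
    f"with >= 3 curated genes; {len(planted_hits)} of the "
    f"{len(truth.planted_target_ids)} planted targets are among them.  "
    "Low q_value plus high overlap k marks targets embedded in "
    "disease-relevant neighborhoods."
)
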