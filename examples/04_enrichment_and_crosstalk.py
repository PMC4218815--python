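"""Gene-set enrichment with overlap clustering, and tumor-host crosstalk.

Up- and down-regulated consensus genes are tested by the hypergeometric
upper tail; significant terms are reported only if they share >= 30% of
their members (overlap coefficient) with another significant term.
Crosstalk candidates are consensus human x consensus mouse gene pairs
backed by a binding-pair reference after orthology normalization.
"""

from xenodeconv import (GeneSetCollection, SimulationConfig,
                        cluster_and_filter, contrast, enrich,
                        generate_bundle, infer_crosstalk, intersect_lines)
from xenodeconv.pipeline import expression_for_species, mask_species

bundle = generate_bundle(SimulationConfig(seed=0))
consensus = {}
for sp, spec in (("human", "B-vs-A"), ("mouse", "B-vs-C")):
    _, mask = mask_species(bundle, sp, 15, 0.75, 3)
    expr = expression_for_species(bundle, sp, mask)
    r1 = contrast(expr, bundle.sample_sheet, spec, sp, "L1")
    r2 = contrast(expr, bundle.sample_sheet, spec, sp, "L2")
    consensus[sp] = intersect_lines(r1, r2)

# enrichment of the human up-regulated consensus genes
cons = consensus["human"]
coll = GeneSetCollection.from_gmt(bundle.gene_sets["human"],
                                  bundle.truth.de_human.index)
up = [g for g in cons.genes if cons.table.loc[g, "direction"] == "up"]
records = enrich(up, coll, direction="up")
clusters = cluster_and_filter(records, coll, theta=0.30, p_max=0.05)
print(f"human up-regulated genes tested: {len(up)}")
print(f"significant terms with a >=30% overlap partner: "
      f"{len(clusters.report)} in {clusters.report.cluster_id.nunique() if len(clusters.report) else 0} cluster(s)")
if len(clusters.report):
    best = clusters.report.iloc[0]
    print(f"top term: {best.term} (k={best.k}/{best.K}, p={best.p:.2e})")

cands = infer_crosstalk(consensus["human"].genes, consensus["mouse"].genes,
                        bundle.interactions, bundle.orthology,
                        human_directions=dict(consensus["human"].table.direction),
                        mouse_directions=dict(consensus["mouse"].table.direction))
print(f"crosstalk candidates (tumor gene x host gene with a known "
      f"binding pair): {len(cands.table)}")
print(cands.table[["human_gene", "mouse_gene", "direction_human",
                   "direction_mouse"]].head().to_string(index=False))
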