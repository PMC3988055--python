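"""Collapse validated reads into isoform models and find novel genes.

Simulates 20 genes but hides 5 of them (and 3 isoforms of visible genes)
from the reference annotation handed to the classifier, mimicking a genome
whose annotation is incomplete.  Reads are collapsed by junction code —
the ordered chain of intron coordinates that identifies an isoform
regardless of its exact 5'/3' ends — and each model is labelled
annotated, novel isoform of a known gene, or novel gene.
"""

from collections import Counter

from isocurate import (
    SimulationConfig,
    build_junction_db,
    classify,
    cluster_new_gene_regions,
    collapse,
    simulate,
    summarize,
    validate_all,
)

dataset = simulate(
    SimulationConfig(
        seed=2,
        n_hidden_genes=5,
        n_hidden_isoforms=3,
        p_truncate_5p=0.0,
        p_truncate_3p=0.0,
    )
)
db = build_junction_db(dataset.junction_records)
_, retained = validate_all(dataset.reads, dataset.genome.chromosomes, db)
models = collapse(retained, dataset.genome.chromosomes)
print(f"{len(retained)} retained reads collapse into {len(models)} isoform models")
print(f"supports sum to {sum(m.support for m in models)} (= retained reads)")

classifications = classify(models, dataset.emitted_annotation)
counts = Counter(c.category for c in classifications)
print("\nclassification against the (incomplete) annotation:")
for category in ("annotated", "novel_isoform_known_gene", "novel_gene"):
    print(f"  {category:26s} {counts.get(category, 0)}")

category_of = {c.model_id: c.category for c in classifications}
novel_gene_models = [m for m in models if category_of[m.id] == "novel_gene"]
regions = cluster_new_gene_regions(novel_gene_models)
summary = summarize(classifications, regions)
print(f"\nnew gene regions found: {len(regions)} "
      f"(simulator hid {len(dataset.truth.hidden_gene_ids)} genes)")
print(f"all new annotations:    {summary.n_new_annotations}")
print(f"exons in new genes:     {summary.n_exons_in_new_genes}")
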