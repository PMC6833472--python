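"""Simulate a four-condition injury/treatment RNA-seq count dataset.

Genes are assigned trajectory classes (e.g. upregulated by injury and
restored to baseline by the drug) and counts drawn from a negative
binomial with variance mu + 0.05 * mu^2 under per-sample depth factors.
"""

from copath import SimulationSpec, simulate_dataset

spec = SimulationSpec(seed=1)
dataset, gene_sets, truth = simulate_dataset(spec)

print(f"conditions: {', '.join(spec.conditions)}")
print(f"counts matrix: {dataset.counts.shape[0]} genes x "
      f"{dataset.counts.shape[1]} samples")
print(truth.gene_truth["path_class"].value_counts().to_string())
print(f"gene-set terms: {len(gene_sets)}, of which "
      f"{int(truth.term_truth['planted'].sum())} planted into a class")

# Each non-flat class holds 5% of genes with a +/-2 log2 effect in the
# conditions its label names; 'flat' genes have no planted effect and
# serve as the null background for calibration checks.
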