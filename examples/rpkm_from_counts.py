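"""Compute RPKM gene-expression values from simulated read counts.

RPKM = count / ((gene length in kb) x (mapped library size in millions)),
the unit the gene-level network is trained on.
"""

import syntrobn as sb

config = sb.ScenarioConfig(n_samples=6, seed=1)
counts, gene_lengths, library_sizes = sb.simulate_counts(config)
print(f"counts: {counts.shape[0]} samples x {counts.shape[1]} genes; "
      f"libraries {library_sizes.min()}-{library_sizes.max()} reads")

rpkm = sb.compute_rpkm(counts, gene_lengths, library_sizes)
summary = rpkm.values.mean(axis=0).round(1)
print("\nmean RPKM per gene:")
for gene, value in summary.items():
    print(f"  {gene:15s} {value:10.1f}  (length {int(gene_lengths[gene])} bp)")
print("\nRPKM removes gene-length and sequencing-depth effects, so values")
print("are comparable across genes and samples.")
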