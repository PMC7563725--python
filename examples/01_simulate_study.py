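"""Generate a synthetic multi-batch case/control expression study.

The generator plants three co-expression modules driven by latent factors
(the first trait-associated, with 10 designated hub genes), background
differentially expressed genes, and per-batch location/scale effects, and
returns the ground truth alongside the matrix.
"""

from coexfeat import default_spec, generate_expression

spec = default_spec(seed=0)
matrix, truth = generate_expression(spec)

print(f"expression matrix: {matrix.n_genes} genes x {matrix.n_samples} samples")
print("samples per batch:", matrix.batch.value_counts().to_dict())
print("cancer samples:", int(matrix.phenotype.sum()))
print("planted module sizes:", truth.module_assignment.value_counts().to_dict())
print("planted hub genes (disease module):", truth.hub_genes["M1"])
print(f"trait-affected genes: {len(truth.de_genes)} "
      f"(|log2FC| range {min(abs(v) for v in truth.de_genes.values()):.2f}"
      f"-{max(abs(v) for v in truth.de_genes.values()):.2f})")
# Every number above is recoverable by the downstream pipeline stages, which
# is what the package's tests verify.
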